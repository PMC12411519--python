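"""Minimal reverse-mode automatic differentiation and neural-network layers.

Everything trainable in this package (the convolutional autoencoder, the
conditional GAN and the windowed-attention classifier) is built on the small
engine in this module: a :class:`Tensor` that records the operations applied
to it and can back-propagate gradients through them, a :class:`Module` base
class that collects parameters, and Adam/AdamW optimizers with an optional
cosine-annealing schedule.

The engine is deliberately small: only the operations the models need are
implemented (dense and convolutional products, gathers, window reshuffles,
element-wise nonlinearities, reductions).  Gradients are exact and are
verified against central finite differences in the test suite.  All
computation is plain NumPy, float32 by default, and fully deterministic for
a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from contextlib import contextmanager
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "Embedding",
    "LayerNorm",
    "Sequential",
    "Adam",
    "CosineAnnealingLR",
    "no_grad",
    "concat",
    "softmax",
    "log_softmax",
    "parameter_checksum",
    "gradcheck",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (evaluation / sampling paths)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward: Callable | None = None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Back-propagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------
    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: _unbroadcast(g, a.shape),
                       lambda g, a, b: _unbroadcast(g, b.shape))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: _unbroadcast(g, a.shape),
                       lambda g, a, b: _unbroadcast(-g, b.shape))

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: _unbroadcast(g * b.data, a.shape),
                       lambda g, a, b: _unbroadcast(g * a.data, b.shape))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: _unbroadcast(g / b.data, a.shape),
                       lambda g, a, b: _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p: float):
        out = _make(np.power(self.data, p), (self,))
        if out._parents:
            def bw(g, a=self, p=p):
                a._accumulate(g * p * np.power(a.data, p - 1))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(np.matmul(self.data, other.data), (self, other))
        if out._parents:
            def bw(g, a=self, b=other):
                if a.requires_grad or a._parents:
                    ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                    a._accumulate(_unbroadcast(ga, a.data.shape))
                if b.requires_grad or b._parents:
                    gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                    b._accumulate(_unbroadcast(gb, b.data.shape))
            out._backward = bw
        return out

    # -- element-wise ------------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = _make(val, (self,))
        if out._parents:
            out._backward = lambda g, a=self, v=val: a._accumulate(g * v)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda g, a=self: a._accumulate(g / a.data)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = _make(val, (self,))
        if out._parents:
            out._backward = lambda g, a=self, v=val: a._accumulate(g * (1.0 - v * v))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(val, (self,))
        if out._parents:
            out._backward = lambda g, a=self, v=val: a._accumulate(g * v * (1.0 - v))
        return out

    def leaky_relu(self, negative_slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, negative_slope).astype(self.data.dtype)
        out = _make(self.data * mask, (self,))
        if out._parents:
            out._backward = lambda g, a=self, m=mask: a._accumulate(g * m)
        return out

    def relu(self):
        return self.leaky_relu(0.0)

    def gelu(self):
        # tanh approximation of the Gaussian error linear unit
        c = np.sqrt(2.0 / np.pi).astype(np.float64)
        inner = _as_tensor(c) * (self + _as_tensor(0.044715) * (self * self * self))
        return _as_tensor(0.5) * self * (1.0 + inner.tanh())

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the band."""
        mask = ((self.data >= lo) & (self.data <= hi)).astype(self.data.dtype)
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out._parents:
            out._backward = lambda g, a=self, m=mask: a._accumulate(g * m)
        return out

    # -- shape -------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            out._backward = lambda g, a=self, s=orig: a._accumulate(g.reshape(s))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = _make(self.data.transpose(axes), (self,))
        if out._parents:
            out._backward = lambda g, a=self, inv=inv: a._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out._parents:
            def bw(g, a=self, idx=idx):
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)
            out._backward = bw
        return out

    def roll(self, shift, axis):
        out = _make(np.roll(self.data, shift, axis=axis), (self,))
        if out._parents:
            if np.isscalar(shift):
                back = -shift
            else:
                back = tuple(-s for s in shift)
            out._backward = lambda g, a=self, s=back, ax=axis: a._accumulate(
                np.roll(g, s, axis=ax))
        return out

    def pad2d(self, p: int):
        """Zero-pad the last two axes of an (N, C, H, W) tensor."""
        if p == 0:
            return self
        out = _make(np.pad(self.data, ((0, 0), (0, 0), (p, p), (p, p))), (self,))
        if out._parents:
            out._backward = lambda g, a=self, p=p: a._accumulate(g[:, :, p:-p, p:-p])
        return out

    def upsample2x(self):
        """Nearest-neighbour 2x upsampling of an (N, C, H, W) tensor."""
        out = _make(self.data.repeat(2, axis=2).repeat(2, axis=3), (self,))
        if out._parents:
            def bw(g, a=self):
                n, c, h2, w2 = g.shape
                a._accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))
            out._backward = bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            def bw(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            denom = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            denom = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32)
                  if not isinstance(x, np.ndarray) else x)


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
    return out


def _binary(a, b, op, bw_a, bw_b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = _make(op(a.data, b.data), (a, b))
    if out._parents:
        def bw(g, a=a, b=b):
            if a.requires_grad or a._parents:
                a._accumulate(bw_a(g, a, b))
            if b.requires_grad or b._parents:
                b._accumulate(bw_b(g, a, b))
        out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g, ts=tensors, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accumulate(piece)
        out._backward = bw
    return out


def take_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather (embedding lookup); backward is scatter-add."""
    idx = np.asarray(idx)
    out = _make(table.data[idx], (table,))
    if out._parents:
        def bw(g, t=table, idx=idx):
            full = np.zeros_like(t.data)
            np.add.at(full, idx, g)
            t._accumulate(full)
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant; softmax is shift-invariant
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    s = x - shift
    return s - s.exp().sum(axis=axis, keepdims=True).log()


# ---------------------------------------------------------------------------
# modules


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: parameter discovery, (de)serialization, checksums."""

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, attr in sorted(vars(self).items()):
            key = f"{prefix}{name}"
            out.extend(_collect(key, attr))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False

    @property
    def frozen(self) -> bool:
        return all(not p.requires_grad for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        mine = dict(self.named_parameters())
        if set(mine) != set(state):
            missing = set(mine) ^ set(state)
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for k, p in mine.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"expected {p.data.shape}, got {arr.shape}")
            p.data = arr.copy()

    def save(self, path: str | Path, sidecar: dict | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.state_dict())
        meta = dict(sidecar or {})
        meta["parameter_checksum"] = parameter_checksum(self)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)

    def load(self, path: str | Path) -> dict:
        path = Path(path)
        with np.load(path) as npz:
            self.load_state_dict({k: npz[k] for k in npz.files})
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            with open(sidecar) as fh:
                return json.load(fh)
        return {}


def _collect(key: str, attr) -> list[tuple[str, Parameter]]:
    if isinstance(attr, Parameter):
        return [(key, attr)]
    if isinstance(attr, Module):
        return attr.named_parameters(prefix=key + ".")
    if isinstance(attr, (list, tuple)):
        out = []
        for i, item in enumerate(attr):
            out.extend(_collect(f"{key}.{i}", item))
        return out
    if isinstance(attr, dict):
        out = []
        for k in sorted(attr):
            out.extend(_collect(f"{key}.{k}", attr[k]))
        return out
    return []


def parameter_checksum(module: Module) -> str:
    """SHA-256 over parameter names and raw bytes, in deterministic order."""
    h = hashlib.sha256()
    for name, p in module.named_parameters():
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """2-D convolution via im2col; input layout (N, C, H, W)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int, padding: int, rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                           size=(out_ch, fan_in)))
        self.bias = Parameter(np.zeros(out_ch))
        self.kernel = kernel
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        xp = x.pad2d(self.padding)
        n, c, h, w = xp.data.shape
        k, s = self.kernel, self.stride
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        cols = _im2col(xp, k, s, ho, wo)                # (N, C*k*k, L)
        out = self.weight @ cols                        # (N, out_ch, L)
        out = out + self.bias.reshape(1, -1, 1)
        return out.reshape(x.data.shape[0], -1, ho, wo)


def _im2col(x: Tensor, k: int, s: int, ho: int, wo: int) -> Tensor:
    """Patch extraction as (N, C*k*k, ho*wo); backward is offset-loop col2im."""
    n, c, h, w = x.data.shape
    st = x.data.strides
    view = np.lib.stride_tricks.as_strided(
        x.data, shape=(n, c, k, k, ho, wo),
        strides=(st[0], st[1], st[2], st[3], st[2] * s, st[3] * s))
    out = _make(view.reshape(n, c * k * k, ho * wo).copy(), (x,))
    if out._parents:
        def bw(g, x=x, k=k, s=s, ho=ho, wo=wo):
            n, c, h, w = x.data.shape
            g6 = g.reshape(n, c, k, k, ho, wo)
            full = np.zeros_like(x.data)
            for ki in range(k):
                for kj in range(k):
                    full[:, :, ki:ki + s * ho:s,
                         kj:kj + s * wo:s] += g6[:, :, ki, kj]
            x._accumulate(full)
        out._backward = bw
    return out


class Embedding(Module):
    def __init__(self, num: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 1.0, size=(num, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return take_rows(self.weight, np.asarray(idx, dtype=np.int64))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, (Module,)) else layer(x)
        return x


class _Lambda(Module):
    """Stateless activation wrapper usable inside Sequential."""

    def __init__(self, fn: Callable[[Tensor], Tensor]):
        self.fn = fn

    def __call__(self, x: Tensor) -> Tensor:
        return self.fn(x)


def leaky(slope: float = 0.2) -> _Lambda:
    return _Lambda(lambda t: t.leaky_relu(slope))


def tanh_layer() -> _Lambda:
    return _Lambda(lambda t: t.tanh())


# ---------------------------------------------------------------------------
# optimization


class Adam:
    """Adam; with ``decoupled_weight_decay`` it is AdamW."""

    def __init__(self, params: Iterable[Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decoupled_weight_decay: bool = False):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled_weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            if self.weight_decay and self.decoupled:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CosineAnnealingLR:
    """Cosine decay of the optimizer learning rate over ``t_max`` steps."""

    def __init__(self, optimizer: Adam, t_max: int, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.t_max = max(int(t_max), 1)
        self.eta_min = eta_min
        self.t = 0

    def step(self) -> None:
        self.t = min(self.t + 1, self.t_max)
        self.optimizer.lr = self.eta_min + 0.5 * (self.base_lr - self.eta_min) * (
            1.0 + np.cos(np.pi * self.t / self.t_max))

    @property
    def lr(self) -> float:
        return self.optimizer.lr


# ---------------------------------------------------------------------------
# verification helper


def gradcheck(fn: Callable[[Tensor], Tensor], x: np.ndarray,
              eps: float = 1e-5, atol: float = 1e-4) -> bool:
    """Compare analytic input gradients of scalar ``fn`` to central differences."""
    x64 = np.asarray(x, dtype=np.float64)
    t = Tensor(x64.copy(), requires_grad=True)
    fn(t).backward()
    analytic = t.grad.copy()
    numeric = np.zeros_like(x64)
    flat = x64.reshape(-1)
    num_flat = numeric.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(Tensor(x64.copy())).item()
        flat[i] = orig - eps
        lo = fn(Tensor(x64.copy())).item()
        flat[i] = orig
        num_flat[i] = (hi - lo) / (2 * eps)
    return np.allclose(analytic, numeric, atol=atol, rtol=1e-3)
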