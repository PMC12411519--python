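"""Hierarchical windowed-attention image classifier.

The backbone is a shifted-window attention network in the Swin family:
images are cut into patches and embedded, then processed by stages of
transformer blocks whose self-attention is restricted to non-overlapping
square windows, with a cyclic half-window shift on every second block so
information crosses window borders; between stages a patch-merging layer
halves the resolution and doubles the channel width.  Pooled features feed
one linear head (softmax over C classes, cross-entropy objective), trained
with AdamW under a cosine-annealed learning rate.

Two variants are exposed:

* ``scratch-small`` — a 2-stage network (window 4, embedding 64, depths
  (2, 2), heads (2, 4)) sized to train from scratch on a CPU at 32-64 px;
  the default path throughout the package.
* ``pretrained-tiny`` — the standard Tiny geometry (window 7, embedding 96,
  depths (2, 2, 6, 2), heads (3, 6, 12, 24), 224 px input).  The
  architecture and its input-size contract are implemented, but no
  pretrained weights ship with the package, so it starts from random
  initialization.

The shifted blocks use the cyclic shift without a border attention mask, an
intentional simplification for the small from-scratch setting.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from ._common import ConfigurationError, DomainError, ShapeError
from .phantom_data import ImageRecord, classifier_chain, load_batch

__all__ = [
    "ClassifierConfig",
    "Prediction",
    "SwinBackbone",
    "SwinClassifier",
    "extract_features",
    "classify",
    "cross_entropy",
    "train_classifier",
]

EPS = 1e-12

_VARIANTS = {
    "scratch-small": dict(input_size=64, patch=4, window=4, embed_dim=64,
                          depths=(2, 2), heads=(2, 4)),
    "pretrained-tiny": dict(input_size=224, patch=4, window=7, embed_dim=96,
                            depths=(2, 2, 6, 2), heads=(3, 6, 12, 24)),
}


@dataclass(frozen=True)
class ClassifierConfig:
    variant: str = "scratch-small"
    input_size: int | None = None        # None -> the variant's default
    num_classes: int = 4
    learning_rate: float = 3e-5
    weight_decay: float = 0.01
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    mlp_ratio: float = 4.0

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; "
                f"choose from {sorted(_VARIANTS)}")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        arch = _VARIANTS[self.variant]
        size = self.input_size or arch["input_size"]
        object.__setattr__(self, "input_size", size)
        _check_geometry(size, arch["patch"], arch["window"],
                        len(arch["depths"]))

    @property
    def arch(self) -> dict:
        return _VARIANTS[self.variant]


def _check_geometry(size: int, patch: int, window: int, n_stages: int) -> None:
    if size % patch != 0:
        raise ShapeError(f"input size {size} not divisible by patch {patch}")
    res = size // patch
    for stage in range(n_stages):
        if res % window != 0 or res == 0:
            raise ShapeError(
                f"token grid {res} at stage {stage} is not divisible by "
                f"window {window} (input size {size})")
        if stage < n_stages - 1:
            if res % 2 != 0:
                raise ShapeError(f"token grid {res} at stage {stage} cannot "
                                 f"be halved for patch merging")
            res //= 2


@dataclass(frozen=True)
class Prediction:
    """Class probabilities (sum to 1), argmax id, optional true id."""

    probabilities: np.ndarray
    predicted_id: int
    true_id: int | None = None

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.min() < -1e-9 or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probabilities", p)


# ---------------------------------------------------------------------------
# backbone


class _WindowAttention(nn.Module):
    def __init__(self, dim: int, heads: int, window: int,
                 rng: np.random.Generator):
        self.heads = heads
        self.head_dim = dim // heads
        if self.head_dim * heads != dim:
            raise ConfigurationError(f"dim {dim} not divisible by {heads} heads")
        self.scale = self.head_dim ** -0.5
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        # learnable relative position bias, indexed per token pair
        self.rel_bias = nn.Parameter(
            rng.normal(0.0, 0.02, size=((2 * window - 1) ** 2, heads)))
        coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                      indexing="ij")).reshape(2, -1)
        rel = coords[:, :, None] - coords[:, None, :] + window - 1
        self._bias_index = (rel[0] * (2 * window - 1) + rel[1]).reshape(-1)
        self.tokens = window * window

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        b, t, c = x.data.shape
        qkv = self.qkv(x).reshape(b, t, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)       # (3, B, heads, T, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        bias = nn.take_rows(self.rel_bias, self._bias_index)
        bias = bias.reshape(t, t, self.heads).transpose(2, 0, 1)
        attn = nn.softmax(attn + bias.reshape(1, self.heads, t, t), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, c)
        return self.proj(out)


class _Mlp(nn.Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc2(self.fc1(x).gelu())


class _SwinBlock(nn.Module):
    def __init__(self, dim: int, heads: int, window: int, shift: int,
                 resolution: int, mlp_ratio: float, rng: np.random.Generator):
        self.window = window
        self.shift = shift
        self.res = resolution
        self.norm1 = nn.LayerNorm(dim)
        self.attn = _WindowAttention(dim, heads, window, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = _Mlp(dim, int(dim * mlp_ratio), rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        b, l, c = x.data.shape
        r, w = self.res, self.window
        h = self.norm1(x).reshape(b, r, r, c)
        if self.shift:
            h = h.roll((-self.shift, -self.shift), axis=(1, 2))
        nw = r // w
        h = (h.reshape(b, nw, w, nw, w, c)
              .transpose(0, 1, 3, 2, 4, 5)
              .reshape(b * nw * nw, w * w, c))
        h = self.attn(h)
        h = (h.reshape(b, nw, nw, w, w, c)
              .transpose(0, 1, 3, 2, 4, 5)
              .reshape(b, r, r, c))
        if self.shift:
            h = h.roll((self.shift, self.shift), axis=(1, 2))
        x = x + h.reshape(b, l, c)
        return x + self.mlp(self.norm2(x))


class _PatchMerging(nn.Module):
    def __init__(self, dim: int, resolution: int, rng: np.random.Generator):
        self.res = resolution
        self.norm = nn.LayerNorm(4 * dim)
        self.reduce = nn.Linear(4 * dim, 2 * dim, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        b, l, c = x.data.shape
        r = self.res
        g = x.reshape(b, r, r, c)
        parts = [g[:, 0::2, 0::2, :], g[:, 1::2, 0::2, :],
                 g[:, 0::2, 1::2, :], g[:, 1::2, 1::2, :]]
        h = nn.concat(parts, axis=-1).reshape(b, (r // 2) ** 2, 4 * c)
        return self.reduce(self.norm(h))


class SwinBackbone(nn.Module):
    """Patch embedding + windowed-attention stages; emits pooled features."""

    def __init__(self, config: ClassifierConfig, rng: np.random.Generator):
        arch = config.arch
        patch, window = arch["patch"], arch["window"]
        self.input_size = config.input_size
        self.patch = patch
        self.patch_embed = nn.Conv2d(3, arch["embed_dim"], kernel=patch,
                                     stride=patch, padding=0, rng=rng)
        self.embed_norm = nn.LayerNorm(arch["embed_dim"])
        res = config.input_size // patch
        dim = arch["embed_dim"]
        stages: list = []
        for s, (depth, heads) in enumerate(zip(arch["depths"], arch["heads"])):
            blocks = [
                _SwinBlock(dim, heads, window,
                           shift=0 if j % 2 == 0 else window // 2,
                           resolution=res, mlp_ratio=config.mlp_ratio, rng=rng)
                for j in range(depth)
            ]
            stages.append(blocks)
            if s < len(arch["depths"]) - 1:
                stages.append(_PatchMerging(dim, res, rng))
                res //= 2
                dim *= 2
        self.stages = stages
        self.norm = nn.LayerNorm(dim)
        self.feature_dim = dim

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.data.shape
        if (c, h, w) != (3, self.input_size, self.input_size):
            raise ShapeError(
                f"backbone expects (3, {self.input_size}, {self.input_size}) "
                f"inputs, got ({c}, {h}, {w})")
        t = self.patch_embed(x)                          # (N, C, r, r)
        r = t.data.shape[-1]
        t = t.reshape(n, -1, r * r).transpose(0, 2, 1)   # (N, L, C)
        t = self.embed_norm(t)
        for stage in self.stages:
            if isinstance(stage, list):
                for block in stage:
                    t = block(t)
            else:
                t = stage(t)
        return self.norm(t).mean(axis=1)                 # (N, feature_dim)


class SwinClassifier(nn.Module):
    def __init__(self, config: ClassifierConfig):
        rng = np.random.default_rng(config.seed)
        self.backbone = SwinBackbone(config, rng)
        self.head = nn.Linear(self.backbone.feature_dim,
                              config.num_classes, rng)
        self.num_classes = config.num_classes

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.head(self.backbone(x))               # logits (N, C)


# ---------------------------------------------------------------------------
# inference


def extract_features(images: np.ndarray, model) -> np.ndarray:
    """Pooled backbone features for a transformed (N, 3, S, S) batch."""
    backbone = model.backbone if isinstance(model, SwinClassifier) else model
    with nn.no_grad():
        return backbone(nn.Tensor(
            np.asarray(images, dtype=np.float32))).data.copy()


def classify(images: np.ndarray, model: SwinClassifier,
             true_ids: Sequence[int] | None = None,
             batch_size: int = 64) -> list[Prediction]:
    """Softmax predictions; argmax ties break toward the lower class id."""
    images = np.asarray(images, dtype=np.float32)
    preds: list[Prediction] = []
    with nn.no_grad():
        for start in range(0, images.shape[0], batch_size):
            logits = model(nn.Tensor(images[start:start + batch_size]))
            probs = nn.softmax(logits, axis=-1).data
            for j in range(probs.shape[0]):
                i = start + j
                preds.append(Prediction(
                    probs[j], int(np.argmax(probs[j])),
                    None if true_ids is None else int(true_ids[i])))
    return preds


def predict_proba(images: np.ndarray, model: SwinClassifier,
                  batch_size: int = 64) -> np.ndarray:
    return np.stack([p.probabilities
                     for p in classify(images, model, batch_size=batch_size)])


def cross_entropy(probabilities: np.ndarray, labels: Sequence[int]) -> float:
    """Mean of -sum_c y_c log p_c over the batch (probabilities given)."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if p.ndim != 2 or len(y) != p.shape[0]:
        raise ValueError("need (N, C) probabilities and N labels")
    if y.min() < 0 or y.max() >= p.shape[1]:
        raise DomainError(f"label out of range [0, {p.shape[1] - 1}]")
    return float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], EPS, 1.0))))


def _ce_loss(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    logp = nn.log_softmax(logits, axis=-1)
    picked = logp[np.arange(len(labels)), np.asarray(labels, dtype=np.int64)]
    return (-1.0) * picked.mean()


# ---------------------------------------------------------------------------
# training


def train_classifier(records: Sequence[ImageRecord],
                     config: ClassifierConfig,
                     ) -> tuple[SwinClassifier, dict[str, list[float]]]:
    """Fine-tune/train on the train split, validating on the val split.

    AdamW with cosine-annealed learning rate (one scheduler step per epoch,
    decaying to ~0 across the run).  Emits per-epoch train/val loss and
    accuracy traces, keeps the best-validation-accuracy parameters, and
    restores them into the returned model.
    """
    train_recs = [r for r in records if r.split == "train"]
    val_recs = [r for r in records if r.split == "val"]
    if not train_recs or not val_recs:
        raise ValueError("train and val splits must both be nonempty")

    chain = classifier_chain(config.input_size)
    x_train, y_train = load_batch(train_recs, chain)
    x_val, y_val = load_batch(val_recs, chain)

    model = SwinClassifier(config)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay,
                  decoupled_weight_decay=True)
    sched = nn.CosineAnnealingLR(opt, t_max=config.epochs)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))

    traces: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
        "lr": []}
    best_acc, best_state = -1.0, None
    n = x_train.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch, yb = nn.Tensor(x_train[idx]), y_train[idx]
            logits = model(batch)
            loss = _ce_loss(logits, yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            hits += int((np.argmax(logits.data, axis=1) == yb).sum())
        traces["lr"].append(float(opt.lr))
        sched.step()
        traces["train_loss"].append(float(np.mean(losses)))
        traces["train_acc"].append(hits / n)
        v_loss, v_acc = evaluate_loss_acc(model, x_val, y_val,
                                          config.batch_size)
        traces["val_loss"].append(v_loss)
        traces["val_acc"].append(v_acc)
        if v_acc > best_acc:
            best_acc = v_acc
            best_state = copy.deepcopy(model.state_dict())
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, traces


def evaluate_loss_acc(model: SwinClassifier, images: np.ndarray,
                      labels: np.ndarray,
                      batch_size: int = 64) -> tuple[float, float]:
    losses, hits = [], 0
    with nn.no_grad():
        for start in range(0, images.shape[0], batch_size):
            batch = nn.Tensor(images[start:start + batch_size])
            yb = labels[start:start + batch_size]
            logits = model(batch)
            losses.append((_ce_loss(logits, yb).item(), len(yb)))
            hits += int((np.argmax(logits.data, axis=1) == yb).sum())
    total = sum(m for _, m in losses)
    loss = sum(v * m for v, m in losses) / total
    return float(loss), hits / len(labels)


def accuracy(model: SwinClassifier, records: Sequence[ImageRecord],
             config: ClassifierConfig) -> float:
    """Plain accuracy of a trained model on a record list."""
    x, y = load_batch(records, classifier_chain(config.input_size))
    return evaluate_loss_acc(model, x, y)[1]
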