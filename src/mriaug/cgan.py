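"""Label-conditioned GAN with an encoder-backed discriminator.

The generator maps (noise z ~ N(0, I), class label y) to a signed-unit
image: the label is embedded, concatenated with the noise, projected to a
small spatial grid, and upsampled through convolution blocks to the working
resolution with a tanh output.  The discriminator scores (image, label)
pairs as sigmoid(head([f(x); e(y)])) where f is a feature extractor — by
default the *frozen* autoencoder encoder, whose parameter checksum is
verified on every call — and e an embedding of the label; only the head and
embedding train.  For the ablation without the autoencoder, the same
architecture is built with a trainable feature extractor instead.

Both players optimize binary cross-entropy.  The discriminator minimizes
    L_D = -1/2 ( E[log D(x_real, y)] + E[log(1 - D(G(z, y), y))] ),
and the generator either the non-saturating surrogate -E[log D(G(z,y), y)]
(default) or the saturating form E[log(1 - D(G(z,y), y))]; both share the
same fixed point.  Probabilities are clamped to [eps, 1-eps] (eps = 1e-7)
inside logarithms.  Training alternates one discriminator step with one
generator step per batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from ._common import ConfigurationError, DomainError, IntegrityError
from .autoencoder import AEConfig, Encoder, FrozenEncoder
from .phantom_data import (ClassRegistry, ImageRecord, ae_chain, load_batch,
                           save_image, write_manifest)

__all__ = [
    "GanConfig",
    "ConditionalGenerator",
    "Discriminator",
    "SyntheticSet",
    "generate",
    "discriminate",
    "discriminator_loss",
    "generator_loss",
    "discriminator_loss_from_probs",
    "generator_loss_from_probs",
    "train_cgan",
    "synthesize_class_set",
    "augment_dataset",
]

EPS = 1e-7


@dataclass(frozen=True)
class GanConfig:
    d_noise: int = 100
    label_embed_dim: int = 32
    learning_rate: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    generator_loss_mode: str = "nonsaturating"   # or "saturating"
    image_size: int = 64
    generator_base_channels: int = 128
    head_hidden: int = 128

    def __post_init__(self):
        if not (0.0 < self.beta1 < 1.0 and 0.0 < self.beta2 < 1.0):
            raise ConfigurationError("Adam betas must lie in (0, 1)")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.generator_loss_mode not in ("nonsaturating", "saturating"):
            raise ConfigurationError(
                f"unknown generator loss mode {self.generator_loss_mode!r}")
        if self.image_size < 8 or self.image_size & (self.image_size - 1):
            raise ConfigurationError("image_size must be a power of two >= 8")


class ConditionalGenerator(nn.Module):
    """(noise, label) -> signed-unit image at the configured size."""

    def __init__(self, config: GanConfig, num_classes: int,
                 rng: np.random.Generator):
        self.num_classes = num_classes
        self.d_noise = config.d_noise
        self.image_size = config.image_size
        base = config.generator_base_channels
        self.start = 4
        n_up = int(math.log2(config.image_size // self.start))
        self.label_emb = nn.Embedding(num_classes, config.label_embed_dim, rng)
        self.fc = nn.Linear(config.d_noise + config.label_embed_dim,
                            base * self.start ** 2, rng)
        self.base = base
        convs = []
        c_in = base
        for i in range(n_up):
            c_out = max(base >> (i + 1), 16)
            convs += [nn.Conv2d(c_in, c_out, kernel=3, stride=1, padding=1,
                                rng=rng)]
            c_in = c_out
        self.convs = convs
        self.out_conv = nn.Conv2d(c_in, 1, kernel=3, stride=1, padding=1,
                                  rng=rng)

    def __call__(self, noise: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
        labels = _check_labels(labels, self.num_classes)
        e = self.label_emb(labels)
        h = self.fc(nn.concat([noise, e], axis=1)).leaky_relu(0.2)
        h = h.reshape(noise.data.shape[0], self.base, self.start, self.start)
        for conv in self.convs:
            h = conv(h.upsample2x()).leaky_relu(0.2)
        return self.out_conv(h).tanh()


class Discriminator(nn.Module):
    """sigmoid(head([features(x); embed(y)])); features frozen by default."""

    def __init__(self, feature_extractor, num_classes: int,
                 config: GanConfig, rng: np.random.Generator):
        self.features = feature_extractor
        self.num_classes = num_classes
        self.frozen_checksum = (feature_extractor.checksum
                                if isinstance(feature_extractor, FrozenEncoder)
                                else None)
        d_z = feature_extractor.latent_dim
        self.label_emb = nn.Embedding(num_classes, config.label_embed_dim, rng)
        self.fc1 = nn.Linear(d_z + config.label_embed_dim,
                             config.head_hidden, rng)
        self.fc2 = nn.Linear(config.head_hidden, 1, rng)

    def verify_frozen(self) -> None:
        if self.frozen_checksum is None:
            return
        now = nn.parameter_checksum(self.features.encoder)
        if now != self.frozen_checksum:
            raise IntegrityError(
                "frozen encoder parameters changed: checksum "
                f"{now[:12]}... != registered {self.frozen_checksum[:12]}...")

    def trainable_parameters(self) -> list[nn.Parameter]:
        return [p for p in self.parameters() if p.requires_grad]

    def __call__(self, images: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
        labels = _check_labels(labels, self.num_classes)
        self.verify_frozen()
        f = self.features(images)
        e = self.label_emb(labels)
        h = self.fc1(nn.concat([f, e], axis=1)).leaky_relu(0.2)
        return self.fc2(h).sigmoid().reshape(images.data.shape[0])


def _check_labels(labels, num_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and (labels.min() < 0 or labels.max() >= num_classes):
        bad = labels[(labels < 0) | (labels >= num_classes)]
        raise DomainError(f"label(s) {sorted(set(bad.tolist()))} out of "
                          f"range [0, {num_classes - 1}]")
    return labels


# ---------------------------------------------------------------------------
# losses


def _clamped_log(p: nn.Tensor) -> nn.Tensor:
    return p.clip(EPS, 1.0 - EPS).log()


def discriminator_loss_from_probs(p_real: nn.Tensor | np.ndarray,
                                  p_fake: nn.Tensor | np.ndarray) -> nn.Tensor:
    """-1/2 (mean log p_real + mean log(1 - p_fake)); nonnegative."""
    p_real = p_real if isinstance(p_real, nn.Tensor) else nn.Tensor(
        np.asarray(p_real, dtype=np.float64))
    p_fake = p_fake if isinstance(p_fake, nn.Tensor) else nn.Tensor(
        np.asarray(p_fake, dtype=np.float64))
    return (-0.5) * (_clamped_log(p_real).mean()
                     + _clamped_log(1.0 - p_fake).mean())


def generator_loss_from_probs(p_fake: nn.Tensor | np.ndarray,
                              mode: str = "nonsaturating") -> nn.Tensor:
    """Non-saturating -E[log p_fake] or saturating E[log(1 - p_fake)]."""
    p_fake = p_fake if isinstance(p_fake, nn.Tensor) else nn.Tensor(
        np.asarray(p_fake, dtype=np.float64))
    if mode == "nonsaturating":
        return (-1.0) * _clamped_log(p_fake).mean()
    if mode == "saturating":
        return _clamped_log(1.0 - p_fake).mean()
    raise ConfigurationError(f"unknown generator loss mode {mode!r}")


def discriminator_loss(disc: Discriminator,
                       real: nn.Tensor, real_labels: np.ndarray,
                       fake: nn.Tensor, fake_labels: np.ndarray) -> nn.Tensor:
    if real.data.shape[0] == 0 or fake.data.shape[0] == 0:
        raise ValueError("batches must be nonempty")
    return discriminator_loss_from_probs(disc(real, real_labels),
                                         disc(fake, fake_labels))


def generator_loss(disc: Discriminator, fake: nn.Tensor,
                   fake_labels: np.ndarray,
                   mode: str = "nonsaturating") -> nn.Tensor:
    return generator_loss_from_probs(disc(fake, fake_labels), mode)


# ---------------------------------------------------------------------------
# inference wrappers


def generate(noise: np.ndarray, labels: np.ndarray,
             generator: ConditionalGenerator) -> np.ndarray:
    """Images in [-1, 1] for (noise, label) pairs; deterministic."""
    noise = np.asarray(noise, dtype=np.float32)
    if noise.shape[0] != len(np.atleast_1d(labels)):
        raise ValueError("noise and label batches must have equal length")
    with nn.no_grad():
        return generator(nn.Tensor(noise), labels).data.copy()


def discriminate(images: np.ndarray, labels: np.ndarray,
                 disc: Discriminator) -> np.ndarray:
    """Real-vs-fake probabilities in (0, 1) for (image, label) pairs."""
    with nn.no_grad():
        return disc(nn.Tensor(np.asarray(images, dtype=np.float32)),
                    labels).data.copy()


# ---------------------------------------------------------------------------
# training


def train_cgan(records: Sequence[ImageRecord] | np.ndarray,
               feature_extractor,
               config: GanConfig,
               labels: np.ndarray | None = None,
               num_classes: int | None = None,
               registry: ClassRegistry | None = None,
               ) -> tuple[ConditionalGenerator, Discriminator,
                          dict[str, list[float]]]:
    """Alternating 1:1 adversarial training; returns (G, D, loss traces).

    ``records`` may be ImageRecords (train split preferred when tagged) or a
    pre-transformed (N, 1, S, S) array with ``labels``.  Every class in
    [0, C) must be present.  The feature extractor is typically a
    :class:`FrozenEncoder`; its checksum is verified throughout.
    """
    if isinstance(records, np.ndarray):
        images = np.asarray(records, dtype=np.float32)
        if labels is None:
            raise ValueError("labels required with an array input")
        y = np.asarray(labels, dtype=np.int64)
    else:
        recs = [r for r in records if r.split == "train"] or list(records)
        images, y = load_batch(recs, ae_chain(config.image_size))
    if num_classes is None:
        num_classes = (registry.num_classes if registry is not None
                       else int(y.max()) + 1)
    present = set(np.unique(y).tolist())
    for c in range(num_classes):
        if c not in present:
            name = registry.name_of(c) if registry is not None else str(c)
            raise DomainError(f"class {name!r} absent from training data")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gen = ConditionalGenerator(config, num_classes,
                               np.random.default_rng(config.seed))
    disc = Discriminator(feature_extractor, num_classes, config,
                         np.random.default_rng(config.seed + 1))
    betas = (config.beta1, config.beta2)
    opt_d = nn.Adam(disc.trainable_parameters(), lr=config.learning_rate,
                    betas=betas)
    opt_g = nn.Adam(gen.parameters(), lr=config.learning_rate, betas=betas)

    n = images.shape[0]
    traces: dict[str, list[float]] = {"d_loss": [], "g_loss": []}
    for _ in range(config.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            real = nn.Tensor(images[idx])
            real_y = y[idx]
            b = len(idx)

            # --- discriminator step (fakes detached) ---
            noise = rng.standard_normal((b, config.d_noise)).astype(np.float32)
            fake_y = rng.integers(0, num_classes, size=b)
            with nn.no_grad():
                fake = gen(nn.Tensor(noise), fake_y)
            d_loss = discriminator_loss(disc, real, real_y,
                                        nn.Tensor(fake.data), fake_y)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # --- generator step (gradient flows through D) ---
            noise = rng.standard_normal((b, config.d_noise)).astype(np.float32)
            fake_y = rng.integers(0, num_classes, size=b)
            fake = gen(nn.Tensor(noise), fake_y)
            g_loss = generator_loss(disc, fake, fake_y,
                                    config.generator_loss_mode)
            opt_g.zero_grad()
            g_loss.backward()
            opt_g.step()

            d_losses.append(d_loss.item())
            g_losses.append(g_loss.item())
        traces["d_loss"].append(float(np.mean(d_losses)))
        traces["g_loss"].append(float(np.mean(g_losses)))
    disc.verify_frozen()
    return gen, disc, traces


# ---------------------------------------------------------------------------
# synthesis and augmentation


@dataclass(frozen=True)
class SyntheticSet:
    """A written set of generated images, per-class balanced, with provenance."""

    records: tuple[ImageRecord, ...]
    per_class_count: int
    class_ids: tuple[int, ...]
    provenance: str                      # generator parameter checksum

    def __post_init__(self):
        counts: dict[int, int] = {}
        for r in self.records:
            counts[r.class_id] = counts.get(r.class_id, 0) + 1
        if set(counts) != set(self.class_ids) or \
                any(v != self.per_class_count for v in counts.values()):
            raise ValueError("synthetic set is not per-class balanced")


def synthesize_class_set(generator: ConditionalGenerator, per_class: int,
                         registry: ClassRegistry, out_dir: str | Path,
                         seed: int = 0,
                         class_ids: Sequence[int] | None = None,
                         batch_size: int = 64) -> SyntheticSet:
    """Write ``per_class`` conditionally generated PNGs per class.

    Files land under ``out_dir/<class_name>/NNNN.png`` with a manifest CSV
    carrying ``source=synthetic``; each record's label is the conditioning
    label, not a prediction.  Deterministic given (generator, seed).
    """
    if per_class < 1:
        raise ConfigurationError("per_class must be >= 1")
    ids = tuple(class_ids if class_ids is not None
                else range(registry.num_classes))
    out = Path(out_dir)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    records: list[ImageRecord] = []
    for cid in ids:
        name = registry.name_of(cid)
        cls_dir = out / name
        cls_dir.mkdir(parents=True, exist_ok=True)
        done = 0
        while done < per_class:
            b = min(batch_size, per_class - done)
            noise = rng.standard_normal((b, generator.d_noise))
            imgs = generate(noise, np.full(b, cid), generator)
            for j in range(b):
                path = cls_dir / f"{done + j:04d}.png"
                save_image(imgs[j, 0], path)
                records.append(ImageRecord(str(path), cid, name,
                                           split="train", source="synthetic"))
            done += b
    write_manifest(records, out / "manifest.csv", include_source=True)
    return SyntheticSet(tuple(records), per_class, ids,
                        provenance=nn.parameter_checksum(generator))


def augment_dataset(real_records: Sequence[ImageRecord],
                    synthetic: SyntheticSet) -> list[ImageRecord]:
    """Real records plus synthetic ones; synthetic enter the train split only.

    Validation/test records pass through untouched, so evaluation data never
    mixes with generated images.
    """
    real_map = {r.class_id: r.class_name for r in real_records}
    for r in synthetic.records:
        if r.class_id in real_map and real_map[r.class_id] != r.class_name:
            raise DomainError(
                f"class registry mismatch: id {r.class_id} is "
                f"{real_map[r.class_id]!r} in the real data but "
                f"{r.class_name!r} in the synthetic set")
    combined = list(real_records)
    combined.extend(synthetic.records)     # all synthetic are split="train"
    return combined
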