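"""Convolutional autoencoder: reconstruction training and the frozen encoder.

The encoder maps a signed-unit grayscale image x to a latent vector
z = E(x) through a stack of stride-2 convolutions and a dense bottleneck;
the decoder mirrors it with nearest-neighbour upsampling and a bounded
(tanh) output so reconstructions stay in [-1, 1].  Training minimizes mean
squared reconstruction error with Adam.

After training, :func:`export_frozen_encoder` detaches a copy of the encoder
whose parameters are flagged non-trainable and fingerprinted with a SHA-256
checksum; the conditional GAN's discriminator uses that copy as its feature
extractor and verifies the checksum on every call, so any drift of the
frozen weights is detected immediately.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from ._common import ConfigurationError, ShapeError
from .phantom_data import ImageRecord, ae_chain, load_batch

__all__ = [
    "AEConfig",
    "Encoder",
    "Decoder",
    "Autoencoder",
    "FrozenEncoder",
    "encode",
    "decode",
    "train_autoencoder",
    "export_frozen_encoder",
]


@dataclass(frozen=True)
class AEConfig:
    image_size: int = 64
    latent_dim: int = 128
    widths: tuple[int, ...] = (32, 64, 128, 256)
    learning_rate: float = 1e-3
    epochs: int = 15
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        n = len(self.widths)
        if self.image_size % (2 ** n) != 0:
            raise ConfigurationError(
                f"image_size {self.image_size} not divisible by 2^{n} "
                f"(one halving per encoder block)")
        if self.latent_dim < 2:
            raise ConfigurationError("latent_dim must be >= 2")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


class Encoder(nn.Module):
    """Stride-2 conv blocks with LeakyReLU, then a dense map to d_z."""

    def __init__(self, config: AEConfig, rng: np.random.Generator):
        self.image_size = config.image_size
        self.latent_dim = config.latent_dim
        layers = []
        c_in = 1
        for w in config.widths:
            layers += [nn.Conv2d(c_in, w, kernel=4, stride=2, padding=1,
                                 rng=rng), nn.leaky(0.2)]
            c_in = w
        self.blocks = nn.Sequential(*layers)
        self.bottom = config.image_size // (2 ** len(config.widths))
        self.fc = nn.Linear(c_in * self.bottom ** 2, config.latent_dim, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        n = x.data.shape[0]
        expected = (1, self.image_size, self.image_size)
        if x.data.shape[1:] != expected:
            raise ShapeError(f"encoder expects images of shape {expected}, "
                             f"got {x.data.shape[1:]}")
        h = self.blocks(x)
        return self.fc(h.reshape(n, -1))


class Decoder(nn.Module):
    """Dense expansion then nearest-up + conv blocks; tanh-bounded output."""

    def __init__(self, config: AEConfig, rng: np.random.Generator):
        self.latent_dim = config.latent_dim
        self.bottom = config.image_size // (2 ** len(config.widths))
        self.c0 = config.widths[-1]
        self.fc = nn.Linear(config.latent_dim, self.c0 * self.bottom ** 2, rng)
        layers = []
        c_in = self.c0
        for w in reversed(config.widths[:-1]):
            layers += [nn.Conv2d(c_in, w, kernel=3, stride=1, padding=1,
                                 rng=rng), nn.leaky(0.2)]
            c_in = w
        self.blocks = layers              # interleaved with upsampling below
        self.out_conv = nn.Conv2d(c_in, 1, kernel=3, stride=1, padding=1,
                                  rng=rng)

    def __call__(self, z: nn.Tensor) -> nn.Tensor:
        if z.data.ndim != 2 or z.data.shape[1] != self.latent_dim:
            raise ShapeError(f"decoder expects latents of dimension "
                             f"{self.latent_dim}, got shape {z.data.shape}")
        h = self.fc(z).leaky_relu(0.2)
        h = h.reshape(z.data.shape[0], self.c0, self.bottom, self.bottom)
        for i in range(0, len(self.blocks), 2):
            h = self.blocks[i](h.upsample2x())
            h = self.blocks[i + 1](h)
        return self.out_conv(h.upsample2x()).tanh()


class Autoencoder(nn.Module):
    def __init__(self, config: AEConfig):
        rng = np.random.default_rng(config.seed)
        self.config_sig = (config.image_size, config.latent_dim,
                           tuple(config.widths))
        self.encoder = Encoder(config, rng)
        self.decoder = Decoder(config, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.decoder(self.encoder(x))


class FrozenEncoder(nn.Module):
    """A non-trainable copy of a trained encoder plus its checksum."""

    def __init__(self, encoder: Encoder):
        self.encoder = copy.deepcopy(encoder)
        self.encoder.freeze()
        self.checksum = nn.parameter_checksum(self.encoder)

    @property
    def latent_dim(self) -> int:
        return self.encoder.latent_dim

    @property
    def image_size(self) -> int:
        return self.encoder.image_size

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.encoder(x)


def _encoder_of(model) -> Encoder:
    if isinstance(model, Autoencoder):
        return model.encoder
    if isinstance(model, FrozenEncoder):
        return model.encoder
    if isinstance(model, Encoder):
        return model
    raise TypeError(f"cannot extract an encoder from {type(model)!r}")


def encode(images: np.ndarray, model) -> np.ndarray:
    """Latent codes z = E(x) for a batch of signed-unit images (N,1,S,S)."""
    enc = _encoder_of(model)
    with nn.no_grad():
        return enc(nn.Tensor(np.asarray(images, dtype=np.float32))).data.copy()


def decode(latents: np.ndarray, model) -> np.ndarray:
    """Reconstructions in [-1, 1] from latent codes (N, d_z)."""
    dec = model.decoder if isinstance(model, Autoencoder) else model
    with nn.no_grad():
        return dec(nn.Tensor(np.asarray(latents, dtype=np.float32))).data.copy()


def reconstruction_loss(output: nn.Tensor, target: nn.Tensor) -> nn.Tensor:
    diff = output - target
    return (diff * diff).mean()


def train_autoencoder(records: Sequence[ImageRecord] | np.ndarray,
                      config: AEConfig) -> tuple[Autoencoder, list[float]]:
    """Train by MSE reconstruction; returns the model and per-epoch losses.

    ``records`` may be ImageRecords (loaded through the signed-unit chain at
    the configured size) or an already-transformed (N, 1, S, S) array.
    """
    if isinstance(records, np.ndarray):
        images = np.asarray(records, dtype=np.float32)
    else:
        if len(records) == 0:
            raise ValueError("empty training set")
        images, _ = load_batch(records, ae_chain(config.image_size))
    if images.shape[0] == 0:
        raise ValueError("empty training set")

    model = Autoencoder(config)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = images.shape[0]
    losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = nn.Tensor(images[order[start:start + config.batch_size]])
            out = model(batch)
            loss = reconstruction_loss(out, batch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        losses.append(float(np.mean(epoch_losses)))
    return model, losses


def export_frozen_encoder(model: Autoencoder) -> FrozenEncoder:
    """Freeze a copy of the encoder for use as the GAN discriminator's
    feature extractor; ``.checksum`` fingerprints the frozen parameters."""
    return FrozenEncoder(_encoder_of(model))
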