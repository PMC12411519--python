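"""Shared fixtures: small phantom datasets and pre-trained tiny models.

Everything is generated programmatically at test time; session scope keeps
the handful of genuinely trained models (autoencoder, small GAN) shared
across the tests that probe them.
"""

from __future__ import annotations

import numpy as np
import pytest

from mriaug import (AEConfig, GanConfig, PhantomSpec, export_frozen_encoder,
                    stratified_split, train_autoencoder, train_cgan,
                    write_phantom_dataset)

SPEC32 = PhantomSpec(image_size=32, seed=0)


@pytest.fixture(scope="session")
def spec32() -> PhantomSpec:
    return SPEC32


@pytest.fixture(scope="session")
def tiny_records(tmp_path_factory):
    """4 classes x 30 phantoms at 32 px, split 80:10:10 -> 24/3/3 per class."""
    root = tmp_path_factory.mktemp("phantoms32")
    records = write_phantom_dataset(SPEC32, root, per_class=30, seed=5)
    return stratified_split(records, (0.8, 0.1, 0.1), seed=5)


@pytest.fixture(scope="session")
def ae_config32() -> AEConfig:
    return AEConfig(image_size=32, latent_dim=64, widths=(16, 32, 64),
                    epochs=3, batch_size=32, seed=0)


@pytest.fixture(scope="session")
def trained_ae(tiny_records, ae_config32):
    train = [r for r in tiny_records if r.split == "train"]
    model, losses = train_autoencoder(train, ae_config32)
    return model, losses


@pytest.fixture(scope="session")
def frozen_encoder(trained_ae):
    return export_frozen_encoder(trained_ae[0])


@pytest.fixture(scope="session")
def gan_config32() -> GanConfig:
    return GanConfig(image_size=32, d_noise=64, generator_base_channels=64,
                     epochs=60, batch_size=32, seed=0)


@pytest.fixture(scope="session")
def trained_gan(tiny_records, frozen_encoder, gan_config32):
    """A briefly but genuinely adversarially-trained conditional GAN."""
    gen, disc, traces = train_cgan(tiny_records, frozen_encoder,
                                   gan_config32, registry=SPEC32.registry())
    return gen, disc, traces


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
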