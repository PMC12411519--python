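"""Shared plumbing: error types, seed derivation, config hashing."""

from __future__ import annotations

import hashlib
import json

import numpy as np


class ConfigurationError(ValueError):
    """A configuration value violates its contract."""


class DomainError(ValueError):
    """An input value is outside the valid domain (e.g. unknown class id)."""


class ShapeError(ValueError):
    """An array has the wrong shape for a model."""


class IntegrityError(RuntimeError):
    """A frozen-artifact checksum no longer matches its registered value."""


# Fixed per-stage offsets so each pipeline stage can be rerun independently
# yet reproducibly from one global seed.
STAGE_SEED_OFFSETS = {
    "phantoms": 11,
    "split": 23,
    "autoencoder": 37,
    "cgan": 53,
    "synthesize": 71,
    "classifier": 97,
    "crossval": 131,
    "ablation": 173,
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from a single global seed, stable across runs."""
    return (int(global_seed) * 1_000 + STAGE_SEED_OFFSETS[stage]) % (2**31)


def config_hash(obj) -> str:
    """SHA-256 of a JSON-canonicalized configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=_jsonify).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    if hasattr(obj, "_asdict"):
        return obj._asdict()
    return str(obj)
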