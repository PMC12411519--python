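"""Phantom image generation, dataset IO, stratified splits and transforms.

The package ships a seeded generator of class-conditional *phantoms*:
grayscale images with an elliptical brain mask on a black field and, for
tumour classes, a single elliptical lesion whose location, size, shape and
intensity are drawn from class-specific intervals.  The four default classes
mirror the usual brain-MRI labelling (no tumour, glioma, meningioma,
pituitary); a three-class registry without the healthy class is also
supported.  Phantoms stand in for real MRI only in structure — folder
layout, label semantics, class-conditional morphology, mild acquisition
jitter — not in physics.

The module also reads/writes PNG class folders and CSV manifests, assigns
stratified train/validation/test splits with largest-remainder rounding, and
implements the two transform chains used downstream: a signed-unit chain
(resize, scale to [-1, 1], single channel) for the autoencoder and GAN, and
a standardized chain (resize, replicate to 3 channels, subtract mean, divide
by sd) for the classifier.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage.transform import resize as _sk_resize

from ._common import ConfigurationError, DomainError

__all__ = [
    "DEFAULT_CLASSES",
    "FIGSHARE_CLASSES",
    "ClassRegistry",
    "ImageRecord",
    "LesionSpec",
    "PhantomSpec",
    "TransformChain",
    "ae_chain",
    "classifier_chain",
    "generate_phantom",
    "sample_phantom_params",
    "write_phantom_dataset",
    "build_dataset",
    "stratified_split",
    "apply_transform",
    "load_image",
    "save_image",
    "write_manifest",
    "read_manifest",
]

SPLITS = ("train", "val", "test")

DEFAULT_CLASSES = ("notumor", "glioma", "meningioma", "pituitary")
FIGSHARE_CLASSES = ("glioma", "meningioma", "pituitary")

# per-channel standardization vectors of the pretrained classifier chain
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class ClassRegistry:
    """Ordered class names; index <-> name is a bijection."""

    names: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate class names: {names}")
        if len(names) not in (3, 4):
            raise ConfigurationError(
                f"expected 3 or 4 classes, got {len(names)}")

    @property
    def num_classes(self) -> int:
        return len(self.names)

    def id_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise DomainError(f"unknown class name {name!r}; "
                              f"registry has {self.names}") from None

    def name_of(self, class_id: int) -> str:
        if not 0 <= class_id < len(self.names):
            raise DomainError(f"class_id {class_id} out of range "
                              f"[0, {len(self.names) - 1}]")
        return self.names[class_id]


@dataclass(frozen=True)
class ImageRecord:
    """One labelled image: where it lives, what it is, which split it is in."""

    path: str
    class_id: int
    class_name: str
    split: str = ""          # one of train/val/test once assigned
    source: str = "real"     # real | synthetic

    def __post_init__(self):
        if self.split and self.split not in SPLITS:
            raise DomainError(f"invalid split tag {self.split!r}")


@dataclass(frozen=True)
class LesionSpec:
    """Sampling intervals for one class's lesion geometry and texture.

    Centers and radii are in unit fractions of the image side; eccentricity
    in [0, 1); intensity in [0, 1].  ``lesion=False`` (the healthy class)
    disables the lesion entirely.
    """

    lesion: bool = True
    center_x_range: tuple[float, float] = (0.4, 0.6)
    center_y_range: tuple[float, float] = (0.4, 0.6)
    radius_range: tuple[float, float] = (0.08, 0.14)
    eccentricity_range: tuple[float, float] = (0.0, 0.5)
    intensity_range: tuple[float, float] = (0.7, 0.9)

    def __post_init__(self):
        for name in ("center_x_range", "center_y_range", "radius_range",
                     "eccentricity_range", "intensity_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ConfigurationError(f"{name} is not a valid interval: "
                                         f"({lo}, {hi})")
        if not (0.0 <= self.eccentricity_range[0]
                and self.eccentricity_range[1] < 1.0):
            raise ConfigurationError("eccentricity must lie in [0, 1)")
        if not (0.0 <= self.intensity_range[0]
                and self.intensity_range[1] <= 1.0):
            raise ConfigurationError("intensity must lie in [0, 1]")


def _default_class_params() -> dict[str, LesionSpec]:
    # Distinct, learnable morphology per class: location, size, shape and
    # brightness all differ, so even a pixel-mean rule beats chance.
    return {
        "notumor": LesionSpec(lesion=False),
        "glioma": LesionSpec(
            center_x_range=(0.28, 0.42), center_y_range=(0.32, 0.48),
            radius_range=(0.10, 0.16), eccentricity_range=(0.3, 0.6),
            intensity_range=(0.75, 0.90)),
        "meningioma": LesionSpec(
            center_x_range=(0.56, 0.70), center_y_range=(0.28, 0.44),
            radius_range=(0.07, 0.12), eccentricity_range=(0.0, 0.3),
            intensity_range=(0.85, 1.00)),
        "pituitary": LesionSpec(
            center_x_range=(0.44, 0.56), center_y_range=(0.56, 0.68),
            radius_range=(0.05, 0.09), eccentricity_range=(0.0, 0.2),
            intensity_range=(0.60, 0.75)),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full sampling specification of the phantom generator.

    ``background`` gives the brain mask's elliptical semi-axes (fractions of
    the side) and the interval the per-image background intensity is drawn
    from — the draw emulates mild acquisition jitter.  ``texture_noise_sd``
    is the sd of additive Gaussian texture inside the brain mask.
    """

    image_size: int = 64
    classes: tuple[str, ...] = DEFAULT_CLASSES
    class_params: dict[str, LesionSpec] = field(
        default_factory=_default_class_params)
    background_semi_axes: tuple[float, float] = (0.42, 0.46)
    background_intensity_range: tuple[float, float] = (0.32, 0.38)
    texture_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ConfigurationError(
                f"image_size must be >= 16, got {self.image_size}")
        if self.texture_noise_sd < 0:
            raise ConfigurationError("texture_noise_sd must be nonnegative")
        for name in self.classes:
            if name not in self.class_params:
                raise ConfigurationError(f"no lesion parameters for class "
                                         f"{name!r}")
        if "notumor" in self.class_params and \
                self.class_params["notumor"].lesion:
            raise ConfigurationError("the healthy class must have no lesion")
        lesioned = [self.class_params[n] for n in self.classes
                    if self.class_params[n].lesion]
        if len({dataclasses.astuple(p) for p in lesioned}) != len(lesioned):
            raise ConfigurationError(
                "distinct classes must have non-identical lesion parameters")

    def registry(self) -> ClassRegistry:
        return ClassRegistry(self.classes)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "image_size": self.image_size,
            "classes": list(self.classes),
            "class_params": {
                n: dataclasses.asdict(p) for n, p in self.class_params.items()
            },
            "background_semi_axes": list(self.background_semi_axes),
            "background_intensity_range":
                list(self.background_intensity_range),
            "texture_noise_sd": self.texture_noise_sd,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        doc = yaml.safe_load(Path(path).read_text())
        params = {
            n: LesionSpec(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in p.items()})
            for n, p in doc.pop("class_params").items()
        }
        for key in ("classes", "background_semi_axes",
                    "background_intensity_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(class_params=params, **doc)


# ---------------------------------------------------------------------------
# phantom generation


def _rng_for(spec: PhantomSpec, class_id: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, class_id, seed]))


def sample_phantom_params(spec: PhantomSpec, class_id: int,
                          seed: int) -> dict:
    """The exact sampled parameters a ``generate_phantom`` call will use.

    Exposed so tests and oracles can recompute geometric quantities (e.g.
    lesion area) independently of the rendered pixels.
    """
    name = spec.registry().name_of(class_id)
    cp = spec.class_params[name]
    rng = _rng_for(spec, class_id, seed)
    out = {"class_name": name,
           "background_level":
               rng.uniform(*spec.background_intensity_range)}
    if cp.lesion:
        out.update(
            center_x=rng.uniform(*cp.center_x_range),
            center_y=rng.uniform(*cp.center_y_range),
            radius=rng.uniform(*cp.radius_range),
            eccentricity=rng.uniform(*cp.eccentricity_range),
            angle=rng.uniform(0.0, np.pi),
            intensity=rng.uniform(*cp.intensity_range),
        )
    return out


def generate_phantom(spec: PhantomSpec, class_id: int, seed: int) -> np.ndarray:
    """Render one phantom; deterministic for fixed ``(spec, class_id, seed)``.

    Returns an ``image_size x image_size`` float array in [0, 1], row-major
    with origin at the top-left.  Tumour classes contain exactly one
    elliptical lesion; the healthy class contains background only.
    """
    name = spec.registry().name_of(class_id)   # validates class_id
    cp = spec.class_params[name]
    rng = _rng_for(spec, class_id, seed)
    s = spec.image_size

    # pixel-center coordinates in unit fractions of the side
    frac = (np.arange(s) + 0.5) / s
    fx, fy = np.meshgrid(frac, frac)           # fy: rows (y), fx: cols (x)

    ax, ay = spec.background_semi_axes
    brain = ((fx - 0.5) / ax) ** 2 + ((fy - 0.5) / ay) ** 2 <= 1.0

    bg_level = rng.uniform(*spec.background_intensity_range)
    img = np.zeros((s, s), dtype=np.float64)
    img[brain] = bg_level

    if cp.lesion:
        cx = rng.uniform(*cp.center_x_range)
        cy = rng.uniform(*cp.center_y_range)
        r = rng.uniform(*cp.radius_range)
        ecc = rng.uniform(*cp.eccentricity_range)
        theta = rng.uniform(0.0, np.pi)
        a, b = r, r * np.sqrt(1.0 - ecc ** 2)
        u = (fx - cx) * np.cos(theta) + (fy - cy) * np.sin(theta)
        v = -(fx - cx) * np.sin(theta) + (fy - cy) * np.cos(theta)
        lesion = ((u / a) ** 2 + (v / b) ** 2 <= 1.0) & brain
        img[lesion] = rng.uniform(*cp.intensity_range)

    if spec.texture_noise_sd > 0:
        img[brain] += rng.normal(0.0, spec.texture_noise_sd,
                                 size=int(brain.sum()))
    return np.clip(img, 0.0, 1.0)


def write_phantom_dataset(spec: PhantomSpec, root_dir: str | Path,
                          per_class: int, seed: int = 0) -> list[ImageRecord]:
    """Write ``per_class`` phantoms per class as 8-bit PNGs under class folders."""
    root = Path(root_dir)
    records: list[ImageRecord] = []
    for class_id, name in enumerate(spec.classes):
        cls_dir = root / name
        cls_dir.mkdir(parents=True, exist_ok=True)
        for i in range(per_class):
            img = generate_phantom(spec, class_id, seed * 1_000_003 + i)
            path = cls_dir / f"{name}_{i:04d}.png"
            save_image(img, path)
            records.append(ImageRecord(str(path), class_id, name))
    return records


# ---------------------------------------------------------------------------
# dataset IO


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG as grayscale float in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64) / 255.0


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Write a float [0, 1] (or signed-unit [-1, 1]) image as 8-bit PNG."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.min() < 0.0:                       # signed-unit range
        arr = (arr + 1.0) / 2.0
    data = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def build_dataset(root_dir: str | Path,
                  registry: ClassRegistry) -> list[ImageRecord]:
    """One record per image under ``root_dir/<class_name>/``; splits unset."""
    root = Path(root_dir)
    subdirs = sorted(p.name for p in root.iterdir() if p.is_dir())
    strays = [d for d in subdirs if d not in registry.names]
    if strays:
        raise DomainError(f"unknown class folder(s) {strays}; "
                          f"registry has {list(registry.names)}")
    records: list[ImageRecord] = []
    for class_id, name in enumerate(registry.names):
        cls_dir = root / name
        if not cls_dir.is_dir():
            raise DomainError(f"missing folder for class {name!r} "
                              f"under {root}")
        files = sorted(cls_dir.glob("*.png"))
        if not files:
            warnings.warn(f"class folder {cls_dir} is empty", stacklevel=2)
        records.extend(ImageRecord(str(f), class_id, name) for f in files)
    return records


def write_manifest(records: Sequence[ImageRecord], path: str | Path,
                   include_source: bool | None = None) -> None:
    """CSV manifest ``path,class_name,class_id,split`` (+``source`` when
    any record is synthetic, or on request)."""
    if include_source is None:
        include_source = any(r.source != "real" for r in records)
    cols = {
        "path": [r.path for r in records],
        "class_name": [r.class_name for r in records],
        "class_id": [r.class_id for r in records],
        "split": [r.split for r in records],
    }
    if include_source:
        cols["source"] = [r.source for r in records]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[ImageRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    has_source = "source" in df.columns
    return [
        ImageRecord(str(row.path), int(row.class_id), str(row.class_name),
                    str(row.split),
                    str(row.source) if has_source else "real")
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# stratified split


def largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of ``n`` over ``fractions`` by largest remainder.

    Floors the quotas, then hands remaining units to the largest fractional
    remainders; ties go to the earlier position (train before val before
    test).  Deterministic and exact: the counts always sum to ``n``.
    """
    quotas = [f * n for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    short = n - sum(base)
    remainders = [q - b for q, b in zip(quotas, base)]
    order = sorted(range(len(fractions)),
                   key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(records: Sequence[ImageRecord],
                     fractions: tuple[float, float, float],
                     seed: int) -> list[ImageRecord]:
    """Assign train/val/test tags per class with largest-remainder rounding."""
    if any(f <= 0 for f in fractions):
        raise ConfigurationError(f"fractions must be positive: {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1: {fractions}")
    by_class: dict[int, list[ImageRecord]] = {}
    for r in records:
        by_class.setdefault(r.class_id, []).append(r)
    out: list[ImageRecord] = []
    for class_id in sorted(by_class):
        recs = by_class[class_id]
        if len(recs) < len(SPLITS):
            raise DomainError(
                f"class {recs[0].class_name!r} has only {len(recs)} records; "
                f"need at least {len(SPLITS)} to split")
        counts = largest_remainder_counts(len(recs), fractions)
        rng = np.random.default_rng(np.random.SeedSequence([seed, class_id]))
        order = rng.permutation(len(recs))
        edges = np.cumsum(counts)
        for pos, idx in enumerate(order):
            split = SPLITS[int(np.searchsorted(edges, pos, side="right"))]
            out.append(replace(recs[idx], split=split))
    return out


# ---------------------------------------------------------------------------
# transform chains


@dataclass(frozen=True)
class TransformChain:
    """Resize + value normalization + channel policy for one model family."""

    target_size: int
    mode: str = "signed_unit"            # signed_unit | standardized
    mean: tuple[float, ...] = IMAGENET_MEAN
    std: tuple[float, ...] = IMAGENET_STD
    channel_policy: str = "gray"         # gray | replicate3
    interpolation: str = "bilinear"      # bilinear | nearest

    def __post_init__(self):
        if self.mode not in ("signed_unit", "standardized"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "standardized":
            if any(s <= 0 for s in self.std):
                raise ConfigurationError(
                    f"standard deviations must be positive: {self.std}")
        if self.interpolation not in ("bilinear", "nearest"):
            raise ConfigurationError(
                f"unknown interpolation {self.interpolation!r}")


def ae_chain(size: int = 64, interpolation: str = "bilinear") -> TransformChain:
    """Signed-unit, single-channel chain for the autoencoder and GAN."""
    return TransformChain(target_size=size, mode="signed_unit",
                          channel_policy="gray", interpolation=interpolation)


def classifier_chain(size: int = 224,
                     mean: tuple[float, ...] = IMAGENET_MEAN,
                     std: tuple[float, ...] = IMAGENET_STD,
                     interpolation: str = "bilinear") -> TransformChain:
    """Standardized 3-channel chain for the classifier."""
    return TransformChain(target_size=size, mode="standardized",
                          mean=mean, std=std, channel_policy="replicate3",
                          interpolation=interpolation)


def apply_transform(image: np.ndarray, chain: TransformChain) -> np.ndarray:
    """Apply a chain to one grayscale image in [0, 1]; returns (C, S, S)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ConfigurationError(f"expected a 2-D grayscale image, "
                                 f"got shape {img.shape}")
    s = chain.target_size
    if img.shape != (s, s):
        order = 1 if chain.interpolation == "bilinear" else 0
        img = _sk_resize(img, (s, s), order=order, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    if chain.mode == "signed_unit":
        out = np.clip(img * 2.0 - 1.0, -1.0, 1.0)
        return out[None, :, :].astype(np.float32)
    # standardized: replicate channels then per-channel standardize exactly
    mean = np.asarray(chain.mean, dtype=np.float64)[:, None, None]
    std = np.asarray(chain.std, dtype=np.float64)[:, None, None]
    reps = len(chain.mean) if chain.channel_policy == "replicate3" else 1
    stacked = np.repeat(img[None, :, :], reps, axis=0)
    return ((stacked - mean) / std).astype(np.float32)


def transform_batch(images: Sequence[np.ndarray],
                    chain: TransformChain) -> np.ndarray:
    return np.stack([apply_transform(im, chain) for im in images])


def load_batch(records: Sequence[ImageRecord],
               chain: TransformChain) -> tuple[np.ndarray, np.ndarray]:
    """Load and transform a record batch -> (images (N,C,S,S), labels (N,))."""
    imgs = transform_batch([load_image(r.path) for r in records], chain)
    labels = np.asarray([r.class_id for r in records], dtype=np.int64)
    return imgs, labels
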