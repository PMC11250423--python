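"""Object exemplar banks: procedural glyphs or Fashion-MNIST patches.

An exemplar is a small grayscale patch together with its intrinsic
attributes: identity class, luminance value (mean pixel, background
included) and the four-level luminance label.  Luminance is *intrinsic* —
a property of the object's own pixels — and is never rescaled or
equalised; the identity–luminance dependency of a bank is therefore
controlled by the per-class luminance distributions of its source
(for glyphs, by ``glyph_luminance_means``).
"""

from __future__ import annotations

import csv
import gzip
import struct
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np

from .glyphs import GLYPH_DRAWERS, draw_glyph

__all__ = [
    "ORIENTATIONS",
    "LUMINANCE_LEVELS",
    "ObjectExemplar",
    "BankConfig",
    "ObjectBank",
    "luminance_value",
    "luminance_level",
    "rotate_object",
    "build_bank",
    "mixed_bank_config",
    "tops_bank_config",
]

#: rotation order: each step is one 90-degree counter-clockwise rotation
ORIENTATIONS = ("up", "left", "down", "right")

#: luminance bins in ascending order, thresholds at multiples of 255/8
LUMINANCE_LEVELS = ("low", "medium_low", "medium_high", "high")
_LUM_EDGES = (255 / 8, 2 * 255 / 8, 3 * 255 / 8)  # 31.875, 63.75, 95.625

# Per-class mean/sd of intrinsic luminance for the default glyph banks.
# The mixed family is strongly class-dependent (shoes dark, bags bright);
# the tops family shares one distribution, making identity and luminance
# independent by construction.
_MIXED_LUM = {"t-shirt": (81.0, 28.6), "pant": (57.2, 13.7),
              "shoe": (33.6, 14.9), "bag": (85.8, 26.2)}
_TOPS_LUM_MEAN, _TOPS_LUM_SD = 90.0, 45.0

# Fashion-MNIST label ids for the classes used here
FASHION_LABELS = {"t-shirt": 0, "pant": 1, "pullover": 2, "coat": 4,
                  "shirt": 6, "shoe": 7, "bag": 8}


def luminance_value(image: np.ndarray) -> float:
    """Mean over every pixel of the patch, zero background included."""
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    return float(arr.mean())


def luminance_level(value: float) -> str:
    """Bin a luminance value into low / medium_low / medium_high / high.

    Bins are closed below and open above: e.g. ``high`` means
    value >= 3*255/8 = 95.625.
    """
    if not 0 <= value <= 255:
        raise ValueError(f"luminance value {value} outside [0, 255]")
    for edge, name in zip(_LUM_EDGES, LUMINANCE_LEVELS[:3]):
        if value < edge:
            return name
    return "high"


@dataclass(frozen=True)
class ObjectExemplar:
    """One object patch plus its intrinsic attributes."""

    image: np.ndarray
    class_label: str
    luminance_value: float
    luminance_level: str
    exemplar_id: int

    def __post_init__(self) -> None:
        lv = luminance_value(self.image)
        if abs(lv - self.luminance_value) > 1e-9:
            raise ValueError("luminance_value inconsistent with image")


def rotate_object(exemplar: ObjectExemplar, orientation: str) -> ObjectExemplar:
    """Return the exemplar rotated into `orientation`.

    "up" is the identity; "left", "down", "right" are one, two and three
    90-degree counter-clockwise rotations.  Rotation permutes pixels, so
    the luminance attributes are unchanged.
    """
    img = rotate_image(exemplar.image, orientation)
    return ObjectExemplar(img, exemplar.class_label, exemplar.luminance_value,
                          exemplar.luminance_level, exemplar.exemplar_id)


def rotate_image(image: np.ndarray, orientation: str) -> np.ndarray:
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    if image.shape[0] != image.shape[1]:
        raise ValueError("rotation requires a square patch")
    return np.rot90(image, k=ORIENTATIONS.index(orientation)).copy()


@dataclass(frozen=True)
class BankConfig:
    source: str = "glyph"  # "glyph" | "fashion_mnist"
    class_names: tuple[str, ...] = ("t-shirt", "pant", "shoe", "bag")
    n_per_class: int = 200
    obj_size: int = 28
    glyph_luminance_means: tuple[float, ...] | None = None
    glyph_luminance_sds: tuple[float, ...] | None = None
    data_dir: str | None = None  # fashion_mnist source only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.source not in ("glyph", "fashion_mnist"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "glyph":
            for name in self.class_names:
                if name not in GLYPH_DRAWERS:
                    raise ValueError(f"unknown class name {name!r}")
            if (self.glyph_luminance_means is not None
                    and len(self.glyph_luminance_means) != len(self.class_names)):
                raise ValueError("glyph_luminance_means length must equal "
                                 "the number of classes")


@dataclass
class ObjectBank:
    """A collection of exemplars grouped by identity class."""

    config: BankConfig
    exemplars: list[ObjectExemplar] = field(default_factory=list)

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.config.class_names

    @property
    def obj_size(self) -> int:
        return self.config.obj_size

    def by_class(self, class_label: str) -> list[ObjectExemplar]:
        return [e for e in self.exemplars if e.class_label == class_label]

    def levels_present(self) -> set[str]:
        return {e.luminance_level for e in self.exemplars}

    def __len__(self) -> int:
        return len(self.exemplars)


def _default_lum_params(cfg: BankConfig) -> tuple[list[float], list[float]]:
    if cfg.glyph_luminance_means is not None:
        means = list(cfg.glyph_luminance_means)
    elif all(c in _MIXED_LUM for c in cfg.class_names):
        means = [_MIXED_LUM[c][0] for c in cfg.class_names]
    else:
        means = [_TOPS_LUM_MEAN] * len(cfg.class_names)
    if cfg.glyph_luminance_sds is not None:
        sds = list(cfg.glyph_luminance_sds)
    elif all(c in _MIXED_LUM for c in cfg.class_names):
        sds = [_MIXED_LUM[c][1] for c in cfg.class_names]
    else:
        sds = [_TOPS_LUM_SD] * len(cfg.class_names)
    return means, sds


def build_bank(config: BankConfig) -> ObjectBank:
    """Build an exemplar bank, deterministic given ``config.seed``."""
    if config.source == "glyph":
        return _build_glyph_bank(config)
    return _build_fashion_bank(config)


def _build_glyph_bank(cfg: BankConfig) -> ObjectBank:
    rng = np.random.default_rng(cfg.seed)
    means, sds = _default_lum_params(cfg)
    family = ("tops" if any(c in ("pullover", "coat", "shirt")
                            for c in cfg.class_names) else "mixed")
    bank = ObjectBank(cfg)
    eid = 0
    for cls, mu, sd in zip(cfg.class_names, means, sds):
        for _ in range(cfg.n_per_class):
            target = float(np.clip(rng.normal(mu, sd), 8.0, 180.0))
            img = draw_glyph(cls, cfg.obj_size, target, rng, family)
            lv = luminance_value(img)
            bank.exemplars.append(
                ObjectExemplar(img, cls, lv, luminance_level(lv), eid))
            eid += 1
    return bank


# ---------------------------------------------------------------------------
# Fashion-MNIST adapter (optional; needs the IDX gz or NPZ files on disk)

def read_idx(path: str | Path) -> np.ndarray:
    """Parse an IDX file (optionally gzip-compressed) into an ndarray."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rb") as fh:
        magic = fh.read(4)
        if len(magic) != 4 or magic[0] != 0 or magic[1] != 0:
            raise ValueError(f"{path} is not an IDX file")
        dtype_code, ndim = magic[2], magic[3]
        if dtype_code != 0x08:
            raise ValueError("only unsigned-byte IDX files are supported")
        dims = struct.unpack(f">{ndim}I", fh.read(4 * ndim))
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    return data.reshape(dims)


def _load_fashion_arrays(data_dir: Path) -> tuple[np.ndarray, np.ndarray]:
    npz = data_dir / "fashion_mnist.npz"
    if npz.exists():
        with np.load(npz) as z:
            return z["images"], z["labels"]
    img_candidates = ["train-images-idx3-ubyte.gz", "train-images-idx3-ubyte"]
    lab_candidates = ["train-labels-idx1-ubyte.gz", "train-labels-idx1-ubyte"]
    for img_name, lab_name in zip(img_candidates, lab_candidates):
        if (data_dir / img_name).exists() and (data_dir / lab_name).exists():
            return read_idx(data_dir / img_name), read_idx(data_dir / lab_name)
    raise FileNotFoundError(
        f"no Fashion-MNIST files found under {data_dir} "
        "(expected fashion_mnist.npz or train-*-ubyte[.gz])")


def _bag_has_handle(image: np.ndarray, top_rows: int = 4) -> bool:
    # handles reach into the top rows of the patch; handleless bags do not
    return bool((image[:top_rows] > 0).any())


def _build_fashion_bank(cfg: BankConfig) -> ObjectBank:
    if cfg.data_dir is None:
        raise ValueError("fashion_mnist source requires data_dir")
    images, labels = _load_fashion_arrays(Path(cfg.data_dir))
    rng = np.random.default_rng(cfg.seed)
    bank = ObjectBank(cfg)
    eid = 0
    for cls in cfg.class_names:
        if cls not in FASHION_LABELS:
            raise ValueError(f"unknown class name {cls!r}")
        idx = np.flatnonzero(labels == FASHION_LABELS[cls])
        if cls == "bag":
            idx = np.array([i for i in idx if _bag_has_handle(images[i])])
        if len(idx) < cfg.n_per_class:
            raise ValueError(f"class {cls!r}: only {len(idx)} exemplars "
                             f"available, {cfg.n_per_class} requested")
        chosen = rng.choice(idx, size=cfg.n_per_class, replace=False)
        for i in chosen:
            img = np.asarray(images[i], dtype=np.uint8)
            lv = luminance_value(img)
            bank.exemplars.append(
                ObjectExemplar(img, cls, lv, luminance_level(lv), eid))
            eid += 1
    return bank


# ---------------------------------------------------------------------------
# bank export / import: NPZ of images plus a CSV manifest

def write_bank(bank: ObjectBank, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path / "images.npz",
                        images=np.stack([e.image for e in bank.exemplars]))
    with open(path / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["exemplar_id", "class", "luminance_value",
                    "luminance_level"])
        for e in bank.exemplars:
            w.writerow([e.exemplar_id, e.class_label,
                        repr(e.luminance_value), e.luminance_level])


def read_bank(path: str | Path, config: BankConfig) -> ObjectBank:
    path = Path(path)
    with np.load(path / "images.npz") as z:
        images = z["images"]
    bank = ObjectBank(config)
    with open(path / "manifest.csv", newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            bank.exemplars.append(ObjectExemplar(
                images[i], row["class"], float(row["luminance_value"]),
                row["luminance_level"], int(row["exemplar_id"])))
    return bank


def mixed_bank_config(n_per_class: int = 200, obj_size: int = 28,
                      seed: int = 0) -> BankConfig:
    """Default bank: four dissimilar classes with class-dependent luminance."""
    return BankConfig(class_names=("t-shirt", "pant", "shoe", "bag"),
                      n_per_class=n_per_class, obj_size=obj_size, seed=seed)


def tops_bank_config(n_per_class: int = 200, obj_size: int = 28,
                     seed: int = 0) -> BankConfig:
    """Tops bank: four upper-body garments sharing one luminance
    distribution, so identity, luminance and orientation are mutually
    independent (the dependency-removed condition)."""
    return BankConfig(class_names=("t-shirt", "pullover", "coat", "shirt"),
                      n_per_class=n_per_class, obj_size=obj_size, seed=seed)
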