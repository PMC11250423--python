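"""Multi-object scene composition and dataset generation.

A scene is a square black canvas (140x140 px by default) holding three
non-overlapping object patches, each centred on one cell of a 3x3 grid.
Locations are numbered 1-9 row-major (1 = top-left, 9 = bottom-right).

Dataset variants
----------------
``original``            all 9 locations; identities / luminance levels /
                        orientations may repeat within a scene.
``equal_classes``       locations restricted to the corners {1, 3, 7, 9},
                        so every attribute has exactly four classes.
``unique_attributes``   all 9 locations, but the three objects of a scene
                        always have pairwise-distinct identities, luminance
                        levels, orientations and locations.

Each variant has a ``*_tops`` twin that is structurally identical but is
meant to be driven by the tops bank (independent attributes); the tops
original variant defaults to 12 000 images instead of 6 000.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bank import ORIENTATIONS, ObjectBank, rotate_image

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "ObjectRecord",
    "Scene",
    "Dataset",
    "DatasetConfig",
    "grid_centers",
    "location_to_rowcol",
    "sample_scene",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

VARIANTS = ("original", "equal_classes", "unique_attributes",
            "original_tops", "equal_classes_tops", "unique_attributes_tops")

_CORNER_LOCATIONS = (1, 3, 7, 9)


@dataclass(frozen=True)
class ObjectRecord:
    """Ground-truth attributes of one placed object."""

    exemplar_id: int
    identity: str
    luminance_value: float
    luminance_level: str
    orientation: str
    location: int  # 1..9 row-major on the 3x3 grid


@dataclass
class Scene:
    canvas: np.ndarray
    objects: list[ObjectRecord]
    scene_id: int


@dataclass
class Dataset:
    train: list[Scene]
    val: list[Scene]
    test: list[Scene]
    config: "DatasetConfig"

    @property
    def splits(self) -> dict[str, list[Scene]]:
        return {"train": self.train, "val": self.val, "test": self.test}


@dataclass(frozen=True)
class DatasetConfig:
    variant: str = "original"
    n_images: int | None = None  # default 6000; 12000 for original_tops
    canvas_size: int = 140
    grid_rows: int = 3
    grid_cols: int = 3
    n_objects: int = 3
    split_fractions: tuple[float, float, float] = (2 / 3, 1 / 6, 1 / 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @property
    def resolved_n_images(self) -> int:
        if self.n_images is not None:
            return self.n_images
        return 12000 if self.variant == "original_tops" else 6000

    @property
    def allowed_locations(self) -> tuple[int, ...]:
        if self.variant.startswith("equal_classes"):
            return _CORNER_LOCATIONS
        return tuple(range(1, self.grid_rows * self.grid_cols + 1))

    @property
    def unique_attributes(self) -> bool:
        return self.variant.startswith("unique_attributes")

    @property
    def n_location_classes(self) -> int:
        return len(self.allowed_locations)


def location_to_rowcol(location: int, grid_cols: int = 3) -> tuple[int, int]:
    """Row-major grid coordinates (0-based) of a 1-based location label."""
    return (location - 1) // grid_cols, (location - 1) % grid_cols


def grid_centers(canvas_size: int, rows: int, cols: int,
                 obj_size: int = 28) -> list[tuple[int, int]]:
    """Pixel centres of an even rows x cols partition of the canvas,
    row-major.  Raises if a cell cannot hold an `obj_size` patch."""
    cell_h = canvas_size / rows
    cell_w = canvas_size / cols
    if cell_h < obj_size or cell_w < obj_size:
        raise ValueError(
            f"grid cell ({cell_h:.1f}x{cell_w:.1f}) smaller than object "
            f"({obj_size}px)")
    centers = []
    for r in range(rows):
        for c in range(cols):
            cr = int((r + 0.5) * cell_h)
            cc = int((c + 0.5) * cell_w)
            centers.append((cr, cc))
    return centers


def _patch_slices(center: tuple[int, int], size: int) -> tuple[slice, slice]:
    r0 = center[0] - size // 2
    c0 = center[1] - size // 2
    return slice(r0, r0 + size), slice(c0, c0 + size)


def _sample_exemplars(bank: ObjectBank, cfg: DatasetConfig,
                      rng: np.random.Generator) -> list:
    n = cfg.n_objects
    if not cfg.unique_attributes:
        idx = rng.choice(len(bank.exemplars), size=n, replace=False)
        return [bank.exemplars[i] for i in idx]
    # unique-attributes: distinct identities and distinct luminance levels
    if len(bank.class_names) < n:
        raise ValueError(f"unique-attributes scene needs >= {n} identity "
                         "classes (failing attribute: identity)")
    if len(bank.levels_present()) < n:
        raise ValueError(f"unique-attributes scene needs >= {n} luminance "
                         "levels in the bank (failing attribute: "
                         "luminance_level)")
    for _ in range(500):
        classes = rng.choice(len(bank.class_names), size=n, replace=False)
        picks = []
        for ci in classes:
            pool = bank.by_class(bank.class_names[ci])
            picks.append(pool[rng.integers(len(pool))])
        if len({e.luminance_level for e in picks}) == n:
            return picks
    raise RuntimeError("could not draw objects with distinct luminance "
                       "levels (failing attribute: luminance_level)")


def sample_scene(bank: ObjectBank, config: DatasetConfig,
                 rng: np.random.Generator, scene_id: int = 0) -> Scene:
    """Compose one scene: sample exemplars, orientations and locations,
    then paint the patches on a black canvas."""
    locs = config.allowed_locations
    n = config.n_objects
    if n > len(locs):
        raise ValueError(f"cannot place {n} objects on {len(locs)} locations")
    centers = grid_centers(config.canvas_size, config.grid_rows,
                           config.grid_cols, bank.obj_size)

    exemplars = _sample_exemplars(bank, config, rng)
    locations = rng.choice(locs, size=n, replace=False)
    if config.unique_attributes:
        oris = rng.choice(len(ORIENTATIONS), size=n, replace=False)
    else:
        oris = rng.integers(len(ORIENTATIONS), size=n)

    canvas = np.zeros((config.canvas_size, config.canvas_size), dtype=np.uint8)
    records = []
    for ex, loc, oi in zip(exemplars, locations, oris):
        orientation = ORIENTATIONS[oi]
        patch = rotate_image(ex.image, orientation)
        rs, cs = _patch_slices(centers[int(loc) - 1], bank.obj_size)
        canvas[rs, cs] = patch
        records.append(ObjectRecord(ex.exemplar_id, ex.class_label,
                                    ex.luminance_value, ex.luminance_level,
                                    orientation, int(loc)))
    return Scene(canvas, records, scene_id)


def split_sizes(n: int, fractions=(2 / 3, 1 / 6, 1 / 6)) -> tuple[int, int, int]:
    n_train = round(n * fractions[0])
    n_val = round(n * fractions[1])
    return n_train, n_val, n - n_train - n_val


def generate_dataset(bank: ObjectBank, config: DatasetConfig) -> Dataset:
    """Generate the train/val/test scene collections, deterministic in
    ``config.seed``; no scene is shared between splits."""
    rng = np.random.default_rng(config.seed)
    n = config.resolved_n_images
    scenes = [sample_scene(bank, config, rng, scene_id=i) for i in range(n)]
    n_train, n_val, n_test = split_sizes(n, config.split_fractions)
    return Dataset(scenes[:n_train], scenes[n_train:n_train + n_val],
                   scenes[n_train + n_val:], config)


# ---------------------------------------------------------------------------
# dataset IO: NPZ canvases + CSV ground truth + JSON config sidecar

_CSV_COLS = ["scene_id", "slot", "exemplar_id", "identity", "luminance_value",
             "luminance_level", "orientation", "location", "split"]


def _config_hash(config: DatasetConfig) -> str:
    blob = json.dumps(vars(config) | {"n_images": config.resolved_n_images},
                      sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_dataset(dataset: Dataset, path: str | Path,
                  image_format: str = "npz") -> None:
    """Write a dataset: canvases as one NPZ (default) or per-scene PNGs,
    ground truth as CSV, configuration as a JSON sidecar."""
    if image_format not in ("npz", "png"):
        raise ValueError(f"unknown image format {image_format!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays, rows = {}, []
    for split, scenes in dataset.splits.items():
        arrays[split] = np.stack([s.canvas for s in scenes]) if scenes else \
            np.zeros((0, dataset.config.canvas_size,
                      dataset.config.canvas_size), dtype=np.uint8)
        for s in scenes:
            for slot, r in enumerate(s.objects):
                rows.append([s.scene_id, slot, r.exemplar_id, r.identity,
                             r.luminance_value, r.luminance_level,
                             r.orientation, r.location, split])
    if image_format == "png":
        from PIL import Image
        png_dir = path / "images"
        png_dir.mkdir(exist_ok=True)
        for split, scenes in dataset.splits.items():
            for s in scenes:
                Image.fromarray(s.canvas, mode="L").save(
                    png_dir / f"{split}_{s.scene_id:06d}.png")
    else:
        np.savez_compressed(path / "images.npz", **arrays)
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path / "records.csv",
                                                 index=False,
                                                 float_format="%.17g")
    sidecar = vars(dataset.config) | {"config_hash": _config_hash(dataset.config)}
    (path / "config.json").write_text(json.dumps(sidecar, indent=2,
                                                 default=str))


def read_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    sidecar_path = path / "config.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing config sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    stored_hash = sidecar.pop("config_hash", None)
    sidecar["split_fractions"] = tuple(sidecar["split_fractions"])
    config = DatasetConfig(**sidecar)
    if stored_hash != _config_hash(config):
        logger.warning("config hash mismatch in %s: sidecar may have been "
                       "edited", path)
        warnings.warn(f"config hash mismatch in {path}", stacklevel=2)

    df = pd.read_csv(path / "records.csv", float_precision="round_trip")
    if (path / "images.npz").exists():
        with np.load(path / "images.npz") as z:
            arrays = {k: z[k] for k in z.files}
    elif (path / "images").is_dir():
        from PIL import Image
        arrays = {}
        for split in ("train", "val", "test"):
            files = sorted((path / "images").glob(f"{split}_*.png"))
            arrays[split] = (np.stack([np.asarray(Image.open(f))
                                       for f in files]) if files else
                             np.zeros((0, config.canvas_size,
                                       config.canvas_size), dtype=np.uint8))
    else:
        raise FileNotFoundError(f"no images.npz or images/ under {path}")
    splits: dict[str, list[Scene]] = {"train": [], "val": [], "test": []}
    for split, scenes in splits.items():
        sub = df[df["split"] == split]
        canvases = arrays[split]
        for i, (sid, grp) in enumerate(sub.groupby("scene_id", sort=True)):
            objs = [ObjectRecord(int(r.exemplar_id), r.identity,
                                 float(r.luminance_value), r.luminance_level,
                                 r.orientation, int(r.location))
                    for r in grp.sort_values("slot").itertuples()]
            scenes.append(Scene(canvases[i], objs, int(sid)))
    return Dataset(splits["train"], splits["val"], splits["test"], config)
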