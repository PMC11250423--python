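"""Factorial experiment grid: variants x maps x tasks x repetitions.

One completed variant yields 4 maps x (4 pathway tasks + 6 pair tasks)
x 3 repetitions = 120 accuracy records — the contents of one results
table (pathway accuracies in part A, two-pathway accuracies in part B).
Pathway networks are trained once per (variant, map, repetition) and
reused by every pair task of that cell, mirroring the pre-train-then-
freeze procedure.  Records are appended to a CSV ledger as they finish,
and a rerun skips cells already present, so a grid is resumable.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .bank import ObjectBank
from .mapping import MAP_NAMES, AttributeCodec
from .pathways import NetworkConfig, build_two_pathways, train_pathway, \
    train_two_pathways
from .scenes import DatasetConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["SINGLE_TASKS", "PAIR_TASKS", "AccuracyRecord", "GridSpec",
           "seed_for", "run_grid", "records_to_frame", "desk_dataset_config"]

SINGLE_TASKS = ("identity", "luminance", "orientation", "location")

#: pair rows in table order
PAIR_TASKS = (("identity", "luminance"), ("orientation", "location"),
              ("identity", "orientation"), ("identity", "location"),
              ("luminance", "orientation"), ("luminance", "location"))


@dataclass(frozen=True)
class AccuracyRecord:
    """One (network, task, map, variant, repetition) measurement."""

    network: str        # "pathway" | "two_pathway"
    task: str           # "identity" or "identity+location"
    map_name: str
    variant: str
    repetition: int     # 1-based
    seed: int
    test_accuracy: float
    runtime_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.test_accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass(frozen=True)
class GridSpec:
    variants: tuple[str, ...] = ("original",)
    maps: tuple[str, ...] = MAP_NAMES
    single_tasks: tuple[str, ...] = SINGLE_TASKS
    pair_tasks: tuple[tuple[str, str], ...] = PAIR_TASKS
    reps: int = 3
    base_seed: int = 0


def seed_for(base_seed: int, *parts) -> int:
    """Deterministic per-cell seed: CRC32 of the cell coordinates."""
    blob = "|".join([str(base_seed)] + [str(p) for p in parts])
    return zlib.crc32(blob.encode()) & 0x7FFFFFFF


def task_name(task) -> str:
    return task if isinstance(task, str) else "+".join(task)


def desk_dataset_config(variant: str = "unique_attributes_tops",
                        n_images: int = 600, canvas_size: int = 42,
                        seed: int = 0) -> DatasetConfig:
    """Scaled-down dataset preset for CPU desk runs."""
    return DatasetConfig(variant=variant, n_images=n_images,
                         canvas_size=canvas_size, seed=seed)


def _load_ledger(path: Path) -> pd.DataFrame | None:
    if path is not None and path.exists():
        return pd.read_csv(path)
    return None


def _has_record(ledger: pd.DataFrame | None, network: str, task: str,
                map_name: str, variant: str, rep: int) -> bool:
    if ledger is None or ledger.empty:
        return False
    m = ((ledger["network"] == network) & (ledger["task"] == task)
         & (ledger["map_name"] == map_name) & (ledger["variant"] == variant)
         & (ledger["repetition"] == rep))
    return bool(m.any())


def _append_record(path: Path | None, record: AccuracyRecord) -> None:
    if path is None:
        return
    df = pd.DataFrame([vars(record)])
    df.to_csv(path, mode="a", header=not path.exists(), index=False)


def run_grid(bank: ObjectBank, grid: GridSpec, net_config: NetworkConfig,
             dataset_config: DatasetConfig | None = None,
             ledger_path: str | Path | None = None,
             progress: bool = False) -> list[AccuracyRecord]:
    """Run the factorial grid and return all AccuracyRecords.

    For every (variant, map, repetition): generate the dataset, train the
    pathway networks needed by the requested tasks, then train a
    two-pathway network for every pair task reusing those pathways.
    Failed cells are logged and skipped, never fatal.
    """
    ledger_path = Path(ledger_path) if ledger_path is not None else None
    ledger = _load_ledger(ledger_path) if ledger_path else None
    records: list[AccuracyRecord] = []

    def emit(record: AccuracyRecord) -> None:
        records.append(record)
        _append_record(ledger_path, record)
        if progress:
            print(f"  {record.network:12s} {record.task:22s} "
                  f"map={record.map_name:11s} rep={record.repetition} "
                  f"acc={record.test_accuracy:.3f} "
                  f"({record.runtime_s:.1f}s)")

    pathway_tasks_needed = set(grid.single_tasks)
    for pair in grid.pair_tasks:
        pathway_tasks_needed.update(pair)

    for variant in grid.variants:
        base_cfg = dataset_config or DatasetConfig(variant=variant)
        if base_cfg.variant != variant:
            base_cfg = replace(base_cfg, variant=variant)
        # one stimulus set per variant; repetitions are training runs
        data_seed = seed_for(grid.base_seed, variant, "data")
        cfg = replace(base_cfg, seed=data_seed)
        dataset = generate_dataset(bank, cfg)
        codec = AttributeCodec(class_names=bank.class_names,
                               locations=cfg.allowed_locations,
                               grid_cols=cfg.grid_cols)
        for rep in range(1, grid.reps + 1):
            for map_name in grid.maps:
                missing_singles = [
                    t for t in grid.single_tasks
                    if not _has_record(ledger, "pathway", t, map_name,
                                       variant, rep)]
                missing_pairs = [
                    p for p in grid.pair_tasks
                    if not _has_record(ledger, "two_pathway", task_name(p),
                                       map_name, variant, rep)]
                to_train = set(missing_singles)
                for pair in missing_pairs:
                    to_train.update(pair)
                pathways = {}
                for task in sorted(to_train & pathway_tasks_needed):
                    cell_seed = seed_for(grid.base_seed, variant, task,
                                         map_name, rep)
                    try:
                        t0 = time.time()
                        tp = train_pathway(
                            dataset, task, map_name,
                            replace(net_config, seed=cell_seed), codec)
                        pathways[task] = tp
                        if task in missing_singles:
                            emit(AccuracyRecord(
                                "pathway", task, map_name, variant, rep,
                                cell_seed, tp.test_accuracy,
                                time.time() - t0))
                    except Exception:
                        logger.exception(
                            "pathway cell failed: %s/%s/%s rep %d",
                            variant, task, map_name, rep)
                for pair in missing_pairs:
                    tname = task_name(pair)
                    if pair[0] not in pathways or pair[1] not in pathways:
                        continue
                    cell_seed = seed_for(grid.base_seed, variant, tname,
                                         map_name, rep)
                    try:
                        t0 = time.time()
                        two = build_two_pathways(
                            pathways[pair[0]], pathways[pair[1]],
                            replace(net_config, seed=cell_seed))
                        train_two_pathways(
                            two, dataset, replace(net_config, seed=cell_seed))
                        emit(AccuracyRecord(
                            "two_pathway", tname, map_name, variant, rep,
                            cell_seed, two.test_accuracy,
                            time.time() - t0))
                    except Exception:
                        logger.exception(
                            "two-pathway cell failed: %s/%s/%s rep %d",
                            variant, tname, map_name, rep)
    return records


def records_to_frame(records: list[AccuracyRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
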