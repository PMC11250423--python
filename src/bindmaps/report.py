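"""Comparisons over accuracy records: mean +- SD tables, Welch's
two-sample t-tests between map conditions, and percentage gains of the
location map over each other map."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harness import MAP_NAMES, PAIR_TASKS, SINGLE_TASKS, task_name

logger = logging.getLogger(__name__)

__all__ = ["ComparisonResult", "GainEntry", "summarize_cells", "welch_test",
           "percentage_gain", "map_comparisons", "location_gains",
           "render_report"]


@dataclass(frozen=True)
class ComparisonResult:
    task: str
    map_a: str
    map_b: str
    t_statistic: float
    df: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class GainEntry:
    task: str
    other_map: str
    gain_percent: float


def welch_test(a, b) -> ComparisonResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Degenerate inputs: if both samples have zero variance the test is
    undefined — equal means give p = 1 by convention, unequal means are
    flagged (t = inf, p = 0) with a log message.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return ComparisonResult("", "", "", 0.0, float(na + nb - 2), 1.0)
        logger.warning("degenerate Welch test: zero variance, unequal means")
        return ComparisonResult("", "", "", np.inf, float(na + nb - 2), 0.0)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    denom = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2 ** 2 / denom
    if not np.isfinite(df) or df <= 0:
        # denominator underflow for near-zero variances; the true df lies
        # in [min(n)-1, n_a+n_b-2] — use the upper end
        df = float(na + nb - 2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult("", "", "", float(t), float(df), float(p))


def percentage_gain(location_acc: float, other_acc: float) -> float:
    """(location-map accuracy - other-map accuracy) / other x 100."""
    if other_acc <= 0:
        raise ValueError("other-map accuracy must be positive")
    return (location_acc - other_acc) / other_acc * 100.0


def summarize_cells(records: pd.DataFrame, network: str = "two_pathway",
                    as_percent: bool = True) -> pd.DataFrame:
    """Mean +- SD per (task, map) cell, tasks as rows, maps as columns.

    SD is the sample standard deviation over repetitions (ddof=1; 0.0
    for a single repetition).  Values are percentages to one decimal
    when ``as_percent``.
    """
    sub = records[records["network"] == network]
    tasks = ([task_name(p) for p in PAIR_TASKS] if network == "two_pathway"
             else list(SINGLE_TASKS))
    rows = []
    for task in tasks:
        row = {}
        for m in MAP_NAMES:
            vals = sub[(sub["task"] == task) & (sub["map_name"] == m)][
                "test_accuracy"].to_numpy()
            if vals.size == 0:
                row[m] = ""
                logger.warning("empty cell: %s / %s", task, m)
                continue
            mean = vals.mean()
            sd = vals.std(ddof=1) if vals.size > 1 else 0.0
            if as_percent:
                row[m] = f"{100 * mean:.1f} ± {100 * sd:.1f}"
            else:
                row[m] = f"{mean:.4f} ± {sd:.4f}"
        rows.append(row)
    return pd.DataFrame(rows, index=tasks, columns=list(MAP_NAMES))


def _cell_values(records: pd.DataFrame, network: str, task: str,
                 map_name: str) -> np.ndarray:
    sub = records[(records["network"] == network)
                  & (records["task"] == task)
                  & (records["map_name"] == map_name)]
    return sub["test_accuracy"].to_numpy()


def map_comparisons(records: pd.DataFrame,
                    network: str = "two_pathway") -> list[ComparisonResult]:
    """Welch tests of the location map against each other map, per task."""
    tasks = ([task_name(p) for p in PAIR_TASKS] if network == "two_pathway"
             else list(SINGLE_TASKS))
    out = []
    for task in tasks:
        loc = _cell_values(records, network, task, "location")
        for other in MAP_NAMES:
            if other == "location":
                continue
            vals = _cell_values(records, network, task, other)
            if loc.size < 2 or vals.size < 2:
                continue
            r = welch_test(loc, vals)
            out.append(ComparisonResult(task, "location", other,
                                        r.t_statistic, r.df, r.p_value))
    return out


def location_gains(records: pd.DataFrame,
                   network: str = "two_pathway") -> list[GainEntry]:
    """Percentage gain of the location map over each other map, per pair
    task, computed from the mean accuracies over repetitions."""
    tasks = ([task_name(p) for p in PAIR_TASKS] if network == "two_pathway"
             else list(SINGLE_TASKS))
    out = []
    for task in tasks:
        loc = _cell_values(records, network, task, "location")
        if loc.size == 0:
            continue
        for other in MAP_NAMES:
            if other == "location":
                continue
            vals = _cell_values(records, network, task, other)
            if vals.size == 0:
                continue
            out.append(GainEntry(task, other,
                                 percentage_gain(loc.mean(), vals.mean())))
    return out


_TASK_SHORT = {"identity": "I", "luminance": "LU", "orientation": "O",
               "location": "LO"}


def _short_task(task: str) -> str:
    return "_".join(_TASK_SHORT.get(t, t) for t in task.split("+"))


def render_report(records: pd.DataFrame, out_dir: str | Path) -> dict:
    """Write per-variant summary CSVs (A: pathway table, B: pair table),
    a Welch-comparison CSV, a gain CSV and one gain bar chart per other
    map.  Returns the produced artefact paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    produced: dict[str, Path] = {}
    if records.empty:
        logger.warning("no records: writing empty report")
        (out_dir / "EMPTY").write_text("no accuracy records\n")
        return {"empty": out_dir / "EMPTY"}
    for variant, sub in records.groupby("variant"):
        a = summarize_cells(sub, network="pathway")
        b = summarize_cells(sub, network="two_pathway")
        pa = out_dir / f"table_{variant}_A_pathways.csv"
        pb = out_dir / f"table_{variant}_B_pairs.csv"
        a.to_csv(pa)
        b.to_csv(pb)
        produced[f"{variant}_A"] = pa
        produced[f"{variant}_B"] = pb

        comps = map_comparisons(sub)
        if comps:
            pc = out_dir / f"welch_{variant}.csv"
            pd.DataFrame([vars(c) | {"significant": c.significant}
                          for c in comps]).to_csv(pc, index=False)
            produced[f"{variant}_welch"] = pc

        gains = location_gains(sub)
        if gains:
            pg = out_dir / f"gains_{variant}.csv"
            gdf = pd.DataFrame([vars(g) for g in gains])
            gdf.to_csv(pg, index=False)
            produced[f"{variant}_gains"] = pg
            produced[f"{variant}_fig"] = _gain_figure(gdf, variant, out_dir)
    return produced


def _gain_figure(gains: pd.DataFrame, variant: str, out_dir: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    others = [m for m in MAP_NAMES if m != "location"]
    fig, axes = plt.subplots(1, len(others), figsize=(4 * len(others), 3),
                             sharey=False)
    for ax, other in zip(np.atleast_1d(axes), others):
        sub = gains[gains["other_map"] == other]
        labels = [_short_task(t) for t in sub["task"]]
        ax.bar(labels, sub["gain_percent"], color="steelblue")
        ax.axhline(0, color="k", lw=0.8)
        ax.set_title(f"location vs {other} map")
        ax.set_ylabel("gain (%)")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    path = out_dir / f"gains_{variant}.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
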