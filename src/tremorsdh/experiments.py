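"""Experiment drivers: coordinate selection, feature sweep, window sweep.

Three experiment families are reproduced on any cohort of recordings:

* coordinate selection — which palm coordinate (x, y, z, or all three)
  carries the tremor information, scored at window size 125;
* feature sweep — per-feature accuracy of each single texture feature
  across a grid of window sizes, for both classifiers;
* window sweep — the full metric battery for chosen feature sets over a
  window-size grid, summarized as min/mean/max over repetitions, with a
  focal-size report in the study's summary-table layout.

Every sweep cell derives its own seed from a stable hash of (master seed,
window size, feature set, classifier), so evaluating a sub-grid reproduces
the corresponding cells of the full grid exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import FeatureDataset, assemble_dataset
from .model import (
    BaggedTreesSpec,
    ClassifierSpec,
    KNNSpec,
    TremorLevelResults,
    repeat_evaluation,
)
from .schema import Recording
from .sdh import FEATURE_NAMES
from .schema import palm_position_channels

#: Coordinate sets compared in the coordinate-selection experiment.
COORDINATE_SETS: dict[str, str] = {"x": "x", "y": "y", "z": "z", "xyz": "xyz"}


def default_window_grid() -> np.ndarray:
    """The 250 odd window sizes 3, 5, ..., 501."""
    return np.arange(3, 502, 2)


def cell_seed(master_seed: int, *parts) -> int:
    """Stable per-cell seed < 2^31 from the master seed and cell identity."""
    key = repr((int(master_seed),) + tuple(str(p) for p in parts))
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _default_classifiers() -> list[ClassifierSpec]:
    return [BaggedTreesSpec(), KNNSpec()]


@dataclasses.dataclass
class SweepResult:
    """Grid of evaluation summaries plus full provenance.

    ``cells`` has one row per (window size, feature set, classifier) with
    min/mean/max of every metric; ``per_rep`` keeps each cell's raw
    per-repetition metrics for audit.
    """

    cells: pd.DataFrame
    per_rep: pd.DataFrame
    provenance: Mapping

    def to_csv(self, cells_path, per_rep_path=None) -> None:
        self.cells.to_csv(cells_path, index=False)
        if per_rep_path is not None:
            self.per_rep.to_csv(per_rep_path, index=False)


def _evaluate_cell(
    recordings: Sequence[Recording],
    channels,
    features: Sequence[str],
    N: int,
    spec: ClassifierSpec,
    reps: int,
    master_seed: int,
    M: int,
    stride: int,
    bin_width: float,
    dataset_cache: dict | None = None,
) -> TremorLevelResults:
    feat_key = tuple(features)
    cache_key = (N, channels if isinstance(channels, str) else tuple(channels))
    if dataset_cache is not None and cache_key in dataset_cache:
        full = dataset_cache[cache_key]
    else:
        full = assemble_dataset(
            recordings, channels=channels, features=None, M=M, N=N,
            stride=stride, bin_width=bin_width,
        )
        if dataset_cache is not None:
            dataset_cache[cache_key] = full
    if isinstance(channels, str):
        keep = list(feat_key)
    else:
        keep = [f"{ch}:{f}" for ch in channels for f in feat_key]
    ds = FeatureDataset(
        frame=full.frame[[*keep, "level", "recording_id", "window_index"]],
        feature_names=keep,
    )
    seed = cell_seed(master_seed, N, feat_key, spec.name)
    return repeat_evaluation(ds, spec, reps=reps, master_seed=seed)


def coordinate_selection(
    recordings: Sequence[Recording],
    classifiers: Sequence[ClassifierSpec] | None = None,
    N: int = 125,
    reps: int = 5,
    master_seed: int = 0,
    M: int = 1,
    stride: int = 1,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Mean accuracy per palm-coordinate set at a fixed window size.

    Evaluates all nine texture features of Cp(x), Cp(y), Cp(z) and
    Cp(x, y, z) for each classifier. Returns a table with one row per
    classifier, one column per coordinate set, plus a ``mean`` row
    averaging over classifiers; window size and seeds are recorded in the
    table attrs.
    """
    classifiers = list(classifiers) if classifiers is not None else _default_classifiers()
    cache: dict = {}
    table: dict[str, dict[str, float]] = {}
    for spec in classifiers:
        row = {}
        for label, axes in COORDINATE_SETS.items():
            channels = (
                palm_position_channels(axes)[0] if len(axes) == 1
                else palm_position_channels(axes)
            )
            res = _evaluate_cell(
                recordings, channels, FEATURE_NAMES, N, spec, reps,
                master_seed, M, stride, bin_width, dataset_cache=cache,
            )
            row[label] = res.mean_accuracy
        table[spec.name] = row
    out = pd.DataFrame(table).T
    out.loc["mean"] = out.mean(axis=0)
    out.index.name = "classifier"
    out.attrs["window_size"] = N
    out.attrs["master_seed"] = int(master_seed)
    out.attrs["reps"] = reps
    return out


def feature_sweep(
    recordings: Sequence[Recording],
    grid: Iterable[int] | None = None,
    classifiers: Sequence[ClassifierSpec] | None = None,
    reps: int = 3,
    master_seed: int = 0,
    channels: str = "palm_pos_x",
    M: int = 1,
    stride: int = 1,
    bin_width: float = 0.1,
) -> SweepResult:
    """Accuracy of each single texture feature across window sizes."""
    grid = list(grid) if grid is not None else list(default_window_grid())
    classifiers = list(classifiers) if classifiers is not None else _default_classifiers()
    cell_rows, rep_rows = [], []
    for N in grid:
        cache: dict = {}
        for feat in FEATURE_NAMES:
            for spec in classifiers:
                res = _evaluate_cell(
                    recordings, channels, (feat,), int(N), spec, reps,
                    master_seed, M, stride, bin_width, dataset_cache=cache,
                )
                acc = res.per_rep["accuracy"]
                cell_rows.append(
                    dict(window_size=int(N), feature=feat, classifier=spec.name,
                         acc_min=acc.min(), acc_mean=acc.mean(), acc_max=acc.max())
                )
                for rep, row in res.per_rep.iterrows():
                    rep_rows.append(
                        dict(window_size=int(N), feature=feat,
                             classifier=spec.name, rep=int(rep), **row.to_dict())
                    )
    return SweepResult(
        cells=pd.DataFrame(cell_rows),
        per_rep=pd.DataFrame(rep_rows),
        provenance=dict(master_seed=int(master_seed), reps=reps, grid=grid,
                        channels=channels, M=M, stride=stride,
                        bin_width=bin_width, kind="feature_sweep"),
    )


def top_features(sweep: SweepResult, classifier: str | None = None, k: int = 2) -> list[str]:
    """The k features with highest mean accuracy at the largest window size."""
    cells = sweep.cells
    at_max = cells[cells["window_size"] == cells["window_size"].max()]
    if classifier is not None:
        at_max = at_max[at_max["classifier"] == classifier]
    ranked = (
        at_max.groupby("feature")["acc_mean"].mean().sort_values(ascending=False)
    )
    return list(ranked.index[:k])


def window_sweep(
    recordings: Sequence[Recording],
    feature_sets: Sequence[Sequence[str]] = (("contrast",), ("homogeneity",)),
    classifier: ClassifierSpec | None = None,
    grid: Iterable[int] | None = None,
    reps: int = 30,
    master_seed: int = 0,
    channels: str = "palm_pos_x",
    M: int = 1,
    stride: int = 1,
    bin_width: float = 0.1,
) -> SweepResult:
    """Full metric battery for chosen feature sets over a window-size grid."""
    grid = list(grid) if grid is not None else list(default_window_grid())
    spec = classifier or BaggedTreesSpec()
    cell_rows, rep_rows = [], []
    for N in grid:
        cache: dict = {}
        for features in feature_sets:
            res = _evaluate_cell(
                recordings, channels, tuple(features), int(N), spec, reps,
                master_seed, M, stride, bin_width, dataset_cache=cache,
            )
            agg = res.aggregate()
            row = dict(window_size=int(N), feature_set="+".join(features),
                       classifier=spec.name)
            for metric, stats in agg.iterrows():
                row[f"{metric}_min"] = stats["min"]
                row[f"{metric}_mean"] = stats["mean"]
                row[f"{metric}_max"] = stats["max"]
            cell_rows.append(row)
            for rep, rrow in res.per_rep.iterrows():
                rep_rows.append(
                    dict(window_size=int(N), feature_set="+".join(features),
                         classifier=spec.name, rep=int(rep), **rrow.to_dict())
                )
    return SweepResult(
        cells=pd.DataFrame(cell_rows),
        per_rep=pd.DataFrame(rep_rows),
        provenance=dict(master_seed=int(master_seed), reps=reps, grid=grid,
                        channels=channels, M=M, stride=stride,
                        bin_width=bin_width, kind="window_sweep"),
    )


def focal_report(sweep: SweepResult, focal_sizes: Sequence[int] = (149, 299, 449)) -> pd.DataFrame:
    """Summary-table-shaped report: metrics x feature set at focal window sizes.

    One row per (metric, feature set), one column triplet (min, mean, max)
    per focal window size.
    """
    cells = sweep.cells
    missing = [w for w in focal_sizes if w not in set(cells["window_size"])]
    if missing:
        raise ValueError(f"focal sizes {missing!r} not in the evaluated grid")
    metric_cols = sorted(
        {c[: -len("_mean")] for c in cells.columns if c.endswith("_mean")}
    )
    rows = []
    for metric in metric_cols:
        for fs in cells["feature_set"].unique():
            row: dict = {"metric": metric, "feature_set": fs}
            for w in focal_sizes:
                cell = cells[(cells["window_size"] == w) & (cells["feature_set"] == fs)]
                for stat in ("min", "mean", "max"):
                    row[f"ws{w}_{stat}"] = float(cell[f"{metric}_{stat}"].iloc[0])
            rows.append(row)
    return pd.DataFrame(rows)
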