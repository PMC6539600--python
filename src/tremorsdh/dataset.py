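"""Labeled feature datasets: assembly, class balancing, train/test splitting."""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .schema import Recording
from .sdh import FEATURE_NAMES, Kernel, features_for_recording

logger = logging.getLogger(__name__)

META_COLUMNS = ("level", "recording_id", "window_index")

Grouping = Literal["window", "recording"]


@dataclasses.dataclass
class FeatureDataset:
    """Windowed texture features with labels and provenance.

    ``frame`` holds the feature columns plus ``level`` (tremor label),
    ``recording_id`` and ``window_index``; every row is one analysis window
    of one recording and inherits that recording's tremor level.
    """

    frame: pd.DataFrame
    feature_names: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in (*self.feature_names, *META_COLUMNS)
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset frame missing columns {missing!r}")
        if self.frame[self.feature_names].isna().any().any():
            raise ValueError("dataset contains missing feature values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.frame["level"].to_numpy()

    def class_counts(self) -> dict[int, int]:
        counts = self.frame["level"].value_counts().to_dict()
        return {int(k): int(v) for k, v in sorted(counts.items())}

    def subset(self, index: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            frame=self.frame.iloc[index].reset_index(drop=True),
            feature_names=list(self.feature_names),
        )


def assemble_dataset(
    recordings: Iterable[Recording],
    channels: str | Sequence[str] = "palm_pos_x",
    features: Sequence[str] | None = None,
    M: int = 1,
    N: int = 149,
    stride: int = 1,
    bin_width: float = 0.1,
    kernel: Kernel = "abs",
) -> FeatureDataset:
    """Concatenate per-window features across recordings (both hands pooled).

    ``features`` optionally restricts to a subset of the nine texture
    features (applied per channel for channel sets). Recordings too short
    for a single window are skipped with a warning.
    """
    single = isinstance(channels, str)
    if features is not None:
        unknown = [f for f in features if f not in FEATURE_NAMES]
        if unknown:
            raise KeyError(f"unknown feature(s) {unknown!r}")
    blocks = []
    for rec in recordings:
        try:
            table = features_for_recording(
                rec, channels=channels, M=M, N=N, stride=stride,
                bin_width=bin_width, kernel=kernel,
            )
        except ValueError as exc:
            warnings.warn(f"skipping {rec.recording_id}: {exc}", stacklevel=2)
            continue
        table["level"] = rec.tremor_level
        table["recording_id"] = rec.recording_id
        blocks.append(table)
    if not blocks:
        raise ValueError("no recording was long enough for a single window")
    frame = pd.concat(blocks, ignore_index=True)
    if features is not None:
        if single:
            keep = list(features)
        else:
            keep = [f"{ch}:{feat}" for ch in channels for feat in features]
        frame = frame[[*keep, *META_COLUMNS]]
        names = keep
    else:
        names = [c for c in frame.columns if c not in META_COLUMNS]
    logger.info("assembled dataset: %d rows, %d features", len(frame), len(names))
    return FeatureDataset(frame=frame, feature_names=list(names))


def balance_classes(
    ds: FeatureDataset, per_class: int | str = "min", seed: int = 0
) -> FeatureDataset:
    """Random undersampling without replacement to equal class counts.

    ``per_class`` is a target count or ``"min"`` (the smallest class's
    count). Deterministic given ``seed``.
    """
    counts = ds.class_counts()
    if not counts:
        raise ValueError("empty dataset")
    target = min(counts.values()) if per_class == "min" else int(per_class)
    short = {c: n for c, n in counts.items() if n < target}
    if short:
        raise ValueError(
            f"per_class={target} exceeds availability for class(es) {short!r}"
        )
    rng = np.random.default_rng(seed)
    picks = []
    for level in sorted(counts):
        idx = np.flatnonzero(ds.frame["level"].to_numpy() == level)
        picks.append(rng.choice(idx, size=target, replace=False))
    index = np.concatenate(picks)
    logger.info("balanced to %d rows per class (%d total)", target, len(index))
    return ds.subset(index)


def split_train_test(
    ds: FeatureDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
    grouping: Grouping = "window",
) -> tuple[FeatureDataset, FeatureDataset]:
    """Random train/test split of the dataset rows.

    ``window`` grouping is a uniform row-level split (sizes within one row
    of the fraction). ``recording`` grouping keeps all windows of a
    recording on one side — the leakage-safe alternative, since overlapping
    windows of one recording are strongly correlated — with sizes as close
    to the fraction as whole recordings allow.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(ds)
    rng = np.random.default_rng(seed)
    if grouping == "window":
        n_train = round(n * train_fraction)
        if n_train == 0 or n_train == n:
            raise ValueError("split would leave one side empty")
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    elif grouping == "recording":
        rec_ids = ds.frame["recording_id"].to_numpy()
        groups = pd.unique(rec_ids)
        order = rng.permutation(len(groups))
        sizes = pd.Series(rec_ids).value_counts()
        target = n * train_fraction
        train_groups, taken = [], 0
        for gi in order:
            g = groups[gi]
            # take the recording if it brings us closer to the target count
            if abs(taken + sizes[g] - target) <= abs(taken - target):
                train_groups.append(g)
                taken += sizes[g]
        if not train_groups or len(train_groups) == len(groups):
            raise ValueError("split would leave one side empty")
        mask = np.isin(rec_ids, train_groups)
        train_idx, test_idx = np.flatnonzero(mask), np.flatnonzero(~mask)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return ds.subset(train_idx), ds.subset(test_idx)
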