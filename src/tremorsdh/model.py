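"""Tremor-level classification model and its repeated-evaluation results.

The estimation protocol mirrors the study design: pool the windowed texture
features of every retained recording (both hands), balance the three classes
by random undersampling, split 70/30 at the window level, train an ensemble
of bagged decision trees (or a nearest-neighbour classifier), and score the
held-out windows; repeat the whole cycle and report min/mean/max of overall
accuracy and per-class one-vs-rest precision, sensitivity and specificity.

:class:`TremorLevelModel` packages that protocol statsmodels-style: build it
from recordings or a prepared feature frame, call :meth:`~TremorLevelModel.fit`,
and read the :class:`TremorLevelResults` it returns.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from . import dataset as _dataset
from .dataset import FeatureDataset, Grouping, assemble_dataset
from .schema import Recording

LEVELS = (0, 1, 2)


# ---------------------------------------------------------------------------
# classifier specs


@dataclasses.dataclass(frozen=True)
class BaggedTreesSpec:
    """Bootstrap-aggregated decision trees combined by majority vote."""

    n_learners: int = 30

    name = "bagged_trees"

    def build(self, seed: int):
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(),
            n_estimators=self.n_learners,
            random_state=int(seed),
        )


@dataclasses.dataclass(frozen=True)
class KNNSpec:
    """k-nearest-neighbour with Euclidean distance; k=1 is the 'fine' preset.

    Features are standardized before the distance computation by default —
    the texture features span wildly different scales (cluster prominence is
    a fourth moment of integer levels), and Euclidean distance is
    meaningless without it; this also matches the common toolbox preset.
    """

    k: int = 1
    standardize: bool = True

    name = "knn"

    def build(self, seed: int):
        knn = KNeighborsClassifier(n_neighbors=self.k, metric="euclidean")
        return make_pipeline(StandardScaler(), knn) if self.standardize else knn


ClassifierSpec = BaggedTreesSpec | KNNSpec


def train_classifier(train: FeatureDataset, spec: ClassifierSpec, seed: int = 0):
    """Fit the specified classifier on a training dataset."""
    counts = train.class_counts()
    if any(v < 1 for v in counts.values()) or not counts:
        raise ValueError("training set needs at least one row per class")
    clf = spec.build(seed)
    clf.fit(train.X, train.y)
    return clf


def evaluate(model, test: FeatureDataset, labels: Sequence[int] = LEVELS) -> np.ndarray:
    """Confusion matrix on a test set: rows true class, columns predicted."""
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test.X)
    k = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(test.y, pred):
        cm[index[int(t)], index[int(p)]] += 1
    return cm


def metrics(cm: np.ndarray, labels: Sequence[int] = LEVELS) -> dict[str, float]:
    """Overall accuracy and one-vs-rest per-class precision/sensitivity/specificity.

    Undefined ratios (0/0, e.g. sensitivity of a class absent from the test
    set) are reported as NaN, never silently zero.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: float, den: float) -> float:
        return float(num / den) if den > 0 else float("nan")

    out: dict[str, float] = {"accuracy": float(np.trace(cm) / total)}
    for i, lab in enumerate(labels):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        out[f"precision_{lab}"] = ratio(tp, tp + fp)
        out[f"sensitivity_{lab}"] = ratio(tp, tp + fn)
        out[f"specificity_{lab}"] = ratio(tn, tn + fp)
    return out


def repeat_evaluation(
    ds: FeatureDataset,
    spec: ClassifierSpec,
    reps: int = 30,
    train_fraction: float = 0.7,
    master_seed: int = 0,
    per_class: int | str = "min",
    grouping: Grouping = "window",
) -> "TremorLevelResults":
    """Repeated balance -> split -> train -> score cycles with derived seeds.

    Returns a results object holding every per-repetition metric (for
    audit) and their min/mean/max aggregates.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows, cms = [], []
    for rep in range(reps):
        ss = np.random.SeedSequence([int(master_seed), rep])
        s_bal, s_split, s_clf = (int(v % (2**31)) for v in ss.generate_state(3))
        balanced = _dataset.balance_classes(ds, per_class=per_class, seed=s_bal)
        train, test = _dataset.split_train_test(
            balanced, train_fraction=train_fraction, seed=s_split, grouping=grouping
        )
        clf = train_classifier(train, spec, seed=s_clf)
        cm = evaluate(clf, test)
        rows.append({"rep": rep, **metrics(cm)})
        cms.append(cm)
    per_rep = pd.DataFrame(rows).set_index("rep")
    return TremorLevelResults(
        per_rep=per_rep,
        confusion_matrices=cms,
        classifier=spec.name,
        params={
            "reps": reps,
            "train_fraction": train_fraction,
            "master_seed": int(master_seed),
            "per_class": per_class,
            "grouping": grouping,
        },
    )


# ---------------------------------------------------------------------------
# model / results objects


class TremorLevelModel:
    """Three-level tremor classifier over windowed SDH texture features.

    Parameters
    ----------
    dataset:
        A :class:`FeatureDataset` of labeled windows.
    classifier:
        A :class:`BaggedTreesSpec` (default) or :class:`KNNSpec`.
    train_fraction, per_class, grouping:
        Evaluation-protocol knobs: split fraction (default 0.7), balancing
        target (default the smallest class), and whether the split is
        window-level (the study protocol) or recording-level (leakage-safe).
    """

    def __init__(
        self,
        dataset: FeatureDataset,
        classifier: ClassifierSpec | None = None,
        train_fraction: float = 0.7,
        per_class: int | str = "min",
        grouping: Grouping = "window",
    ) -> None:
        self.dataset = dataset
        self.classifier = classifier or BaggedTreesSpec()
        self.train_fraction = train_fraction
        self.per_class = per_class
        self.grouping = grouping

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        feature_names: Sequence[str] | None = None,
        **kwargs,
    ) -> "TremorLevelModel":
        """Build from a prepared frame with level/recording_id/window_index."""
        if feature_names is None:
            feature_names = [
                c for c in frame.columns if c not in _dataset.META_COLUMNS
            ]
        ds = FeatureDataset(frame=frame.copy(), feature_names=list(feature_names))
        return cls(ds, **kwargs)

    @classmethod
    def from_recordings(
        cls,
        recordings: Iterable[Recording],
        channels: str | Sequence[str] = "palm_pos_x",
        features: Sequence[str] | None = ("contrast", "homogeneity"),
        M: int = 1,
        N: int = 149,
        stride: int = 1,
        bin_width: float = 0.1,
        **kwargs,
    ) -> "TremorLevelModel":
        """Extract windowed features from recordings and build the model."""
        ds = assemble_dataset(
            recordings, channels=channels, features=features, M=M, N=N,
            stride=stride, bin_width=bin_width,
        )
        return cls(ds, **kwargs)

    def fit(self, reps: int = 30, seed: int = 0) -> "TremorLevelResults":
        """Run the repeated evaluation protocol and return its results."""
        res = repeat_evaluation(
            self.dataset,
            self.classifier,
            reps=reps,
            train_fraction=self.train_fraction,
            master_seed=seed,
            per_class=self.per_class,
            grouping=self.grouping,
        )
        res.model = self
        return res


@dataclasses.dataclass
class TremorLevelResults:
    """Per-repetition metrics and their min/mean/max aggregates.

    ``per_rep`` has one row per repetition with overall accuracy and
    per-class precision/sensitivity/specificity; :meth:`aggregate` reduces
    each metric to (min, mean, max) in the layout of the study's summary
    tables.
    """

    per_rep: pd.DataFrame
    confusion_matrices: list[np.ndarray]
    classifier: str
    params: Mapping
    model: "TremorLevelModel | None" = None

    def aggregate(self) -> pd.DataFrame:
        agg = self.per_rep.agg(["min", "mean", "max"]).T
        agg.index.name = "metric"
        return agg

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_rep["accuracy"].mean())

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            "Tremor-level classification results",
            f"  classifier: {self.classifier}   repetitions: {self.params['reps']}",
            f"  train fraction: {self.params['train_fraction']}   "
            f"grouping: {self.params['grouping']}   "
            f"balancing: {self.params['per_class']}",
            "",
            agg.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<TremorLevelResults {self.classifier} reps={self.params['reps']} "
            f"mean_accuracy={self.mean_accuracy:.4f}>"
        )
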