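"""Plots of sweep results: accuracy vs window size."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # file output only; no display server assumed
import matplotlib.pyplot as plt

from .experiments import SweepResult


def plot_window_sweep(sweep: SweepResult, metric: str = "accuracy", ax=None):
    """Mean metric vs window size, one line per feature set (min-max band)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    cells = sweep.cells
    for fs, sub in cells.groupby("feature_set"):
        sub = sub.sort_values("window_size")
        ax.plot(sub["window_size"], sub[f"{metric}_mean"], marker="o", label=fs)
        ax.fill_between(
            sub["window_size"], sub[f"{metric}_min"], sub[f"{metric}_max"], alpha=0.2
        )
    ax.set_xlabel("window size N (samples)")
    ax.set_ylabel(f"{metric} (min/mean/max over repetitions)")
    ax.legend(title="feature set")
    ax.set_ylim(0, 1.02)
    return ax


def plot_feature_sweep(sweep: SweepResult, classifier: str, ax=None):
    """Per-feature mean accuracy vs window size for one classifier."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    cells = sweep.cells[sweep.cells["classifier"] == classifier]
    for feat, sub in cells.groupby("feature"):
        sub = sub.sort_values("window_size")
        ax.plot(sub["window_size"], sub["acc_mean"], label=feat)
    ax.set_xlabel("window size N (samples)")
    ax.set_ylabel("mean accuracy")
    ax.set_title(classifier)
    ax.legend(fontsize=7)
    ax.set_ylim(0, 1.02)
    return ax
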