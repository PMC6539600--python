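"""Sum-and-difference-of-histograms (SDH) texture features for 1-D signals.

SDH replaces the gray-level co-occurrence matrix of classical 2-D texture
analysis with two one-dimensional histograms: the distribution of pairwise
sums and of pairwise differences of values at a fixed displacement M. For a
quantized position series V(l), l = 1..n, the vectors

    VS(l) = V(l) + V(l - M),    VD(l) = V(l) - V(l - M),    l = M+1..n

are computed once over the whole series; a sliding window of N consecutive
entries then yields, per window, normalized histograms hS and hD (counts
divided by N, so each sums to one) from which nine texture scalars are
evaluated:

    mu        = 1/2 sum_j j hS(j)
    mean      = mu
    variance  = 1/2 ( sum_j (j - 2 mu)^2 hS(j) + sum_k k^2 hD(k) )
    energy    = ( sum_j hS(j)^2 ) ( sum_k hD(k)^2 )
    correlation = 1/2 ( sum_j (j - 2 mu)^2 hS(j) - sum_k k^2 hD(k) )
    entropy   = - sum_j hS log hS - sum_k hD log hD      (natural log)
    contrast  = sum_k k^2 hD(k)
    homogeneity = sum_k hD(k) / (1 + |k|)    [or 1/(1 + k^2)]
    cluster shade      = sum_j (j - 2 mu)^3 hS(j)
    cluster prominence = sum_j (j - 2 mu)^4 hS(j)

Contrast measures the discontinuity of successive displacements (it grows
with tremor amplitude and frequency) and homogeneity their similarity (it is
1 exactly for a constant signal); these two are the discriminative features
used for tremor-level classification downstream.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import extract_channel
from .schema import Recording

#: Canonical order of the nine texture features.
FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "variance",
    "energy",
    "correlation",
    "entropy",
    "contrast",
    "homogeneity",
    "cluster_shade",
    "cluster_prominence",
)

Kernel = Literal["abs", "squared"]


@dataclasses.dataclass
class QuantizedSignal:
    """Integer-level series with its quantization map: value = offset + k * bin_width."""

    levels: np.ndarray
    offset: float
    bin_width: float

    def dequantize(self) -> np.ndarray:
        return self.offset + self.levels * self.bin_width

    def __len__(self) -> int:
        return len(self.levels)


@dataclasses.dataclass
class SDHPair:
    """Sum and difference vectors at displacement M (length n - M each)."""

    sum_vector: np.ndarray
    diff_vector: np.ndarray
    displacement: int

    def __len__(self) -> int:
        return len(self.sum_vector)


@dataclasses.dataclass
class HistogramPair:
    """Normalized sum and difference histograms for one analysis window."""

    sum_values: np.ndarray    # distinct sum levels j
    sum_masses: np.ndarray    # hS(j), sums to 1
    diff_values: np.ndarray   # distinct difference levels k
    diff_masses: np.ndarray   # hD(k), sums to 1
    window_size: int

    @property
    def sum_hist(self) -> dict[int, float]:
        return dict(zip(self.sum_values.tolist(), self.sum_masses.tolist()))

    @property
    def diff_hist(self) -> dict[int, float]:
        return dict(zip(self.diff_values.tolist(), self.diff_masses.tolist()))


@dataclasses.dataclass
class TextureFeatures:
    mean: float
    variance: float
    energy: float
    correlation: float
    entropy: float
    contrast: float
    homogeneity: float
    cluster_shade: float
    cluster_prominence: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def quantize(signal: Sequence[float] | np.ndarray, bin_width: float = 0.1) -> QuantizedSignal:
    """Quantize a real series (mm) to integer levels of width ``bin_width``.

    The offset is the series minimum, so levels are non-negative and the
    de-quantization error is at most ``bin_width / 2``.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("signal must be non-empty")
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    offset = float(x.min())
    levels = np.rint((x - offset) / bin_width).astype(np.int64)
    return QuantizedSignal(levels=levels, offset=offset, bin_width=float(bin_width))


def sum_diff_vectors(q: QuantizedSignal | np.ndarray, M: int = 1) -> SDHPair:
    """Pairwise sums and differences at displacement M over the full series."""
    levels = q.levels if isinstance(q, QuantizedSignal) else np.asarray(q, dtype=np.int64)
    n = len(levels)
    if not 1 <= M < n:
        raise ValueError(f"displacement M must satisfy 1 <= M < n = {n}, got {M}")
    return SDHPair(
        sum_vector=levels[M:] + levels[:-M],
        diff_vector=levels[M:] - levels[:-M],
        displacement=int(M),
    )


def _normalized_hist(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, counts = np.unique(values, return_counts=True)
    return uniq, counts / len(values)


def window_histograms(
    pair: SDHPair, N: int, stride: int = 1
) -> list[HistogramPair]:
    """Normalized histogram pairs over sliding windows of N entries.

    Windows start at 0, stride, 2*stride, ... while a full window fits:
    floor((len - N) / stride) + 1 of them.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(pair)
    if not 1 <= N <= n:
        raise ValueError(f"window size N must satisfy 1 <= N <= {n}, got {N}")
    out = []
    for start in range(0, n - N + 1, stride):
        sv, sm = _normalized_hist(pair.sum_vector[start : start + N])
        dv, dm = _normalized_hist(pair.diff_vector[start : start + N])
        out.append(
            HistogramPair(
                sum_values=sv, sum_masses=sm, diff_values=dv, diff_masses=dm,
                window_size=N,
            )
        )
    return out


def contrast(h: HistogramPair) -> float:
    """Second moment of the difference histogram: sum_k k^2 hD(k)."""
    return float(np.sum(h.diff_values.astype(float) ** 2 * h.diff_masses))


def homogeneity(h: HistogramPair, kernel: Kernel = "abs") -> float:
    """Inverse-distance-weighted mass of the difference histogram.

    ``abs`` weights by 1/(1+|k|), ``squared`` by 1/(1+k^2); both lie in
    (0, 1] and equal 1 exactly when all mass sits at k = 0.
    """
    k = h.diff_values.astype(float)
    if kernel == "abs":
        w = 1.0 / (1.0 + np.abs(k))
    elif kernel == "squared":
        w = 1.0 / (1.0 + k**2)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return float(np.sum(w * h.diff_masses))


def _xlogx(p: np.ndarray) -> np.ndarray:
    # 0 log 0 := 0
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def texture_features(h: HistogramPair, kernel: Kernel = "abs") -> TextureFeatures:
    """All nine SDH texture scalars for one window's histogram pair."""
    j = h.sum_values.astype(float)
    pj = h.sum_masses
    k = h.diff_values.astype(float)
    pk = h.diff_masses

    mu = 0.5 * float(np.sum(j * pj))
    dev = j - 2.0 * mu
    sum_sq = float(np.sum(dev**2 * pj))
    con = float(np.sum(k**2 * pk))
    return TextureFeatures(
        mean=mu,
        variance=0.5 * (sum_sq + con),
        energy=float(np.sum(pj**2)) * float(np.sum(pk**2)),
        correlation=0.5 * (sum_sq - con),
        entropy=float(-np.sum(_xlogx(pj)) - np.sum(_xlogx(pk))),
        contrast=con,
        homogeneity=homogeneity(h, kernel),
        cluster_shade=float(np.sum(dev**3 * pj)),
        cluster_prominence=float(np.sum(dev**4 * pj)),
    )


def _sliding_features(
    pair: SDHPair, N: int, stride: int, kernel: Kernel
) -> np.ndarray:
    """Vectorized nine-feature table over sliding windows (rows = windows).

    Moment features come from windowed raw moments; energy and entropy need
    the per-window histograms, built with bincount over offset levels.
    """
    vs = pair.sum_vector.astype(float)
    vd = pair.diff_vector.astype(float)
    n = len(pair)
    if not 1 <= N <= n:
        raise ValueError(f"window size N must satisfy 1 <= N <= {n}, got {N}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    vs_w = np.lib.stride_tricks.sliding_window_view(vs, N)[::stride]
    vd_w = np.lib.stride_tricks.sliding_window_view(vd, N)[::stride]
    n_win = vs_w.shape[0]

    es = vs_w.mean(axis=1)                       # E[VS] = 2 mu
    mu = 0.5 * es
    dev = vs_w - es[:, None]
    sum_sq = (dev**2).mean(axis=1)
    con = (vd_w**2).mean(axis=1)
    if kernel == "abs":
        hom = (1.0 / (1.0 + np.abs(vd_w))).mean(axis=1)
    elif kernel == "squared":
        hom = (1.0 / (1.0 + vd_w**2)).mean(axis=1)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    shade = (dev**3).mean(axis=1)
    prom = (dev**4).mean(axis=1)

    energy = np.empty(n_win)
    entropy = np.empty(n_win)
    vs_i = pair.sum_vector
    vd_i = pair.diff_vector
    for i, start in enumerate(range(0, n - N + 1, stride)):
        ws = vs_i[start : start + N]
        wd = vd_i[start : start + N]
        cs = np.bincount(ws - ws.min())
        cd = np.bincount(wd - wd.min())
        ps = cs[cs > 0] / N
        pd_ = cd[cd > 0] / N
        energy[i] = np.sum(ps**2) * np.sum(pd_**2)
        entropy[i] = -np.sum(ps * np.log(ps)) - np.sum(pd_ * np.log(pd_))

    table = np.column_stack(
        [mu, 0.5 * (sum_sq + con), energy, 0.5 * (sum_sq - con), entropy,
         con, hom, shade, prom]
    )
    return table


def features_for_signal(
    signal: np.ndarray,
    M: int = 1,
    N: int = 149,
    stride: int = 1,
    bin_width: float = 0.1,
    kernel: Kernel = "abs",
) -> pd.DataFrame:
    """Windowed nine-feature table for one raw channel series."""
    q = quantize(signal, bin_width)
    pair = sum_diff_vectors(q, M)
    table = _sliding_features(pair, N, stride, kernel)
    return pd.DataFrame(table, columns=list(FEATURE_NAMES))


def features_for_recording(
    rec: Recording,
    channels: str | Sequence[str] = "palm_pos_x",
    M: int = 1,
    N: int = 149,
    stride: int = 1,
    bin_width: float = 0.1,
    kernel: Kernel = "abs",
) -> pd.DataFrame:
    """Windowed texture features for one recording.

    For a single channel the columns are the nine feature names; for a
    channel set, per-channel features are concatenated in requested order as
    ``channel:feature`` — one row per window either way, plus a
    ``window_index`` column. Row count is floor((n - M - N)/stride) + 1.
    """
    single = isinstance(channels, str)
    names = [channels] if single else list(channels)
    if rec.n_samples < N + M:
        raise ValueError(
            f"recording {rec.recording_id} too short: {rec.n_samples} samples "
            f"< N + M = {N + M}"
        )
    blocks = []
    for name in names:
        df = features_for_signal(
            extract_channel(rec, name), M=M, N=N, stride=stride,
            bin_width=bin_width, kernel=kernel,
        )
        if not single:
            df.columns = [f"{name}:{feat}" for feat in FEATURE_NAMES]
        blocks.append(df)
    out = pd.concat(blocks, axis=1)
    out.insert(0, "window_index", np.arange(len(out)))
    return out


def save_feature_table(
    table: pd.DataFrame, path: str | Path, params: Mapping | None = None
) -> Path:
    """Write a feature table as CSV with a JSON sidecar of its parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    if params is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(dict(params), indent=2, default=str))
    return path
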