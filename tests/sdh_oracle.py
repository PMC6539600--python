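"""Brute-force SDH oracle: explicit multisets and term-by-term summation.

Kept deliberately naive and independent of the package's vectorized path:
the sum/difference multisets are built with Python lists, histograms with
collections.Counter, and every feature formula is evaluated by direct
summation over histogram entries.
"""

import math
from collections import Counter


def oracle_sum_diff(levels, M):
    V = [int(v) for v in levels]
    sums = [V[l] + V[l - M] for l in range(M, len(V))]
    diffs = [V[l] - V[l - M] for l in range(M, len(V))]
    return sums, diffs


def oracle_histograms(sums, diffs, start, N):
    hS = {j: c / N for j, c in Counter(sums[start : start + N]).items()}
    hD = {k: c / N for k, c in Counter(diffs[start : start + N]).items()}
    return hS, hD


def oracle_features(levels, M, start, N, kernel="abs"):
    sums, diffs = oracle_sum_diff(levels, M)
    hS, hD = oracle_histograms(sums, diffs, start, N)
    mu = 0.5 * sum(j * p for j, p in hS.items())
    sum_sq = sum((j - 2 * mu) ** 2 * p for j, p in hS.items())
    con = sum(k**2 * p for k, p in hD.items())
    if kernel == "abs":
        hom = sum(p / (1 + abs(k)) for k, p in hD.items())
    else:
        hom = sum(p / (1 + k**2) for k, p in hD.items())
    ent = -sum(p * math.log(p) for p in hS.values() if p > 0)
    ent += -sum(p * math.log(p) for p in hD.values() if p > 0)
    return {
        "mean": mu,
        "variance": 0.5 * (sum_sq + con),
        "energy": sum(p**2 for p in hS.values()) * sum(p**2 for p in hD.values()),
        "correlation": 0.5 * (sum_sq - con),
        "entropy": ent,
        "contrast": con,
        "homogeneity": hom,
        "cluster_shade": sum((j - 2 * mu) ** 3 * p for j, p in hS.items()),
        "cluster_prominence": sum((j - 2 * mu) ** 4 * p for j, p in hS.items()),
    }
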