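"""Independent brute-force oracles used by the test suite.

These deliberately recompute results with the most literal possible code
(python loops, no shared helpers with the package) so they stay independent
of the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def nrmse_bruteforce(complete: np.ndarray, imputed: np.ndarray, mask: np.ndarray) -> float:
    """Literal NRMSE: mean squared error over masked cells / unbiased variance."""
    truth, est = [], []
    for i in range(complete.shape[0]):
        for j in range(complete.shape[1]):
            if mask[i, j]:
                truth.append(complete[i, j])
                est.append(imputed[i, j])
    n = len(truth)
    mse = sum((t - e) ** 2 for t, e in zip(truth, est)) / n
    mean_t = sum(truth) / n
    var = sum((t - mean_t) ** 2 for t in truth) / (n - 1)
    return math.sqrt(mse / var)


def knn_impute_bruteforce(X: np.ndarray, k: int) -> np.ndarray:
    """Feature-space KNN imputation recomputed cell by cell.

    Distance between features j and l: sqrt(mean over mutually observed
    samples of squared difference); inf if no overlap.  For each feature
    with missing cells, the k closest other features (ties by index) vote;
    a missing cell takes the inverse-distance weighted mean of the voters
    observed at that sample, or the feature's observed mean if none is.
    """
    n, p = X.shape
    out = X.copy()

    def dist(j, l):
        acc, cnt = 0.0, 0
        for i in range(n):
            if not math.isnan(X[i, j]) and not math.isnan(X[i, l]):
                acc += (X[i, j] - X[i, l]) ** 2
                cnt += 1
        return math.sqrt(acc / cnt) if cnt else math.inf

    for j in range(p):
        col_missing = [i for i in range(n) if math.isnan(X[i, j])]
        if not col_missing:
            continue
        cand = sorted(
            (l for l in range(p) if l != j and math.isfinite(dist(j, l))),
            key=lambda l: (dist(j, l), l),
        )[:k]
        obs_vals = [X[i, j] for i in range(n) if not math.isnan(X[i, j])]
        col_mean = sum(obs_vals) / len(obs_vals)
        for i in col_missing:
            voters = [l for l in cand if not math.isnan(X[i, l])]
            if not voters:
                out[i, j] = col_mean
                continue
            weights = [1.0 / max(dist(j, l), 1e-12) for l in voters]
            out[i, j] = sum(w * X[i, l] for w, l in zip(weights, voters)) / sum(weights)
    return out


def constant_impute_bruteforce(X: np.ndarray, strategy: str) -> np.ndarray:
    """Per-feature constant fills recomputed with loops."""
    n, p = X.shape
    out = X.copy()
    for j in range(p):
        obs = [X[i, j] for i in range(n) if not math.isnan(X[i, j])]
        if strategy == "zero":
            fill = 0.0
        elif strategy == "mean":
            fill = sum(obs) / len(obs)
        elif strategy == "min":
            fill = min(obs)
        elif strategy == "half_min":
            fill = min(obs) / 2.0
        else:
            raise ValueError(strategy)
        for i in range(n):
            if math.isnan(X[i, j]):
                out[i, j] = fill
    return out


def replay_events(shape, events):
    """Re-apply a mask's events one by one, yielding (event, mask_before)."""
    mask = np.zeros(shape, dtype=bool)
    for ev in events:
        yield ev, mask.copy()
        for i, j in ev.masked_cells:
            assert not mask[i, j], "cell masked twice"
            mask[i, j] = True
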