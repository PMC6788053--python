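"""NRMSE scoring and the permutation benchmark.

One *permutation* of the benchmark: pick one dataset from the pool, select a
fresh random subset of complete features, simulate each missing mechanism at
each rate on that subset, impute every mask with every requested method, and
score each imputation by the normalised root mean squared error

    NRMSE = sqrt( mean((X_comp - X_imp)^2) / var(X_comp) ),

taken over the originally masked cells (every method preserves observed
cells exactly, so including them would only dilute the error), with the
unbiased (n-1) sample variance in the denominator.  NRMSE is 0 for a
perfect imputation and ~1 for one no better than the masked cells' mean.
A per-feature aggregation (NRMSE per incomplete feature, averaged across
features, each feature normalised by its own full-column variance) is
available via ``mode="per_feature"``.

Because all methods in a trial score the same mask, method comparisons are
paired.  Seeds for every trial are derived deterministically from the master
seed, so any single cell of the benchmark grid can be reproduced alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import DatagenConfig, IntensityMatrix, generate_complete_matrix, subsample_features
from .imputers import METHODS, ImputedMatrix, ImputerConfig, impute
from .missingness import (
    MECHANISMS,
    STANDARD_RATES,
    MaskedMatrix,
    MissingnessSpec,
    simulate_missingness,
)

__all__ = [
    "EvaluationError",
    "BenchmarkRecord",
    "BenchmarkConfig",
    "nrmse",
    "run_single_trial",
    "run_benchmark",
    "summarize",
    "heatmap_table",
    "records_to_frame",
    "trial_seed",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "permutation",
    "dataset_id",
    "mechanism",
    "rate",
    "method",
    "nrmse",
    "seed",
    "runtime_s",
    "ok",
    "message",
]


class EvaluationError(ValueError):
    """Raised for undefined evaluations (e.g. an empty mask)."""


def _values(x) -> np.ndarray:
    if isinstance(x, (IntensityMatrix, ImputedMatrix, MaskedMatrix)):
        return x.values
    return np.asarray(x, dtype=float)


def nrmse(complete, imputed, mask: np.ndarray, mode: str = "global") -> float:
    """Normalised root mean squared imputation error over masked cells.

    ``mode="global"`` (default): one ratio over all masked cells, variance
    of the true masked values (ddof=1) in the denominator.
    ``mode="per_feature"``: NRMSE per feature holding missing cells, each
    normalised by that feature's full-column variance, averaged over
    features.
    """
    comp = _values(complete)
    imp = _values(imputed)
    mask = np.asarray(mask, dtype=bool)
    if comp.shape != imp.shape or comp.shape != mask.shape:
        raise EvaluationError("complete, imputed and mask shapes must agree")
    n_masked = int(mask.sum())
    if n_masked < 2:
        raise EvaluationError(
            f"NRMSE needs at least 2 masked cells (got {n_masked})"
        )
    if mode == "global":
        truth = comp[mask]
        err = imp[mask] - truth
        var = float(np.var(truth, ddof=1))
        if var == 0.0:
            raise EvaluationError("masked true values are constant; NRMSE undefined")
        return float(np.sqrt(np.mean(err**2) / var))
    if mode == "per_feature":
        vals = []
        for j in np.flatnonzero(mask.any(axis=0)):
            col_mask = mask[:, j]
            err = imp[col_mask, j] - comp[col_mask, j]
            var = float(np.var(comp[:, j], ddof=1))
            if var == 0.0:
                continue
            vals.append(np.sqrt(np.mean(err**2) / var))
        if not vals:
            raise EvaluationError("no feature with positive variance holds masked cells")
        return float(np.mean(vals))
    raise EvaluationError(f"unknown NRMSE mode {mode!r}")


@dataclass
class BenchmarkRecord:
    """One method's score on one simulated mask."""

    permutation: int
    dataset_id: str
    mechanism: str
    rate: float
    method: str
    nrmse: float
    seed: int
    runtime_s: float
    ok: bool = True
    message: str = ""


def records_to_frame(records: Sequence[BenchmarkRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)


@dataclass
class BenchmarkConfig:
    """Parameters of the full permutation study.

    Defaults mirror the benchmark design: 100 permutations, 200 features
    per trial, all 7 mechanisms, rates 5/10/20/30%, all 9 methods.
    """

    datasets: Sequence[IntensityMatrix | DatagenConfig] = ()
    n_permutations: int = 100
    n_features_per_trial: int = 200
    mechanisms: Sequence[str] = MECHANISMS
    rates: Sequence[float] = STANDARD_RATES
    methods: Sequence[str] = METHODS
    imputer: ImputerConfig = field(default_factory=ImputerConfig)
    master_seed: int = 0
    truncation_side: str = "left"
    nrmse_mode: str = "global"


def trial_seed(master_seed: int, permutation: int, mechanism: str, rate: float) -> int:
    """Deterministic per-trial seed; any grid cell is reproducible alone."""
    mech_idx = MECHANISMS.index(mechanism)
    rate_key = int(round(rate * 10_000))
    ss = np.random.SeedSequence([int(master_seed), int(permutation), mech_idx, rate_key])
    return int(ss.generate_state(1)[0] % (2**31))


def run_single_trial(
    matrix: IntensityMatrix,
    spec: MissingnessSpec,
    methods: Sequence[str] = METHODS,
    config: ImputerConfig | None = None,
    seed: int = 0,
    permutation: int = 0,
    dataset_id: str = "dataset",
    nrmse_mode: str = "global",
) -> list[BenchmarkRecord]:
    """Simulate one mask and score every requested method on it."""
    config = config or ImputerConfig()
    masked = simulate_missingness(matrix, spec, seed)
    records: list[BenchmarkRecord] = []
    for method in methods:
        t0 = time.perf_counter()
        try:
            result = impute(masked, method, config)
            score = nrmse(matrix, result, masked.mask, mode=nrmse_mode)
            records.append(
                BenchmarkRecord(
                    permutation=permutation,
                    dataset_id=dataset_id,
                    mechanism=spec.mechanism,
                    rate=spec.rate,
                    method=method,
                    nrmse=score,
                    seed=seed,
                    runtime_s=time.perf_counter() - t0,
                )
            )
        except Exception as exc:  # noqa: BLE001 - a failed method must not abort the run
            logger.warning(
                "method %s failed on %s@%.2f (seed %d): %s",
                method, spec.mechanism, spec.rate, seed, exc,
            )
            records.append(
                BenchmarkRecord(
                    permutation=permutation,
                    dataset_id=dataset_id,
                    mechanism=spec.mechanism,
                    rate=spec.rate,
                    method=method,
                    nrmse=float("nan"),
                    seed=seed,
                    runtime_s=time.perf_counter() - t0,
                    ok=False,
                    message=str(exc),
                )
            )
    return records


def _materialize_pool(
    datasets: Sequence[IntensityMatrix | DatagenConfig],
) -> list[tuple[str, IntensityMatrix]]:
    pool: list[tuple[str, IntensityMatrix]] = []
    for k, entry in enumerate(datasets):
        if isinstance(entry, DatagenConfig):
            pool.append((f"synthetic-{k}", generate_complete_matrix(entry)))
        else:
            pool.append((f"dataset-{k}", entry))
    return pool


def run_benchmark(config: BenchmarkConfig) -> list[BenchmarkRecord]:
    """Run the full permutation study; returns one record per trial x method."""
    if not config.datasets:
        raise EvaluationError("dataset pool is empty")
    pool = _materialize_pool(config.datasets)
    usable = [
        (did, m) for did, m in pool if m.n_features >= config.n_features_per_trial
    ]
    for did, m in pool:
        if m.n_features < config.n_features_per_trial:
            logger.warning(
                "dataset %s has %d features (< %d requested); skipped",
                did, m.n_features, config.n_features_per_trial,
            )
    if not usable:
        raise EvaluationError(
            "no dataset in the pool has enough complete features"
        )

    records: list[BenchmarkRecord] = []
    for perm in range(config.n_permutations):
        perm_rng = np.random.default_rng(
            np.random.SeedSequence([int(config.master_seed), perm])
        )
        dataset_id, full = usable[int(perm_rng.integers(len(usable)))]
        subset = subsample_features(
            full,
            config.n_features_per_trial,
            seed=int(perm_rng.integers(2**31)),
        )
        for mechanism in config.mechanisms:
            for rate in config.rates:
                spec = MissingnessSpec(mechanism, rate, config.truncation_side)
                seed = trial_seed(config.master_seed, perm, mechanism, rate)
                records.extend(
                    run_single_trial(
                        subset,
                        spec,
                        methods=config.methods,
                        config=config.imputer,
                        seed=seed,
                        permutation=perm,
                        dataset_id=dataset_id,
                        nrmse_mode=config.nrmse_mode,
                    )
                )
    return records


def summarize(records: Sequence[BenchmarkRecord] | pd.DataFrame) -> pd.DataFrame:
    """Mean/sd NRMSE per (method, mechanism, rate), plus pooled-over-rates rows.

    Failed records (``ok == False``) are excluded and their count logged.
    Pooled rows carry ``rate == "all"``.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise EvaluationError("no records to summarize")
    n_failed = int((~frame["ok"]).sum())
    if n_failed:
        logger.info("summarize: excluding %d failed records", n_failed)
    frame = frame[frame["ok"]]
    if frame.empty:
        raise EvaluationError("all records are flagged as failed")

    def _agg(group_cols: list[str]) -> pd.DataFrame:
        g = (
            frame.groupby(group_cols, sort=True)["nrmse"]
            .agg(mean_nrmse="mean", sd_nrmse="std", n_reps="count")
            .reset_index()
        )
        g["sd_nrmse"] = g["sd_nrmse"].fillna(0.0)
        return g

    per_rate = _agg(["method", "mechanism", "rate"])
    pooled = _agg(["method", "mechanism"])
    pooled.insert(2, "rate", "all")
    out = pd.concat([per_rate, pooled], ignore_index=True)
    out["n_reps"] = out["n_reps"].astype(int)
    return out


def heatmap_table(summary: pd.DataFrame, mechanism: str) -> pd.DataFrame:
    """Methods x rates matrix of mean NRMSE for one mechanism."""
    sub = summary[(summary["mechanism"] == mechanism) & (summary["rate"] != "all")]
    if sub.empty:
        raise EvaluationError(f"no summary rows for mechanism {mechanism!r}")
    return sub.pivot(index="method", columns="rate", values="mean_nrmse").sort_index()
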