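"""The nine imputation methods and a uniform dispatcher.

Three method categories:

* single-value replacement -- ``ZERO``, ``MEAN``, ``MIN``, ``HALF_MIN``
  (per-feature constants);
* local structure -- ``KNN`` (feature-space K nearest neighbours, K = 10),
  ``RF`` (missForest-style iterative random forest, 100 trees, up to 10
  sweeps);
* global structure -- ``SVD`` (iterative truncated SVD), ``PPCA``
  (probabilistic PCA by EM), ``BPCA`` (Bayesian PCA with ARD priors).

Every method is a scikit-learn style transformer; :func:`impute` wraps them
behind one call that takes a :class:`~metimpute.missingness.MaskedMatrix`
and returns an :class:`ImputedMatrix` with convergence diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ..missingness import MaskedMatrix
from ._base import (
    BaseMatrixImputer,
    DegenerateFeatureError,
    ImputationError,
    check_matrix,
)
from ._forest import MissForestImputer
from ._knn import FeatureKNNImputer, masked_rms_distance
from ._pca import BPCAImputer, PPCAImputer, SVDImputer
from ._simple import ConstantFillImputer

__all__ = [
    "METHODS",
    "ImputerConfig",
    "ImputedMatrix",
    "ConstantFillImputer",
    "FeatureKNNImputer",
    "MissForestImputer",
    "SVDImputer",
    "PPCAImputer",
    "BPCAImputer",
    "DegenerateFeatureError",
    "ImputationError",
    "BaseMatrixImputer",
    "masked_rms_distance",
    "check_matrix",
    "make_imputer",
    "impute",
    "impute_constant",
    "impute_knn",
    "impute_rf",
    "impute_svd",
    "impute_ppca",
    "impute_bpca",
]

METHODS = ("ZERO", "MEAN", "MIN", "HALF_MIN", "KNN", "RF", "SVD", "PPCA", "BPCA")


@dataclass(frozen=True)
class ImputerConfig:
    """Shared knob set for the nine methods.

    Defaults follow the benchmark's stated settings: K = 10 neighbours,
    100 trees and at most 10 sweeps for the random forest; 5 latent
    components and a 1e-5 relative-change tolerance for the PCA family.
    """

    knn_k: int = 10
    rf_ntree: int = 100
    rf_maxiter: int = 10
    rf_max_features: Any = "sqrt"
    pca_components: int = 5
    tol: float = 1e-5
    max_em_iter: int = 100
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.knn_k < 1 or self.rf_ntree < 1 or self.rf_maxiter < 1:
            raise ValueError("knn_k, rf_ntree and rf_maxiter must be >= 1")
        if self.pca_components < 1:
            raise ValueError("pca_components must be >= 1")
        if self.tol <= 0 or self.max_em_iter < 1:
            raise ValueError("tol must be > 0 and max_em_iter >= 1")


@dataclass
class ImputedMatrix:
    """A fully filled matrix plus method name and fit diagnostics."""

    values: np.ndarray
    method: str
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = True
    criterion: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ImputationError("imputed matrix still contains missing entries")


def make_imputer(method: str, config: ImputerConfig | None = None) -> BaseMatrixImputer:
    """Build the estimator for one of the nine method identifiers."""
    config = config or ImputerConfig()
    method = method.upper()
    if method in ("ZERO", "MEAN", "MIN", "HALF_MIN"):
        return ConstantFillImputer(strategy=method.lower())
    if method == "KNN":
        return FeatureKNNImputer(n_neighbors=config.knn_k)
    if method == "RF":
        return MissForestImputer(
            n_estimators=config.rf_ntree,
            max_iter=config.rf_maxiter,
            max_features=config.rf_max_features,
            random_state=config.seed,
        )
    if method == "SVD":
        return SVDImputer(
            n_components=config.pca_components,
            tol=config.tol,
            max_iter=config.max_em_iter,
        )
    if method == "PPCA":
        return PPCAImputer(
            n_components=config.pca_components,
            tol=config.tol,
            max_iter=config.max_em_iter,
            random_state=config.seed,
        )
    if method == "BPCA":
        return BPCAImputer(
            n_components=config.pca_components,
            tol=config.tol,
            max_iter=config.max_em_iter,
            random_state=config.seed,
        )
    raise ValueError(f"unknown imputation method {method!r}; expected one of {METHODS}")


def _as_nan_matrix(masked: MaskedMatrix | np.ndarray) -> np.ndarray:
    if isinstance(masked, MaskedMatrix):
        return masked.values
    return np.asarray(masked, dtype=float)


def impute(
    masked: MaskedMatrix | np.ndarray,
    method: str,
    config: ImputerConfig | None = None,
) -> ImputedMatrix:
    """Impute a masked matrix with one of the nine methods.

    Observed cells are preserved exactly; the returned object carries the
    method's convergence diagnostics where the method iterates.
    """
    estimator = make_imputer(method, config)
    X = _as_nan_matrix(masked)
    filled = estimator.fit_transform(X)
    sample_ids = list(masked.sample_ids) if isinstance(masked, MaskedMatrix) else []
    feature_ids = list(masked.feature_ids) if isinstance(masked, MaskedMatrix) else []
    return ImputedMatrix(
        values=filled,
        method=method.upper(),
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        iterations_run=int(getattr(estimator, "n_iter_", 0)),
        converged=bool(getattr(estimator, "converged_", True)),
        criterion=float(getattr(estimator, "criterion_", 0.0))
        if math.isfinite(float(getattr(estimator, "criterion_", 0.0)))
        else float("nan"),
    )


def impute_constant(masked, strategy: str, config: ImputerConfig | None = None):
    """Single-value replacement: strategy in {zero, mean, min, half_min}."""
    return impute(masked, strategy.upper(), config)


def impute_knn(masked, config: ImputerConfig | None = None):
    return impute(masked, "KNN", config)


def impute_rf(masked, config: ImputerConfig | None = None):
    return impute(masked, "RF", config)


def impute_svd(masked, config: ImputerConfig | None = None):
    return impute(masked, "SVD", config)


def impute_ppca(masked, config: ImputerConfig | None = None):
    return impute(masked, "PPCA", config)


def impute_bpca(masked, config: ImputerConfig | None = None):
    return impute(masked, "BPCA", config)
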