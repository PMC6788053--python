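"""Shared machinery for the matrix imputers.

All imputers follow the scikit-learn transformer protocol: ``fit(X)`` learns
from a matrix containing NaN at missing cells, ``transform(X)`` returns a
fully filled copy, and ``fit_transform(X)`` runs the method's native
(possibly iterative) algorithm on the fit data.  Every imputer guarantees
that entries observed in the input are returned bit-identical, and that the
output contains no missing entries.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


class DegenerateFeatureError(ValueError):
    """A feature has no observed values, so its statistics are undefined."""


class ImputationError(RuntimeError):
    """Numerical degeneracy during model-based imputation."""


def check_matrix(X) -> np.ndarray:
    """Validate a 2-d float matrix that may contain NaN (= missing)."""
    return check_array(
        X, dtype=np.float64, ensure_all_finite="allow-nan", copy=True
    )


class BaseMatrixImputer(TransformerMixin, BaseEstimator):
    """Base class: validation + observed-cell preservation."""

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = check_matrix(X)
        self.n_features_in_ = X.shape[1]
        filled = self._fit_transform(X)
        return self._finalize(filled, X)

    def transform(self, X):
        check_is_fitted(self)
        X = check_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; imputer was fitted on "
                f"{self.n_features_in_}"
            )
        filled = self._transform(X)
        return self._finalize(filled, X)

    @staticmethod
    def _finalize(filled: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Restore observed cells exactly and verify completeness."""
        observed = ~np.isnan(X)
        filled = np.asarray(filled, dtype=np.float64)
        filled[observed] = X[observed]
        if np.isnan(filled).any():
            raise ImputationError("imputer left missing entries unfilled")
        return filled

    # subclasses implement these on validated arrays
    def _fit_transform(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _transform(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def observed_column_stats(X: np.ndarray):
    """Per-column observed means and minima; errors on all-NaN columns."""
    obs = ~np.isnan(X)
    empty = np.flatnonzero(obs.sum(axis=0) == 0)
    if empty.size:
        raise DegenerateFeatureError(
            f"features with no observed values: {empty.tolist()}"
        )
    with np.errstate(invalid="ignore"):
        means = np.nanmean(X, axis=0)
        mins = np.nanmin(X, axis=0)
    return means, mins
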