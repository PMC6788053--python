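"""Single-value replacement imputers: ZERO, MEAN, MIN, half-MIN.

MEAN, MIN and half-MIN statistics are computed per feature (column-wise),
the convention of left-censoring-aware metabolomics imputation: feature
intensities live on very different scales, so a global minimum would be
meaningless for most features.  Half-minimum targets left-censored data,
approximating values below the detection limit by half the smallest
observed intensity of that feature.
"""

from __future__ import annotations

import numpy as np

from ._base import BaseMatrixImputer, observed_column_stats

STRATEGIES = ("zero", "mean", "min", "half_min")


class ConstantFillImputer(BaseMatrixImputer):
    """Fill each feature's missing cells with one per-feature constant.

    Parameters
    ----------
    strategy : {"zero", "mean", "min", "half_min"}
        Constant used for each feature: 0, the observed mean, the observed
        minimum, or half the observed minimum.

    Attributes
    ----------
    statistics_ : ndarray of shape (n_features,)
        The fill value per feature.
    """

    def __init__(self, strategy: str = "mean"):
        self.strategy = strategy

    def _fill_values(self, X: np.ndarray) -> np.ndarray:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if self.strategy == "zero":
            return np.zeros(X.shape[1])
        means, mins = observed_column_stats(X)
        if self.strategy == "mean":
            return means
        if self.strategy == "min":
            return mins
        return mins / 2.0

    def _fit_transform(self, X: np.ndarray) -> np.ndarray:
        self.statistics_ = self._fill_values(X)
        return self._transform(X)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        filled = X.copy()
        missing = np.isnan(filled)
        filled[missing] = np.broadcast_to(self.statistics_, X.shape)[missing]
        return filled
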