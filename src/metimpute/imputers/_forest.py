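"""missForest-style iterative random-forest imputation.

Missing cells are initialised with the feature's observed mean.  Features
are then visited in order of ascending missingness; each incomplete feature
is regressed on all other features with a random-forest regressor (trained
on the rows where it is observed, using the current imputed values of the
predictors) and its missing cells are overwritten with the forest's
predictions.  Full sweeps repeat until the normalised squared difference
between successive imputations

    crit = sum((X_new - X_old)^2 at imputed cells) / sum(X_new^2 at imputed cells)

first increases, at which point the previous sweep's matrix is returned, or
until ``max_iter`` sweeps have run.  Defaults (10 sweeps, 100 trees, mtry =
floor(sqrt(p)) candidate features per split) follow missForest's.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from ._base import BaseMatrixImputer, observed_column_stats

logger = logging.getLogger(__name__)


class MissForestImputer(BaseMatrixImputer):
    """Iterative random-forest imputer.

    Parameters
    ----------
    n_estimators : int, default 100
        Trees per forest.
    max_iter : int, default 10
        Maximum number of full sweeps over the incomplete features.
    max_features : "sqrt", float or int, default "sqrt"
        Candidate features per split of each tree.
    min_samples_leaf : int, default 5
        Minimum terminal-node size, the regression default of the R
        randomForest stack that missForest wraps.
    random_state : int or None
        Seeds every forest; fixed value gives reproducible imputations.

    Attributes
    ----------
    n_iter_ : int
        Sweeps actually run (including a final non-improving sweep, if any).
    converged_ : bool
        True when the stopping criterion rose before ``max_iter``.
    criterion_ : float
        Normalised squared change of the last accepted sweep.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_iter: int = 10,
        max_features="sqrt",
        min_samples_leaf: int = 5,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def _fit_transform(self, X: np.ndarray) -> np.ndarray:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        n, p = X.shape
        if p < 2:
            raise ValueError("missForest imputation needs at least 2 features")
        missing = np.isnan(X)
        means, _ = observed_column_stats(X)
        self.initial_fill_ = means
        self.n_iter_ = 0
        self.converged_ = False
        self.criterion_ = np.nan
        self.forests_: dict[int, RandomForestRegressor] = {}
        self.visit_order_ = np.array([], dtype=int)
        if not missing.any():
            return X.copy()

        rng = np.random.default_rng(self.random_state)
        filled = X.copy()
        filled[missing] = np.broadcast_to(means, X.shape)[missing]

        miss_counts = missing.sum(axis=0)
        # ascending missingness, ties broken by column index (stable sort)
        order = np.argsort(miss_counts, kind="stable")
        self.visit_order_ = order[miss_counts[order] > 0]

        best = filled.copy()
        best_forests: dict[int, RandomForestRegressor] = {}
        prev_crit = np.inf
        for sweep in range(self.max_iter):
            self.n_iter_ = sweep + 1
            previous = filled.copy()
            sweep_forests: dict[int, RandomForestRegressor] = {}
            for j in self.visit_order_:
                obs_rows = ~missing[:, j]
                predictors = np.delete(filled, j, axis=1)
                forest = RandomForestRegressor(
                    n_estimators=self.n_estimators,
                    max_features=self.max_features,
                    min_samples_leaf=self.min_samples_leaf,
                    random_state=int(rng.integers(2**31 - 1)),
                    n_jobs=1,
                )
                forest.fit(predictors[obs_rows], filled[obs_rows, j])
                filled[missing[:, j], j] = forest.predict(predictors[missing[:, j]])
                sweep_forests[int(j)] = forest
            num = float(np.sum((filled[missing] - previous[missing]) ** 2))
            den = float(np.sum(filled[missing] ** 2))
            crit = num / den if den > 0 else 0.0
            if crit > prev_crit:
                # last sweep degraded the fit: keep the previous sweep
                self.converged_ = True
                break
            best = filled.copy()
            best_forests = sweep_forests
            self.criterion_ = crit
            prev_crit = crit
        if not self.converged_:
            logger.info(
                "missForest: stopping criterion still decreasing after "
                "%d sweeps", self.n_iter_
            )
        self.forests_ = best_forests
        return best

    def _transform(self, X: np.ndarray) -> np.ndarray:
        # single pass with the fitted forests (mean initialisation)
        missing = np.isnan(X)
        filled = X.copy()
        filled[missing] = np.broadcast_to(self.initial_fill_, X.shape)[missing]
        for j in self.visit_order_:
            if int(j) not in self.forests_ or not missing[:, j].any():
                continue
            predictors = np.delete(filled, j, axis=1)
            filled[missing[:, j], j] = self.forests_[int(j)].predict(
                predictors[missing[:, j]]
            )
        return filled
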