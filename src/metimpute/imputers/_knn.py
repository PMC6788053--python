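"""K-nearest-neighbour imputation in feature space.

Follows the expression-matrix KNN-imputation lineage: a feature with missing
cells is imputed from the K most similar *features* (not samples).
Similarity is root-mean-square Euclidean distance computed over the samples
where both features are observed (normalising by the overlap size keeps
distances comparable between pairs with different numbers of mutually
observed samples).  A missing cell is filled with the inverse-distance
weighted average of the neighbour features' values at that sample; neighbours
themselves missing at that sample are skipped.  Sample-space KNN (impute a
sample's missing features from similar samples) is available via
``orientation="samples"``.
"""

from __future__ import annotations

import logging

import numpy as np

from ._base import BaseMatrixImputer, observed_column_stats

logger = logging.getLogger(__name__)

_TINY = 1e-12


def masked_rms_distance(columns: np.ndarray) -> np.ndarray:
    """Pairwise RMS Euclidean distance between columns, NaN-aware.

    ``d[j, k] = sqrt(mean over mutually observed rows of (x_j - x_k)^2)``;
    pairs with no mutually observed rows get ``inf``.
    """
    obs = ~np.isnan(columns)
    Z = np.where(obs, columns, 0.0)
    M = obs.astype(float)
    sq = Z * Z
    counts = M.T @ M
    d2 = sq.T @ M + M.T @ sq - 2.0 * (Z.T @ Z)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_d2 = np.where(counts > 0, d2 / counts, np.inf)
    mean_d2 = np.maximum(mean_d2, 0.0)  # clip tiny negative round-off
    return np.sqrt(mean_d2)


class FeatureKNNImputer(BaseMatrixImputer):
    """Impute each feature from its K most similar features.

    Parameters
    ----------
    n_neighbors : int, default 10
        Number of neighbouring features that vote for each missing cell.
    orientation : {"features", "samples"}, default "features"
        Whether neighbours are features (columns) or samples (rows).

    Attributes
    ----------
    neighbors_ : dict mapping column index -> (neighbor indices, distances)
        Neighbour sets for the columns (rows) that had missing cells at fit.
    n_fallback_cells_ : int
        Cells where no neighbour had an observed value and the per-feature
        observed mean was used instead.
    """

    def __init__(self, n_neighbors: int = 10, orientation: str = "features"):
        self.n_neighbors = n_neighbors
        self.orientation = orientation

    def _check_params(self, X: np.ndarray) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.orientation not in ("features", "samples"):
            raise ValueError("orientation must be 'features' or 'samples'")
        axis_len = X.shape[1] if self.orientation == "features" else X.shape[0]
        if axis_len <= self.n_neighbors:
            raise ValueError(
                f"need more than n_neighbors={self.n_neighbors} "
                f"{self.orientation} (got {axis_len})"
            )

    def _fit_transform(self, X: np.ndarray) -> np.ndarray:
        self._check_params(X)
        A = X if self.orientation == "features" else X.T
        self.distances_ = masked_rms_distance(A)
        self.neighbors_ = {}
        self.n_fallback_cells_ = 0
        filled = self._impute(A)
        return filled if self.orientation == "features" else filled.T

    def _neighbor_set(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        d = self.distances_[:, j].copy()
        d[j] = np.inf  # a column is not its own neighbour
        # stable sort: ties broken by column index, deterministic
        order = np.argsort(d, kind="stable")
        order = order[np.isfinite(d[order])][: self.n_neighbors]
        return order, d[order]

    def _impute(self, A: np.ndarray) -> np.ndarray:
        filled = A.copy()
        means, _ = observed_column_stats(A)
        observed = ~np.isnan(A)
        for j in np.flatnonzero(~observed.all(axis=0)):
            nbrs, dists = self._neighbor_set(j)
            self.neighbors_[int(j)] = (nbrs, dists)
            for i in np.flatnonzero(~observed[:, j]):
                have = observed[i, nbrs]
                if not have.any():
                    filled[i, j] = means[j]
                    self.n_fallback_cells_ += 1
                    continue
                w = 1.0 / np.maximum(dists[have], _TINY)
                filled[i, j] = float(np.sum(w * A[i, nbrs[have]]) / np.sum(w))
        if self.n_fallback_cells_:
            logger.info(
                "KNN: %d cells had no observed neighbour value; used the "
                "feature's observed mean",
                self.n_fallback_cells_,
            )
        return filled

    def _transform(self, X: np.ndarray) -> np.ndarray:
        # one pass with the fitted neighbour geometry applied to X's own values
        A = X if self.orientation == "features" else X.T
        filled = A.copy()
        means, _ = observed_column_stats(A)
        observed = ~np.isnan(A)
        for j in np.flatnonzero(~observed.all(axis=0)):
            if int(j) in self.neighbors_:
                nbrs, dists = self.neighbors_[int(j)]
            else:
                nbrs, dists = self._neighbor_set(j)
            for i in np.flatnonzero(~observed[:, j]):
                have = observed[i, nbrs]
                if not have.any():
                    filled[i, j] = means[j]
                    continue
                w = 1.0 / np.maximum(dists[have], _TINY)
                filled[i, j] = float(np.sum(w * A[i, nbrs[have]]) / np.sum(w))
        return filled if self.orientation == "features" else filled.T
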