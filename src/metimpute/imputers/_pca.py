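"""Global-structure imputers: iterative SVD, probabilistic PCA, Bayesian PCA.

All three model the intensity matrix as approximately low-rank and fill
missing cells with a rank-r reconstruction; they differ in how the low-rank
fit is estimated:

* **SVDImputer** -- classic SVDimpute: missing cells start at zero, then the
  matrix is repeatedly truncated to rank r by SVD and the missing cells are
  overwritten with the reconstruction, until the imputed values stop
  changing.  The decomposition is applied to the raw (uncentred) matrix, so
  the zero initialisation genuinely biases the early factorisations -- the
  known weakness of this method on positive intensity data.
* **PPCAImputer** -- probabilistic PCA, x = W z + mu + eps with isotropic
  Gaussian residual, fitted by EM.  Missing cells are treated as latent: at
  every iteration they are replaced by their conditional mean under the
  current model, and at convergence those conditional means are the
  imputations.  With complete data the maximum-likelihood W spans the same
  subspace as the leading principal components.
* **BPCAImputer** -- PPCA with automatic-relevance-determination (ARD)
  priors on the loading columns.  Each column j carries a precision alpha_j
  re-estimated as p / ||w_j||^2 every iteration; columns that do not help
  explain the data have their norm driven towards zero, so the effective
  rank can shrink below ``n_components``.

The PPCA/BPCA EM loops operate on column-centred data internally (the mean
is a model parameter) and add the centre back; no other preprocessing (no
log transform, no scaling) is applied by any of the three.
"""

from __future__ import annotations

import logging

import numpy as np

from ._base import BaseMatrixImputer, ImputationError

logger = logging.getLogger(__name__)


def _relative_change(new: np.ndarray, old: np.ndarray) -> float:
    denom = float(np.linalg.norm(new))
    if denom == 0.0:
        return float(np.linalg.norm(new - old))
    return float(np.linalg.norm(new - old) / denom)


class SVDImputer(BaseMatrixImputer):
    """Iterative truncated-SVD imputation (SVDimpute).

    Parameters
    ----------
    n_components : int, default 5
        Rank r of the truncated decomposition.
    tol : float, default 1e-5
        Relative change of the imputed values below which iteration stops.
    max_iter : int, default 100

    Attributes
    ----------
    n_iter_, converged_, criterion_ : fit diagnostics
    components_, singular_values_ : the final rank-r fit
    """

    def __init__(self, n_components: int = 5, tol: float = 1e-5, max_iter: int = 100):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def _check(self, X: np.ndarray) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_components >= min(X.shape):
            raise ValueError(
                f"n_components={self.n_components} must be < min(n_samples, "
                f"n_features) = {min(X.shape)}"
            )
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def _rank_r(self, filled: np.ndarray):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        r = self.n_components
        recon = (U[:, :r] * s[:r]) @ Vt[:r]
        return recon, s[:r], Vt[:r]

    def _fit_transform(self, X: np.ndarray) -> np.ndarray:
        self._check(X)
        missing = np.isnan(X)
        filled = X.copy()
        self.n_iter_ = 0
        self.converged_ = True
        self.criterion_ = 0.0
        if not missing.any():
            _, self.singular_values_, self.components_ = self._rank_r(filled)
            return filled

        filled[missing] = 0.0
        self.converged_ = False
        current = filled[missing]
        for it in range(self.max_iter):
            self.n_iter_ = it + 1
            recon, s, Vt = self._rank_r(filled)
            new = recon[missing]
            self.criterion_ = _relative_change(new, current)
            filled[missing] = new
            current = new
            if self.criterion_ < self.tol:
                self.converged_ = True
                break
        if not self.converged_:
            logger.info(
                "SVD imputation did not converge in %d iterations "
                "(criterion %.2e)", self.max_iter, self.criterion_
            )
        self.singular_values_, self.components_ = s, Vt
        return filled

    def _transform(self, X: np.ndarray) -> np.ndarray:
        # project each incomplete row's observed part onto the fitted basis
        filled = X.copy()
        V = self.components_  # (r, p)
        for i in np.flatnonzero(np.isnan(X).any(axis=1)):
            mis = np.isnan(X[i])
            obs = ~mis
            z, *_ = np.linalg.lstsq(V[:, obs].T, X[i, obs], rcond=None)
            filled[i, mis] = z @ V[:, mis]
        return filled


class _EMPCABase(BaseMatrixImputer):
    """Shared EM loop for PPCA and BPCA imputation."""

    def __init__(
        self,
        n_components: int = 5,
        tol: float = 1e-5,
        max_iter: int = 100,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # BPCA overrides this to add the ARD penalty
    def _update_W(self, XtEz: np.ndarray, sum_Ezz: np.ndarray, sigma2: float):
        return np.linalg.solve(sum_Ezz.T, XtEz.T).T, None

    def _fit_transform(self, X: np.ndarray) -> np.ndarray:
        n, p = X.shape
        r = self.n_components
        if not (1 <= r < p):
            raise ValueError(f"n_components must satisfy 1 <= r < n_features={p}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        missing = np.isnan(X)
        filled = X.copy()
        obs_counts = (~missing).sum(axis=0)
        if (obs_counts == 0).any():
            raise ImputationError("a feature has no observed values")
        obs_means = np.where(missing, 0.0, X).sum(axis=0) / obs_counts
        filled[missing] = np.broadcast_to(obs_means, X.shape)[missing]

        rng = np.random.default_rng(self.random_state)
        mu = filled.mean(axis=0)
        Xc = filled - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        W = Vt[:r].T * (s[:r] / np.sqrt(n))
        # seeded jitter so EM does not start exactly on an SVD saddle
        W = W + rng.normal(0.0, 1e-3 * (np.abs(W).mean() + 1e-30), size=W.shape)
        total_var = float(np.sum(Xc**2)) / (n * p)
        resid = float(np.sum(s[r:] ** 2)) / (n * p) if p > r else 1e-6 * total_var
        sigma2 = max(resid, 1e-12 * max(total_var, 1.0))

        self.n_iter_ = 0
        self.converged_ = False
        self.criterion_ = np.nan
        had_missing = bool(missing.any())
        floor = 1e-12 * max(total_var, 1.0)
        for it in range(self.max_iter):
            self.n_iter_ = it + 1
            mu = filled.mean(axis=0)
            Xc = filled - mu
            M = W.T @ W + sigma2 * np.eye(r)
            Minv = np.linalg.inv(M)
            Ez = Xc @ W @ Minv                      # (n, r)
            sum_Ezz = n * sigma2 * Minv + Ez.T @ Ez  # (r, r)
            XtEz = Xc.T @ Ez                        # (p, r)
            W_new, alpha = self._update_W(XtEz, sum_Ezz, sigma2)
            sigma2_new = (
                float(np.sum(Xc**2))
                - 2.0 * float(np.sum((Xc @ W_new) * Ez))
                + float(np.trace(sum_Ezz @ (W_new.T @ W_new)))
            ) / (n * p)
            sigma2_new = max(sigma2_new, floor)
            if not np.isfinite(sigma2_new) or not np.all(np.isfinite(W_new)):
                raise ImputationError("EM diverged: non-finite parameters")

            if had_missing:
                recon = mu + Ez @ W_new.T
                new_vals = recon[missing]
                self.criterion_ = _relative_change(new_vals, filled[missing])
                filled[missing] = new_vals
            else:
                self.criterion_ = _relative_change(W_new, W)
            W, sigma2 = W_new, sigma2_new
            if self.criterion_ < self.tol:
                self.converged_ = True
                break
        if not self.converged_:
            logger.info(
                "%s did not converge in %d iterations (criterion %.2e)",
                type(self).__name__, self.max_iter, self.criterion_,
            )
        self.mean_ = filled.mean(axis=0)
        self.components_ = W.T  # (r, p)
        self.noise_variance_ = sigma2
        if alpha is not None:
            self.alpha_ = alpha
        return filled

    def _transform(self, X: np.ndarray) -> np.ndarray:
        W = self.components_.T  # (p, r)
        r = W.shape[1]
        filled = X.copy()
        for i in np.flatnonzero(np.isnan(X).any(axis=1)):
            mis = np.isnan(X[i])
            obs = ~mis
            Wo = W[obs]
            M = Wo.T @ Wo + self.noise_variance_ * np.eye(r)
            Ez = np.linalg.solve(M, Wo.T @ (X[i, obs] - self.mean_[obs]))
            filled[i, mis] = self.mean_[mis] + W[mis] @ Ez
        return filled


class PPCAImputer(_EMPCABase):
    """Probabilistic-PCA imputation fitted by EM.

    Attributes
    ----------
    components_ : ndarray (n_components, n_features)
        Fitted loading matrix W (transposed).
    noise_variance_ : float
        Isotropic residual variance sigma^2.
    n_iter_, converged_, criterion_ : fit diagnostics
    """


class BPCAImputer(_EMPCABase):
    """Bayesian-PCA imputation with ARD priors on the loading columns.

    Attributes
    ----------
    alpha_ : ndarray (n_components,)
        ARD precisions; large alpha marks a pruned (irrelevant) component.
    effective_rank_ : int
        Loading columns whose norm exceeds 1% of the largest column norm.
    """

    _ALPHA_CAP = 1e20

    def _update_W(self, XtEz: np.ndarray, sum_Ezz: np.ndarray, sigma2: float):
        p = XtEz.shape[0]
        if not hasattr(self, "_alpha"):
            self._alpha = np.zeros(XtEz.shape[1])
        A = sum_Ezz + sigma2 * np.diag(self._alpha)
        W_new = np.linalg.solve(A.T, XtEz.T).T
        norms2 = np.sum(W_new**2, axis=0)
        scale = max(norms2.max(), 1e-300)
        self._alpha = np.minimum(p / (norms2 + 1e-12 * scale), self._ALPHA_CAP)
        return W_new, self._alpha.copy()

    def _fit_transform(self, X: np.ndarray) -> np.ndarray:
        if hasattr(self, "_alpha"):
            del self._alpha
        filled = super()._fit_transform(X)
        norms = np.linalg.norm(self.components_, axis=1)
        self.effective_rank_ = int(np.sum(norms > 0.01 * norms.max()))
        return filled
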