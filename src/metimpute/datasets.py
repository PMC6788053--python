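"""Synthetic LC-MS-like intensity matrices.

Non-targeted LC-MS metabolite profiling yields a samples x features table of
strictly positive, strongly right-skewed peak intensities in which groups of
molecular features (isotopes, adducts, members of the same metabolic pathway)
are highly correlated.  The generator here emulates exactly those three
properties -- positivity, skew, and low-rank inter-feature correlation -- with
a log-scale latent factor model

    log x_ij = mu_j + a_j * f_{g(j), i} + eps_ij,

where each feature j is assigned to one of ``latent_rank`` latent factors
g(j), f ~ N(0, 1) are per-sample factor scores, a_j is the feature's loading
(its log-scale biological spread) and eps is analytical noise.  Exponentiation
makes every feature log-normal, hence positive and right-skewed, and features
sharing a factor are strongly correlated -- the structure that feature-wise
imputation methods exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "DatagenConfig",
    "generate_complete_matrix",
    "subsample_features",
]


class ConfigurationError(ValueError):
    """Raised for invalid data-generation parameters."""


@dataclass
class IntensityMatrix:
    """Complete samples x features table of positive abundances.

    Invariants enforced on construction: all values finite and strictly
    positive, no missing entries, id lists matching the matrix dimensions.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("values must be a 2-d matrix")
        n, p = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"F{j:04d}" for j in range(p)]
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ConfigurationError("id lists do not match matrix dimensions")
        if len(set(self.sample_ids)) != n or len(set(self.feature_ids)) != p:
            raise ConfigurationError("sample/feature ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("matrix contains non-finite entries")
        if not np.all(self.values > 0):
            raise ConfigurationError("intensities must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IntensityMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=[str(i) for i in frame.index],
            feature_ids=[str(c) for c in frame.columns],
        )


@dataclass(frozen=True)
class DatagenConfig:
    """Parameters of the log-scale factor model.

    Defaults emulate one per-trial subset of a human plasma LC-MS feature
    table: 100 samples, 200 features, five correlated feature blocks,
    baseline log-intensity around 12 (raw intensities ~1.6e5), per-feature
    biological log-spread around 1 and ~30% analytical noise.
    """

    n_samples: int = 100
    n_features: int = 200
    latent_rank: int = 5
    noise_sd: float = 0.3
    mean_log: float = 12.0
    sd_log: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise ConfigurationError("matrix dimensions must be positive")
        if not (0 < self.latent_rank < min(self.n_samples, self.n_features)):
            raise ConfigurationError(
                "latent_rank must satisfy 0 < latent_rank < min(n_samples, n_features)"
            )
        if self.noise_sd <= 0 or self.sd_log <= 0:
            raise ConfigurationError("noise_sd and sd_log must be positive")


def generate_complete_matrix(config: DatagenConfig) -> IntensityMatrix:
    """Draw one complete intensity matrix from the latent factor model.

    Deterministic for a fixed ``config.seed``.  Feature j loads on factor
    ``j % latent_rank`` with loading ``a_j ~ U(0.5, 1.5) * sd_log``; feature
    baselines are spread with unit log-sd around ``mean_log``.
    """
    rng = np.random.default_rng(config.seed)
    n, p, r = config.n_samples, config.n_features, config.latent_rank

    factor_of = np.arange(p) % r
    loadings = rng.uniform(0.5, 1.5, size=p) * config.sd_log
    baselines = rng.normal(config.mean_log, 1.0, size=p)
    scores = rng.normal(size=(n, r))
    noise = rng.normal(0.0, config.noise_sd, size=(n, p))

    log_x = baselines[None, :] + scores[:, factor_of] * loadings[None, :] + noise
    return IntensityMatrix(values=np.exp(log_x))


def subsample_features(
    matrix: IntensityMatrix, n_select: int, seed: int
) -> IntensityMatrix:
    """Restrict to ``n_select`` features drawn uniformly without replacement.

    The sample set is unchanged and selected columns are copied verbatim.
    """
    if n_select > matrix.n_features:
        raise ConfigurationError(
            f"cannot select {n_select} features from {matrix.n_features}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(matrix.n_features, size=n_select, replace=False)
    return IntensityMatrix(
        values=matrix.values[:, idx].copy(),
        sample_ids=list(matrix.sample_ids),
        feature_ids=[matrix.feature_ids[j] for j in idx],
    )
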