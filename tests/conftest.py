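import numpy as np
import pytest

from metimpute import (
    DatagenConfig,
    IntensityMatrix,
    MissingnessSpec,
    generate_complete_matrix,
    simulate_missingness,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_matrix() -> IntensityMatrix:
    """Deterministic 12x8 positive matrix with two correlated feature blocks."""
    cfg = DatagenConfig(
        n_samples=12, n_features=8, latent_rank=2, noise_sd=0.2, seed=7
    )
    return generate_complete_matrix(cfg)


@pytest.fixture(scope="session")
def structured_matrix() -> IntensityMatrix:
    """60x20 rank-2 matrix with low noise: clear structure for model imputers."""
    cfg = DatagenConfig(
        n_samples=60, n_features=20, latent_rank=2, noise_sd=0.1,
        sd_log=0.8, seed=11,
    )
    return generate_complete_matrix(cfg)


@pytest.fixture()
def mcar_masked(structured_matrix):
    """10% MCAR mask on the structured matrix."""
    return simulate_missingness(
        structured_matrix, MissingnessSpec("MCAR", 0.10), seed=5
    )
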