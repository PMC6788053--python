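"""The nine imputers: arithmetic oracles, contracts, model properties."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from metimpute import (
    METHODS,
    BPCAImputer,
    ConstantFillImputer,
    DatagenConfig,
    FeatureKNNImputer,
    ImputerConfig,
    MissForestImputer,
    MissingnessSpec,
    PPCAImputer,
    SVDImputer,
    generate_complete_matrix,
    impute,
    make_imputer,
    nrmse,
    simulate_missingness,
)
from metimpute.imputers import DegenerateFeatureError

from .oracles import constant_impute_bruteforce, knn_impute_bruteforce

CHEAP = ImputerConfig(knn_k=3, rf_ntree=5, rf_maxiter=2, pca_components=2, max_em_iter=5)


def _mask_random(values, frac, seed):
    rng = np.random.default_rng(seed)
    X = values.copy()
    idx = rng.choice(X.size, size=max(2, int(frac * X.size)), replace=False)
    X.ravel()[idx] = np.nan
    # keep at least one observed value per column
    for j in range(X.shape[1]):
        if np.isnan(X[:, j]).all():
            X[0, j] = values[0, j]
    return X


class TestConstantFill:
    @pytest.mark.parametrize(
        "strategy,expected", [("zero", 0.0), ("mean", 2.0), ("min", 1.0), ("half_min", 0.5)]
    )
    def test_column_arithmetic(self, strategy, expected):
        X = np.array([[1.0, 9.0], [np.nan, 9.0], [3.0, 9.0]])
        out = ConstantFillImputer(strategy=strategy).fit_transform(X)
        assert out[1, 0] == pytest.approx(expected)
        assert np.array_equal(out[:, 1], X[:, 1])

    @pytest.mark.parametrize("strategy", ["zero", "mean", "min", "half_min"])
    def test_matches_bruteforce(self, strategy, small_matrix):
        X = _mask_random(small_matrix.values, 0.2, seed=4)
        out = ConstantFillImputer(strategy=strategy).fit_transform(X)
        assert np.allclose(out, constant_impute_bruteforce(X, strategy))

    @pytest.mark.parametrize("strategy", ["mean", "min", "half_min"])
    def test_fully_missing_feature_rejected(self, strategy):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(DegenerateFeatureError, match="1"):
            ConstantFillImputer(strategy=strategy).fit_transform(X)

    def test_zero_tolerates_fully_missing_feature(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        out = ConstantFillImputer(strategy="zero").fit_transform(X)
        assert np.array_equal(out[:, 1], [0.0, 0.0])


class TestKNN:
    def test_matches_bruteforce_on_single_missing_cell(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(10, 2, (6, 4))) + 0.1
        X[3, 1] = np.nan
        out = FeatureKNNImputer(n_neighbors=2).fit_transform(X)
        assert np.allclose(out, knn_impute_bruteforce(X, k=2), rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_small_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(5, 9)), int(rng.integers(4, 9))
        X = np.abs(rng.normal(10, 3, (n, p))) + 0.1
        X = _mask_random(X, 0.15, seed=seed + 100)
        k = int(rng.integers(1, p - 1))
        out = FeatureKNNImputer(n_neighbors=k).fit_transform(X)
        assert np.allclose(out, knn_impute_bruteforce(X, k=k), rtol=1e-10)

    def test_unanimous_duplicate_neighbours_reproduce_value(self):
        rng = np.random.default_rng(3)
        base = np.abs(rng.normal(10, 2, 8)) + 0.1
        X = np.column_stack([base] * 4 + [np.abs(rng.normal(100, 5, 8))])
        X[2, 0] = np.nan
        out = FeatureKNNImputer(n_neighbors=3).fit_transform(X)
        assert out[2, 0] == pytest.approx(base[2])

    def test_requires_more_features_than_neighbours(self):
        X = np.ones((5, 3))
        with pytest.raises(ValueError, match="n_neighbors"):
            FeatureKNNImputer(n_neighbors=3).fit_transform(X)

    def test_sample_orientation_runs(self, small_matrix):
        X = _mask_random(small_matrix.values, 0.1, seed=0)
        out = FeatureKNNImputer(n_neighbors=3, orientation="samples").fit_transform(X)
        assert not np.isnan(out).any()


class TestSVD:
    def test_recovers_rank_one_matrix(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, np.nan]])
        est = SVDImputer(n_components=1, tol=1e-9, max_iter=500)
        out = est.fit_transform(X)
        assert out[1, 2] == pytest.approx(6.0, rel=1e-6)
        assert est.converged_

    def test_first_iteration_is_reconstruction_of_zero_fill(self, small_matrix):
        X = _mask_random(small_matrix.values, 0.15, seed=1)
        missing = np.isnan(X)
        zero_filled = np.where(missing, 0.0, X)
        U, s, Vt = np.linalg.svd(zero_filled, full_matrices=False)
        expected = ((U[:, :2] * s[:2]) @ Vt[:2])[missing]
        out = SVDImputer(n_components=2, max_iter=1).fit_transform(X)
        assert np.allclose(out[missing], expected)

    def test_no_missing_is_identity_with_zero_iterations(self, small_matrix):
        est = SVDImputer(n_components=2)
        out = est.fit_transform(small_matrix.values)
        assert np.array_equal(out, small_matrix.values)
        assert est.n_iter_ == 0

    def test_component_bound_enforced(self):
        with pytest.raises(ValueError, match="n_components"):
            SVDImputer(n_components=3).fit_transform(np.ones((3, 5)))


class TestPPCA:
    def test_complete_data_subspace_matches_pca(self, structured_matrix):
        X = structured_matrix.values
        est = PPCAImputer(n_components=2, tol=1e-9, max_iter=2000, random_state=0)
        est.fit(X)
        _, _, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
        angles = subspace_angles(est.components_.T, Vt[:2].T)
        assert angles.max() < 1e-3

    def test_beats_mean_on_structured_mcar(self, structured_matrix, mcar_masked):
        cfg = ImputerConfig(pca_components=2)
        ppca = impute(mcar_masked, "PPCA", cfg)
        mean = impute(mcar_masked, "MEAN", cfg)
        assert nrmse(structured_matrix, ppca, mcar_masked.mask) < nrmse(
            structured_matrix, mean, mcar_masked.mask
        )

    def test_seed_determinism(self, mcar_masked):
        a = impute(mcar_masked, "PPCA", ImputerConfig(seed=3, pca_components=2))
        b = impute(mcar_masked, "PPCA", ImputerConfig(seed=3, pca_components=2))
        assert np.array_equal(a.values, b.values)


def _gaussian_rank2(n=60, p=20, noise=0.3, seed=0):
    """Rank-2 factor matrix with small isotropic noise: the regime where the
    ARD rank-recovery property is well defined."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n, 2))
    loadings = rng.normal(size=(2, p)) * 3.0
    return scores @ loadings + rng.normal(0, noise, (n, p))


class TestBPCA:
    def test_ard_prunes_superfluous_components(self):
        """Rank-2 data + small isotropic noise fitted with 8 components:
        at least one loading column collapses below 1% of the largest."""
        X = _mask_random(_gaussian_rank2(), 0.05, seed=2)
        est = BPCAImputer(n_components=8, tol=1e-8, max_iter=500, random_state=0)
        est.fit(X)
        norms = np.linalg.norm(est.components_, axis=1)
        assert norms.min() < 0.01 * norms.max()
        assert est.effective_rank_ < 8

    def test_beats_mean_on_structured_mcar(self, structured_matrix, mcar_masked):
        cfg = ImputerConfig(pca_components=4)
        bpca = impute(mcar_masked, "BPCA", cfg)
        mean = impute(mcar_masked, "MEAN", cfg)
        assert nrmse(structured_matrix, bpca, mcar_masked.mask) < nrmse(
            structured_matrix, mean, mcar_masked.mask
        )


class TestMissForest:
    def test_learns_duplicate_feature_map(self):
        """With an exact duplicate column available, imputed cells track the
        duplicate within 5% relative error averaged over 10 seeds.  Trees are
        grown to single-sample leaves over all predictors so the forest can
        actually memorise the identity map; leaf averaging with the default
        node size would cap the achievable precision, not the forest's
        ability to find the duplicate."""
        rng = np.random.default_rng(5)
        base = generate_complete_matrix(
            DatagenConfig(n_samples=120, n_features=8, latent_rank=2,
                          noise_sd=0.15, sd_log=0.5, seed=21)
        ).values
        base[:, 1] = base[:, 0]
        errors = []
        for seed in range(10):
            X = base.copy()
            miss = rng.choice(120, size=12, replace=False)
            X[miss, 0] = np.nan
            out = MissForestImputer(
                n_estimators=100, min_samples_leaf=1, max_features=1.0,
                random_state=seed,
            ).fit_transform(X)
            errors.append(np.mean(np.abs(out[miss, 0] - base[miss, 1]) / base[miss, 1]))
        assert np.mean(errors) < 0.05

    def test_no_missing_is_identity_with_zero_sweeps(self, small_matrix):
        est = MissForestImputer(n_estimators=5)
        out = est.fit_transform(small_matrix.values)
        assert np.array_equal(out, small_matrix.values)
        assert est.n_iter_ == 0

    def test_seed_determinism(self, small_matrix):
        X = _mask_random(small_matrix.values, 0.1, seed=6)
        a = MissForestImputer(n_estimators=10, random_state=1).fit_transform(X)
        b = MissForestImputer(n_estimators=10, random_state=1).fit_transform(X)
        assert np.array_equal(a, b)

    def test_invalid_iterations_rejected(self, small_matrix):
        X = _mask_random(small_matrix.values, 0.1, seed=0)
        with pytest.raises(ValueError, match="max_iter"):
            MissForestImputer(max_iter=0).fit_transform(X)


class TestDispatcher:
    def test_unknown_method_rejected(self, mcar_masked):
        with pytest.raises(ValueError, match="unknown imputation method"):
            impute(mcar_masked, "MAGIC")

    def test_zero_method_fills_zeros(self, mcar_masked):
        out = impute(mcar_masked, "ZERO")
        assert np.all(out.values[mcar_masked.mask] == 0.0)

    @pytest.mark.parametrize("method", METHODS)
    def test_contract_sweep_observed_cells_and_completeness(self, method, small_matrix):
        masked = simulate_missingness(small_matrix, MissingnessSpec("MCAR", 0.2), 13)
        out = impute(masked, method, CHEAP)
        obs = ~masked.mask
        assert np.array_equal(out.values[obs], small_matrix.values[obs])
        assert not np.isnan(out.values).any()
        assert out.method == method

    def test_paper_stated_defaults(self):
        cfg = ImputerConfig()
        assert (cfg.knn_k, cfg.rf_ntree, cfg.rf_maxiter) == (10, 100, 10)
        knn = make_imputer("KNN")
        rf = make_imputer("RF")
        assert knn.n_neighbors == 10
        assert (rf.n_estimators, rf.max_iter) == (100, 10)

    def test_transform_after_fit_fills_new_mask(self, structured_matrix):
        """sklearn protocol: fit on one mask, transform another."""
        X_fit = _mask_random(structured_matrix.values, 0.1, seed=1)
        X_new = _mask_random(structured_matrix.values, 0.1, seed=2)
        for est in (
            ConstantFillImputer("mean"),
            FeatureKNNImputer(n_neighbors=3),
            SVDImputer(n_components=2),
            PPCAImputer(n_components=2, random_state=0),
            MissForestImputer(n_estimators=5, random_state=0),
        ):
            est.fit(X_fit)
            out = est.transform(X_new)
            obs = ~np.isnan(X_new)
            assert np.array_equal(out[obs], X_new[obs])
            assert not np.isnan(out).any()
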