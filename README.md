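# metimpute

Missing-value simulation and imputation benchmarking for LC-MS metabolomics
intensity matrices.

Non-targeted LC-MS metabolite profiling produces samples × features tables
of positive, right-skewed peak intensities in which 30–50% of cells can be
missing — because a metabolite is truly absent, because it fell below the
instrument's detection limit, or because peak picking failed.  Downstream
statistics need a complete matrix, so the missing cells must be imputed,
and the right imputation method depends on *why* the values are missing.
`metimpute` lets you study that question systematically: it simulates the
three canonical missingness mechanisms and their combinations on complete
matrices where the ground truth is known, imputes the masked cells with
nine standard methods, and scores every method by normalised error over
repeated permutations.

## What it implements

**Missingness mechanisms** (7): `MCAR` (cells removed uniformly at random),
`MAR` (high abundance of a driver feature X₁ masks a second feature X₂ in
the same sample), `MNAR` (left truncation: a feature's smallest values fall
below an effective detection limit), and the sequential combinations
`MCAR_MAR`, `MCAR_MNAR`, `MAR_MNAR`, `MCAR_MAR_MNAR`, which split the total
rate equally among their components.  MAR/MNAR event sizes are drawn from
χ²(1)/30 clipped to [0, 1] (mean ≈ 3.3%, sd ≈ 4.7%), and events repeat
until the requested fraction of cells — exactly `round(rate × cells)` — is
masked.  Every masked cell carries event provenance.

**Imputation methods** (9), as scikit-learn style transformers:

| category | methods |
| --- | --- |
| single-value replacement | `ZERO`, `MEAN`, `MIN`, `HALF_MIN` (per feature) |
| local structure | `KNN` (feature-space, K = 10), `RF` (missForest-style iterative random forest, 100 trees, ≤ 10 sweeps) |
| global structure | `SVD` (iterative truncated SVD from zero fill), `PPCA` (probabilistic PCA by EM), `BPCA` (Bayesian PCA with ARD priors) |

**Evaluation**: for a mask M on a complete matrix X with imputation X̂,

    NRMSE = sqrt( mean_{(i,j)∈M} (X_ij − X̂_ij)² / var_{(i,j)∈M}(X_ij) )

(0 = perfect, ≈ 1 = no better than the masked cells' mean; unbiased
variance).  A per-feature aggregation — NRMSE per incomplete feature,
averaged over features — is available via `mode="per_feature"`.  The
benchmark repeats, per permutation: draw a dataset from a pool, subsample
complete features, simulate every mechanism × rate, impute each mask with
every method, and score; all methods in a trial share the identical mask,
so comparisons are paired.

**Synthetic data**: the bundled generator emulates LC-MS feature tables
with a log-scale latent factor model (exponentiated), giving positive,
right-skewed intensities with low-rank inter-feature correlation.

## Worked example

```python
import metimpute as mi

matrix = mi.generate_complete_matrix(mi.DatagenConfig(n_samples=100, n_features=200, seed=1))
masked = mi.simulate_missingness(matrix, mi.MissingnessSpec("MCAR_MAR_MNAR", 0.30), seed=7)
print(masked.n_missing, masked.step_counts())

for method in ("RF", "KNN", "MEAN", "MIN"):
    result = mi.impute(masked, method, mi.ImputerConfig(rf_ntree=50))
    print(method, round(mi.nrmse(matrix, result, masked.mask), 3))
```

prints

```
6000 {'MCAR': 2000, 'MAR': 2000, 'MNAR': 2000}
RF 0.846
KNN 0.989
MEAN 1.086
MIN 1.015
```

6,000 of 20,000 cells (30%) were masked, exactly 2,000 per mechanism step.
At this heavy mixed missingness the random forest is the only method
clearly better than guessing each feature's mean (global NRMSE 0.85
against ≈ 1.0 for the others); minimum-value imputation — the right tool
only for pure left censoring — buys nothing when two thirds of the
missingness is random.

The same pipeline is scriptable from the shell:

```bash
metimpute generate --n-samples 100 --n-features 200 --seed 1 --output matrix.csv
metimpute simulate --input matrix.csv --mechanism MNAR --rate 0.1 --seed 7 --output masked.csv
metimpute impute   --input masked.csv --method RF --output filled.csv
metimpute benchmark --config bench.yaml --output results/
```

Every command writes a JSON run echo with the effective parameters and
seeds; `benchmark` emits long-format records, a mean/sd summary per
(method, mechanism, rate), and per-mechanism heatmap tables.

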