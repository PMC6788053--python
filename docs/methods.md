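# Methods

This note records the models, algorithms, numerical choices and known
limitations behind `metimpute`, in the order data flows through the
pipeline: synthetic data → missingness simulation → imputation → scoring.

## Synthetic intensity matrices

Real LC-MS feature tables have three statistical properties that matter for
imputation: strictly positive intensities, strong right skew, and low-rank
correlation among features (adducts, isotopes, co-regulated metabolites).
The generator reproduces exactly these with a log-scale factor model

    log x_ij = mu_j + a_j * f_{g(j), i} + eps_ij,        x_ij = exp(log x_ij)

* `f ~ N(0, I)` — per-sample scores of `latent_rank` latent factors;
* `g(j) = j mod latent_rank` — each feature belongs to one factor block,
  emulating clusters of correlated features;
* `a_j ~ U(0.5, 1.5) * sd_log` — the feature's log-scale biological spread;
* `mu_j ~ N(mean_log, 1)` — per-feature baseline log intensity;
* `eps ~ N(0, noise_sd^2)` — analytical noise.

Defaults: 100 samples × 200 features, `latent_rank = 5`, `mean_log = 12`
(raw intensities ~1.6e5, a typical qTOF peak-height magnitude),
`sd_log = 1.0` (per-feature log-e spreads 0.5–1.5, i.e. geometric SDs of
~1.6–4.5, spanning typical biological variation of plasma metabolites up to
highly variable diet-derived compounds) and `noise_sd = 0.3` (~30%
analytical CV).  Exponentiation makes every feature log-normal, hence
positive and right-skewed; same-block features are strongly correlated but
related by *power laws* (exponents a_k/a_j), not linearly — so linear
global imputers are genuinely mis-specified on the raw scale, as they are
on real data.

What the generator does **not** emulate: batch and injection-order effects,
retention-time drift, heteroscedastic detection noise near the limit of
detection, heavy-tailed outliers, and biological group structure.  In
particular its left tails are exact log-normal tails; real censored
features cluster just under a sharp detection limit.  Benchmark
conclusions transfer to real data only insofar as these properties are
irrelevant to the compared methods (see "Reading the benchmark" below).

## Missingness simulation

All mechanisms mask exactly `round(rate × n_cells)` cells; the paper rates
are 5/10/20/30%.  Rates above 30% are allowed but logged, since heavy
masking tends to produce left-truncation-like patterns no matter the
nominal mechanism.

* **MCAR** — a uniform draw without replacement over all unmasked cells.
* **MAR** — repeatedly: draw a distinct driver/target pair (X₁, X₂)
  uniformly; draw a cut-off fraction c; mask X₂ in the ⌈c·n_samples⌉
  samples with the highest X₁ (ranks computed on the complete data, the
  simulator's privilege), skipping already-masked target cells.
* **MNAR** — repeatedly: draw one feature; draw c; mask its ⌈c·n_obs⌉
  smallest still-observed values (left truncation; right truncation is
  implemented behind `truncation_side="right"` but excluded from benchmark
  defaults).
* **Mixed** — the components run sequentially, each on the output of the
  previous, with per-step quotas from cumulative rounding of the equal
  split (exactly equal whenever the total divides evenly).

The cut-off sampler is a χ²(df = 1) draw divided by 30 and clipped to
[0, 1].  df = 1 is adopted because the scaled distribution's analytic
moments — mean 1/30 ≈ 3.33%, sd √2/30 ≈ 4.71% — match the sampler's
documented empirical behaviour; clipping changes them only in the fifth
decimal.  The ceiling in ⌈c·n⌉ guarantees every event masks at least one
cell, so the loop cannot stall on tiny draws.

Because events overshoot the target count, the last event is trimmed.
Trimming keeps the semantics of the mechanism rather than a random subset:
MAR keeps the highest-driver samples, MNAR keeps the most extreme values,
MCAR trims uniformly.  This preserves two per-event invariants the test
suite replays from provenance: MAR masks exactly the top-ranked available
samples, and MNAR-left masks values no larger than anything left observed.

## Imputation methods

All methods are scikit-learn transformers (`fit`, `transform`,
`fit_transform`); `fit_transform` runs the native algorithm on the fit
matrix, `transform` applies the fitted model to new masks in a single
pass.  Two contracts hold universally: observed cells are returned
bit-identical, and the output is complete.  No preprocessing (no log, no
scaling) is applied before any method.

* **ZERO / MEAN / MIN / HALF_MIN** — per-feature constants from observed
  values.  Per-feature (not global) statistics respect the orders of
  magnitude separating feature scales; half-minimum is the conventional
  proxy for values censored below a detection limit.
* **KNN** — feature-space neighbours: distance between two features is the
  root-mean-square difference over mutually observed samples (normalising
  by overlap keeps distances comparable across pairs); the K = 10 nearest
  features vote with inverse-distance weights; voters missing at the cell
  are skipped; if none remains the feature's observed mean is used
  (logged).  Ties break on feature index, so results are deterministic.
  Sample-space KNN is available via `orientation="samples"`.
* **RF** — missForest: mean-initialise; visit features by ascending
  missingness; regress each on all others with a random forest (100 trees,
  mtry = ⌊√p⌋, terminal nodes ≥ 5 — the defaults of the R randomForest
  regression stack that missForest wraps); sweep until the normalised
  squared change of the imputed cells first rises, then return the previous
  sweep (cap 10 sweeps).
* **SVD** — SVDimpute: missing cells start at 0; iterate truncated rank-r
  SVD of the raw (uncentred) matrix, overwriting missing cells with the
  reconstruction, until the imputed values change by < `tol`.  No centring
  is applied: the zero initialisation is part of the method and the known
  source of its bias on positive data.
* **PPCA** — x = Wz + μ + ε with isotropic Gaussian ε, fitted by EM on
  column-centred data; missing cells are replaced by their conditional mean
  under the current model at every iteration (an imputation-EM variant) and
  those conditional means are the result.  Initialised from the SVD of the
  mean-filled matrix plus a small seeded jitter.
* **BPCA** — PPCA with automatic-relevance-determination priors: each
  loading column j carries a precision α_j = p/‖w_j‖², and the M-step
  solves (ΣE[zzᵀ] + σ²·diag α) Wᵀ = (X_cᵀ E[Z])ᵀ.  Columns the data do not
  support collapse towards zero, so the effective rank can fall below
  `n_components` (reported as `effective_rank_`).  Note the collapse is
  only guaranteed when the residual is close to isotropic — on raw
  intensity scales with wildly heterogeneous feature variances, extra
  components legitimately survive because they capture real variance
  structure.

Numerical choices: `pca_components = 5` for the SVD/PPCA/BPCA family
(small against 200 features and matching the generator's default latent
rank order of magnitude), relative-change tolerance `tol = 1e-5`, EM cap
100 iterations; non-convergence is reported via `converged_ = False` and
logged, never raised.  σ² is floored at 1e-12 of the data variance; EM
aborts with an error only on non-finite parameters.  Degenerate features
(no observed value) raise an error naming the feature for mean/min
strategies; ZERO tolerates them.

## Scoring and the permutation benchmark

    NRMSE = sqrt( mean((X_comp − X_imp)²) / var(X_comp) )

evaluated over the *originally masked cells only* (every method preserves
observed cells exactly, so a whole-matrix ratio would only dilute the
signal), with the unbiased (n−1) variance.  Two aggregations are
implemented, because either reading of "error per molecular feature" is
defensible:

* `global` (package default) — one ratio over all masked cells;
* `per_feature` — one NRMSE per incomplete feature, each normalised by the
  feature's own full-column variance, averaged across features.

They weight features very differently: the global ratio is dominated by the
highest-variance (highest-intensity) features, while the per-feature mean
treats all features equally.  The ranking-replication tests use
`per_feature`, matching the description of the error as computed per
molecular feature; rankings among multivariate methods can change between
modes, and both are one flag away.

The benchmark: per permutation, one dataset is drawn uniformly from the
pool, a fresh random subset of complete features is taken (default 200),
and every mechanism × rate is simulated and imputed by every method on the
*same* mask — comparisons are therefore paired within a trial.  Per-trial
seeds derive deterministically from `(master_seed, permutation, mechanism,
rate)` via `numpy` seed sequences, so any single grid cell can be
reproduced in isolation.  A failing method yields a flagged record
(excluded from summaries, with counts logged) rather than aborting the
run.  Summaries report mean, sd (ddof = 1; 0 for singleton groups) and
count per (method, mechanism, rate) and pooled over rates.

Wall-clock runtimes are recorded per trial as diagnostics but omitted from
serialized records so that reruns under one master seed are byte-identical.

## Reading the benchmark (and its reduced scale)

The test suite's permutation study runs 10 permutations of 50-sample ×
50-feature subsets drawn from three synthetic pools, all nine methods,
with 50 trees per forest — desk-scale settings chosen so the full study
completes in minutes on one CPU; the scientific contrasts it probes (RF
lowest under MCAR/MAR and all mixed mechanisms; censoring-aware constants
winning under left-truncated MNAR; RF beating ZERO and SVD everywhere
random missingness dominates) are stable at this scale, but absolute NRMSE
levels are not comparable to larger matrices.

One caveat the synthetic data makes visible: under pure MNAR at low rates,
minimum and half-minimum imputation are both far ahead of every other
method, but their mutual order depends on how deep the censored tail
reaches.  On exact log-normal tails (this generator), censored values
average ~0.7× the observed minimum, which slightly favours half-minimum;
on real data where censored values crowd just under the detection limit,
the minimum itself is the better proxy.  The same tail depth lets the
censoring-aware constants rival the random forest in MNAR-heavy *mixed*
masking at 30% total missingness — a regime where left truncation starts
to dominate whatever the nominal mechanism.  Those orderings should not be
read as transferable to real feature tables.

## Known limitations

* Group-wise (stratified) imputation is out of scope; all methods treat
  the sample set as homogeneous.
* No method propagates imputation uncertainty (single imputation only).
* Mechanism *detection* on observed data is not attempted; the simulators
  require the complete ground truth.
* The PPCA/BPCA EM uses conditional-mean refilling rather than the full
  missing-data sufficient statistics; with the benchmark's missingness
  rates this is standard practice, but at extreme rates it can understate
  the residual variance.
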