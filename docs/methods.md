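# Methods

`dapsel` identifies differentially abundant proteins (DAPs) between sample
groups in small-n, large-p label-based proteomics experiments (the motivating
design: 12 samples — two sugarcane genotypes × two treatments × three
biological replicates — and ~3,000 quantified proteins). The pipeline is:
batch correction by a crossed-random-effects linear mixed model, then three
complementary selection methods per two-group comparison, then
Bayesian-FDR / Bonferroni control, direction calls and cross-method pooling.

## Batch correction

Log-intensities are modeled per feature `k`, group `g`, replicate `j` as

    y_kgj = mu_kg + b_j + s_kj + e_kgj,
    b_j ~ N(0, sigma_r^2),  s_kj ~ N(0, sigma_s^2),  e ~ N(0, sigma_e^2),

with a fixed mean per (feature, group) cell. The replicate index is shared
across groups: the j-th replicates of all groups were processed together, so
`b_j` is a batch main effect and `s_kj` a feature-specific batch effect.
Variance components are estimated by maximum likelihood (ML, not REML). In
this balanced design the GLS fixed-effect estimates coincide with the OLS
cell means for any variance components, and the profiled likelihood
separates over three orthogonal eigenspaces of the per-replicate covariance
block, giving closed-form ML estimates; a bounded L-BFGS-B solve (relative
tolerance 1e-6) takes over only when a closed-form component is negative
(boundary solutions). The correction subtracts the BLUP of `s_kj` from each
observation. Group effects and `b_j` are retained by design: `b_j` is
constant within a sample and cannot masquerade as a group difference in a
balanced comparison.

Two structural facts about this estimator are worth knowing:

* **ML attenuation.** Profiling the per-(feature, group) means removes the
  replicate-mean of every random effect, so ML variance estimates carry an
  exact `(J-1)/J` factor at `J` replicates (2/3 at J = 3). This is inherent
  to ML with cell-mean fixed effects, not an implementation artifact; the
  test suite asserts both the attenuated behavior at J = 3 and accurate
  recovery at J = 30.
* **Identifiable part of `s`.** For the same reason the BLUP predicts
  `s_kj - mean_j(s_kj)`, so its correlation with the realized `s_kj` is
  bounded by `sqrt(1 - 1/J)` (0.82 at J = 3) no matter how small the noise.
  BLUP-quality checks therefore use J = 10 designs, where the bound is 0.95
  and the observed correlation is ~0.94.

PCA on feature-centered, unscaled data (full SVD; deterministic signs via
the largest-magnitude loading) provides the before/after QC view; percent
variance explained sums to 100 over all components.

## Marginal regression

Each feature is regressed on the 0/1 group indicator; for a binary regressor
this is algebraically the pooled equal-variance two-sample t-test with
n - 2 degrees of freedom (the suite asserts identity to 1e-10). Two-sided
p-values are Bonferroni-adjusted with `m` = number of features with a
defined p-value; constant features are flagged (`p = NaN`) and can never be
selected. No covariates enter the model — the study design has none.

**Caveat for crossed designs:** subtracting the BLUP of `s_kj` removes noise
shared by the samples of one replicate. When a comparison places those
samples in opposite groups, the corrected within-group variances shrink
while group differences are preserved, so marginal t-statistics on corrected
data are anti-conservative. Null-calibration tests therefore run on data
meeting the t-test's own iid assumptions; the pipeline's marginal results on
corrected data should be read as liberal.

## Elastic-net logistic regression

All features enter one penalized logistic model; the objective is

    sum_i [log(1 + exp(eta_i)) - y_i eta_i]
      + lambda * [omega * ||beta||_1 + (1 - omega) * ||beta||_2^2],

with the L2 term deliberately carrying **no 1/2 factor** — callers comparing
against solvers parameterized as `lambda*(1-alpha)/2*||beta||_2^2` must
rescale. Features are standardized within the comparison (penalties are
scale-sensitive); coefficients are reported on the standardized scale. The
solver is cyclic coordinate descent on the IRLS surrogate with an active-set
strategy; its contract is the KKT system of the objective at tolerance
`tol` (default 1e-8), verified in tests against an independent
proximal-gradient solver.

`(lambda, omega)` are tuned by nested cross-validation: leave-one-sample-out
outer folds; stratified 3-fold inner CV (folds capped by the smaller class)
scoring held-out binomial deviance over a grid of 50 log-spaced lambdas per
omega (from the all-zero-solution `lambda_max` down to 1%) and
omega ∈ {0.1, 0.3, 0.5, 0.7, 0.9}; ties break toward larger lambda then
larger omega (the sparser model). Inner-CV fits use a relaxed KKT tolerance
(2e-3) — held-out deviance is insensitive at that scale — while the final
refit on all samples uses the strict tolerance. Non-convergent grid points
score infinite deviance; the run errors only if the whole grid fails.

With ~11 training samples the CV deviance surface is noisy: on null data the
*modal* outcome is the (near-)empty model, but individual datasets can
select large ridge-dominated models. This is CV variance, not bias (the
fold-averaged surface over many datasets is monotone in lambda).

## Spike-and-slab Bayesian logistic regression (SSVS)

Per comparison, with standardized features:

    logit P(y_i=1) = beta_0 + sum_j x_ij beta_j
    beta_j | r_j ~ (1 - r_j) delta_0 + r_j N(0, sigma_j^2)
    r_j ~ Bernoulli(w),  w = 0.05 fixed
    sigma_j^2 ~ Inverse-Gamma(a, b),  a = b = 0.1

Polya-Gamma augmentation (one latent `phi_i ~ PG(1, eta_i)` per sample)
renders the conditional model Gaussian in the working response
`kappa_i = y_i - 1/2`, enabling an exact Gibbs sweep: PG latents; intercept
(N(0, 100) prior); each `(r_j, beta_j)` jointly from the analytic
spike-and-slab conditional, sweeping features in fixed index order for
reproducibility; `sigma_j^2` from Inverse-Gamma(a + r_j/2, b + r_j
beta_j^2/2) — the prior itself when the feature is excluded, keeping the
chain irreducible. PG(1, z) draws use an exact Devroye-type rejection
sampler (alternating-series accept/reject between a truncated exponential
and a truncated inverse-Gaussian proposal), validated against closed-form
moments; PG(b, z) for integer b is the b-fold convolution. Chains default to
5,000 iterations with 1,000 burn-in (simulation harnesses use 2,000/500);
the chain is a deterministic function of the seed.

The posterior mean of `r_j` is the feature's posterior inclusion
probability (PIP). `1 - PIP` is a local false discovery rate (lfdr);
sorting lfdrs ascending, the selection keeps the largest prefix whose
running mean (the Bayesian FDR) is still strictly below alpha = 0.05, with
lexicographic tie-breaks. A `PIP > 0.5` heuristic is provided but BFDR is
the primary rule.

Correctness of the sampler is established three independent ways: prior
recovery (mean PIP ≈ w under a diffuse likelihood), a conjugate
linear-Gaussian check with frozen PG latents, and agreement of PIPs with an
exact model-enumeration posterior computed by dense quadrature on a
two-feature problem.

### Behavior at n = 12 — read before trusting error rates

Three properties of this model/sampler combination dominate its small-sample
behavior; all are verified consequences of the specification, not bugs:

1. **Chance separation.** With 6-vs-6 labels, a null feature perfectly
   separates the groups with probability 2/C(12,6) ≈ 0.0022, so among ~500
   null features one separating feature is *expected per dataset*. A
   correctly computed posterior must assign such features high PIP, and BFDR
   then selects them. BFDR controls the posterior-expected FDR under the
   model's own prior — not the frequentist FDR of a fixed-truth simulation.
   In the packaged 200-dataset harness (10 true signals at twice the
   residual SD) the realized mean false-discovery proportion is ~0.24 at
   alpha = 0.05 (recomputed by `scripts/acceptance.py`).
2. **Feature competition.** Once one strong feature is included it explains
   the 12 labels almost fully; the conditional inclusion odds of the other
   signals revert to the prior. PIP-based rankings of all signal features
   are accordingly weak (rank-AUC ~0.57 in the same harness) even when the
   top pick is a true signal.
3. **Heavy-tailed slab and mode-sticking.** Marginalizing sigma_j^2 makes
   the slab a t distribution with 0.2 degrees of freedom, which
   Lindley-penalizes moderate effects — only near-separating features reach
   high PIP. And the fixed-order single-site scan switches very slowly
   between competing-feature modes (a two-feature posterior that splits
   0.59/0.43 exactly is visited as ~1/0 or ~0.4/0.6 by single chains).

## Synthetic data

The generator emulates the study design: `n_groups` × `n_reps_per_group`
samples (default 4 × 3; group labels RCK/MCK/R400/M400 with the 2×2
genotype × treatment coding), `n_features` log-intensities (default 3,000;
test scale 500) with baseline 15, replicate effects `b_j` (SD 0.3),
feature × replicate effects `s_kj` (SD 0.5) shared across groups within a
replicate, and residual SD 1.0 — noise scales chosen for testability since
the source data's scales are not published. A uniformly chosen sparse subset
of features receives a ±`effect_size` mean shift (half up, half down); in
factorial designs each signal feature is randomly assigned to one factorial
axis and shifted in that axis's first level, so both genotype- and
treatment-associated proteins exist. Output is a pure function of the
config; truth (signal ids, signed effects, realized `b` and `s`) is
returned and optionally written as a JSON sidecar.

Not emulated: missing values (the reader drops incomplete features),
intensity-dependent variance, correlated protein modules, or any
spectrum-level processing. Passing tests therefore demonstrate statistical
correctness under the stated Gaussian model, not robustness to real
iTRAQ artifacts.

## Problem sizes and runtime choices

Simulation harnesses run at the design scale the study motivates: 12
samples, 500 features, 10 signals, 200 replicated datasets for error-rate
estimates, 2,000-iteration chains (the FDR harness), 20 seeds for ranking
metrics. BLUP-quality and variance-recovery checks use enlarged replicate
counts (J = 10, J = 30) for the identifiability reasons above. The
`--scale test` pipeline flag swaps 3,000 features for 500.

## Known limitations

* Balanced designs only (each group must contain each replicate exactly
  once); unbalanced data error out rather than silently refit.
* Marginal tests on corrected data are anti-conservative in crossed designs
  (see above); frequentist FDR of SSVS+BFDR is not controlled at n = 12.
* Elastic-net coefficients carry no uncertainty measures; selection
  stability at this n is limited.
* The w = 0.05 prior inclusion probability is fixed, not learned.
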