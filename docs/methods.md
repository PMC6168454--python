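# Methods

`polskit` implements the quantitative core of a pace-of-life-syndrome
(POLS) analysis: the hypothesis that life-history, behavioural and
physiological traits covary *among individuals* — bold, active animals
carrying fast life histories and high metabolic throughput — and that the
strength of this coupling can differ between populations. The package
covers the full chain from raw respirometry traces to cross-population
covariance tests, together with a synthetic-data generator that carries
known ground truth for every stage.

## The mixed model

Every repeatedly measured trait is modelled with an individual random
intercept. For a vector of `q` traits, the observation of trait `t` on
individual `i` at occasion `o` is

    y_ito = x_ito' beta_t + u_it + e_ito,
    u_i ~ MVN(0, Sigma_ind),   e_io ~ MVN(0, Sigma_res),

where `u_i` is the individual's latent trait vector, `Sigma_ind` the
among-individual covariance matrix, and `Sigma_res` the residual
(within-individual) covariance. Residuals are correlated only between
traits measured on the *same occasion*: traits never co-measured on an
occasion have no data to identify their residual covariance, and that
element is structurally fixed to zero (and reported as such). In the
default design, the two open-field behaviours share trial occasions and
metabolic rate shares the once-per-stage measurement occasion with body
size, so the residual matrix is block-diagonal with two 2x2 blocks.

Fixed effects are trait-specific: intercept, ontogenetic stage and sex
for every trait, plus the within-stage trial sequence for traits measured
twice per stage. Sex and stage are coded -0.5/+0.5 (female/immature low),
so main effects are evaluated at the design midpoint; the trial covariate
is centred. Responses are transformed (log for emergence latency; square
root for hiding time, freezing time and mass-specific SMR) and then
mean-centred and variance-standardized so variance components are
comparable across traits. Standardization is pooled across populations
for mean-comparison models (population differences must survive
centring) and per-population for covariance models. Transformation
precedes standardization.

## Estimation

All variance parameters are estimated by restricted maximum likelihood
(REML). Writing `V` for the marginal covariance implied by
`(Sigma_ind, Sigma_res)` and the design, the restricted log-likelihood

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ]

is maximized with fixed effects profiled out by GLS. Two code paths:

* **Univariate fits** profile the variance ratio
  `lambda = sigma2_ind / sigma2_res`: given `lambda`, both `beta` and
  `sigma2_res` have closed forms, reducing the fit to a one-dimensional
  bounded search over a grid plus Brent refinement (`xatol 1e-12`). The
  boundary `lambda = 0` is part of the search space, so null fits land
  exactly on zero — essential for boundary-mixture tests. This path
  reproduces the balanced one-way ANOVA closed form to < 1e-6 and
  matches `statsmodels` `MixedLM` to 1e-4 on unbalanced panels.

* **Multivariate fits** optimize on the log-Cholesky scale (L-BFGS-B,
  numerical gradients, dispersed restarts; Cholesky diagonals bounded
  below at 1e-10, with estimates within 10x the bound flagged "at
  boundary"). Each individual's covariance block is assembled from its
  observed rows only, so missing responses are marginalized exactly.
  Individuals sharing an observation pattern share one Cholesky
  factorization per likelihood evaluation, which keeps study-scale fits
  (40 individuals, 4 traits, ~20 parameters) under a second. Starting
  values come from individual-mean moment estimates.

Constrained covariance structures used by the hypothesis tests:

* *diagonal* — all among-individual covariances zero (overall POLS test);
* *single element zero* — the constrained pair is permuted to the leading
  2x2 block, where `Sigma[0,1] = 0` is exactly `L[1,0] = 0` in the
  Cholesky factor, keeping the parameterization smooth and positive
  definite;
* *dropped trait* — one trait's variance and covariances removed (an
  unstructured block on the remaining traits);
* *shared covariances across populations* — per-population variances with
  tied covariances have no Cholesky form, so this map parameterizes
  elements directly and enforces positive definiteness by an eigenvalue
  clip with a smooth penalty on the violation.

Standard errors of variance components come from the numerical Hessian
of the restricted likelihood (delta method for derived elements);
standard errors of repeatabilities and correlations use a parametric
bootstrap from the asymptotic distribution of the variance parameters
(default 1000 draws, seeded; delta method available as an option). At a
boundary the bootstrap spread is one-sided and the repeatability point
estimate is 0.

## Hypothesis tests

Likelihood-ratio statistics are `2 (l_full - l_reduced)`, floored at 0.
Reference distributions:

* among-individual **variance** (bounded at zero): equal mixture
  `{1/2 chi2_0, 1/2 chi2_1}` — the df-0 point mass contributes nothing to
  the tail for positive statistics and makes p = 1 at zero;
* single **covariance** (unbounded): plain `chi2_1`;
* a trait's variance *plus* its `k` covariances: `{1/2 chi2_k, 1/2 chi2_{k+1}}`
  (for two traits, the familiar `{1/2 chi2_1, 1/2 chi2_2}`);
* **overall structure** (all covariances zero) and **population equality**
  (covariances tied across two populations): `chi2` with one df per trait
  pair (6 for four traits).

Fixed effects are tested with Wald F statistics. The denominator df uses
a containment-style approximation, `n_obs - rank(X) - n_individuals + 1`,
recorded on every fit; specialised algebraic df algorithms in commercial
mixed-model software can differ slightly, so fixed-effect p-values may
deviate in the second decimal. Null simulations show the approximation
is well calibrated for within-individual terms and for between-individual
terms in once-per-stage designs.

### Finite-sample calibration

Null simulations at the default study scale (40 individuals, four
measures per behavioural trait, 20% attrition):

* the `{1/2 chi2_0, 1/2 chi2_1}` variance LRT rejects at 0.051 over 2000
  replicates, with the estimate landing on the boundary in ~50% of
  replicates, as theory predicts;
* the `chi2_1` covariance LRT rejects at 0.058 over 2000 replicates at
  the default behavioural-trait components (repeatabilities ~0.2–0.4,
  20% attrition). The asymptotic reference is mildly inflated at this
  sample size — under equal moderate variances without attrition the rate
  rises to ~0.064, and it shrinks toward nominal as the number of
  individuals grows (~0.057 at 160 individuals under those conditions).
  This is not an optimization artifact: restarts move statistics by
  < 1e-8, and the likelihood itself is verified against a dense
  brute-force evaluation to 1e-6. Users testing covariances on samples
  of this size should treat p-values near 0.05 with caution; the package
  reports raw statistics so any reference distribution can be applied
  afterwards.

## Standard metabolic rate

Intermittent-flow respirometry alternates open (flush) and closed
(sealed) phases; during a closed phase dissolved O2 declines linearly at
the fish's respiration rate. Extraction:

1. trim 2 minutes from each end of every closed phase and fit an OLS
   line; keep phases with R^2 >= 0.95 that start after the 1-hour
   acclimation window (defaults; all three are parameters);
2. convert retained slopes to mass-specific rates,
   `rate = |slope| * 60 * chamber_volume / fish_mass` (mg O2 kg^-1 h^-1);
3. fit a two-component normal mixture by EM (10 restarts from jittered
   25th/75th-percentile initializations; component SDs floored at 1e-6
   of the data scale; the per-iteration log-likelihood is asserted
   non-decreasing). The lower component mean is the SMR; the upper
   component absorbs phases inflated by spontaneous activity. Ties are
   broken toward the lower first mean; at least 4 retained phases are
   required, else the caller is directed to a fallback summary.

Background (microbial) respiration is not corrected; traces are assumed
blank-corrected upstream. Chamber volume handling is explicit in the
trace container since hardware details vary between setups.

## The synthetic-data generator

The generator emulates the two-population repeated-measures design: 40
individuals per population; behaviours measured twice per stage at two
ontogenetic stages (hiding time and distance moved sharing each trial
occasion), SMR and standard size once per stage on a shared metabolic
occasion; individual-level attrition after stage 1 (defaults 8/40 and
1/40, mirroring the overnight mortality event of the emulated design);
sex assigned at random. Default variance components and fixed effects
are the published univariate estimates for the two populations; the
slow-growing population's among-individual correlations carry the POLS
signature (hiding~distance +0.6, distance~size +0.6, smr~size -0.6),
the fast-growing population none; the only non-zero residual correlation
is the expected negative smr~size coupling (-0.4). Trials are
conditionally independent given the individual effect.

Respirometry traces default to a 12-h session of 10-min closed / 5-min
open cycles sampled every 5 s, resting drawdown -0.05 mg L^-1 min^-1,
active drawdown -0.15, activity probability per closed phase, optode
noise 0.01 mg L^-1 (so clean resting phases show R^2 ~ 0.999, as in real
data), and optional injected quadratic curvature for testing the
linearity filter. Ground-truth phase states and slopes are retained.

What the generator does *not* emulate: measurement-device drift,
background respiration, non-Gaussian trait distributions, family/tank
structure, record-level missingness, or temporal autocorrelation beyond
the individual intercept. Passing tests therefore demonstrate correct
recovery under the model's own assumptions, not robustness to violations
of them.

## Pipeline

`run_pipeline` executes: data acquisition (CSV panel + optional traces,
or simulation) → covariate coding and standardization (both scopes) →
population mean comparisons (linear models for life-history traits;
mixed models with estimated marginal means for behaviour and SMR) →
per-population repeatability with boundary-mixture LRTs → a gate that
admits to the multivariate stage only traits significantly repeatable in
*both* populations (default alpha 0.05) → covariance decomposition,
overall-structure and population-equality tests. Every exclusion and
boundary event is logged in the JSON report, and reports are
byte-identical under a fixed seed. At the default generator's
fast-growing-population parameters the gate has limited power for the
low-repeatability traits (R ~ 0.14 with two measures), so simulated runs
often admit fewer than four traits — a faithful property of the design,
not a defect.

## Problem sizes used in the shipped checks

Monte-Carlo suites use 100 replicates for parameter-recovery checks
(tolerance 3 Monte-Carlo SEs), 2000 replicates for LRT type-I
calibration, 50 seeded traces for SMR recovery (5% tolerance), and
single seeded instances for oracle equivalences (1e-6). The acceptance
script reports the same quantities at moderately reduced replicate
counts, stated in its output.
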