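# polskit

Tools for pace-of-life-syndrome (POLS) analysis in repeated-measures
animal studies: restricted-maximum-likelihood (REML) variance-component
estimation, adjusted repeatability with boundary-mixture likelihood-ratio
tests, among-individual covariance decomposition and cross-population
covariance-structure tests, and standard-metabolic-rate (SMR) extraction
from intermittent-flow respirometry traces. A synthetic-data generator
reproduces the two-population mosquitofish-style study design with known
ground truth, so every stage of the pipeline has a parameter-recovery
test surface.

## Who this is for

Behavioural ecologists and ecophysiologists who measure individuals
repeatedly over ontogeny and want to ask: are traits repeatable, do
behaviour, physiology and life history covary among individuals (a
pace-of-life syndrome), and does that covariance structure differ
between populations?

## The model

Each trait `t` measured on individual `i` at occasion `o` follows

    y_ito = x_ito' beta_t + u_it + e_ito
    u_i  ~ MVN(0, Sigma_ind)        (among-individual covariance)
    e_io ~ MVN(0, Sigma_res)        (residual, within-occasion)

fitted by REML. Adjusted repeatability is
`R = sigma2_ind / (sigma2_ind + sigma2_res)`; the individual effect is
tested with a likelihood-ratio statistic referred to the boundary
mixture `{1/2 chi2_0, 1/2 chi2_1}` (a variance cannot be negative).
Among-individual covariances are tested against `chi2_1` (they are
unbounded), the overall syndrome against `chi2` with one df per trait
pair, and population differences by tying pairwise covariances across
populations. SMR is the lower mean of a two-component normal mixture
over closed-phase respiration rates, after a 2-minute trim, an
R^2 >= 0.95 linearity filter and a 1-hour acclimation exclusion.

See `docs/methods.md` for estimation details, reference distributions,
and what the synthetic generator does and does not emulate.

## Worked example

Simulate the default two-population study (40 fish per population; four
traits: hiding time, distance moved, mass-specific SMR, standard size),
then decompose the slow-growing population's covariance:

```python
import polskit as pk

panel = pk.generate_trait_panel(pk.default_study_config(seed=3))
traits = ["hiding_time", "distance_moved", "smr", "standard_size"]

dec = pk.decompose(panel, traits, "SG", n_boot=200, seed=1)
print(dec.report())
ov = pk.test_overall_structure(panel, traits, "SG", full_fit=dec.fit)
print(f"overall POLS: chi2 = {ov.statistic:.2f} ({ov.df_label}), p = {ov.p_value:.2g}")
```

which prints

```
Among-individual correlations — population SG
       hiding_time ~ distance_moved   r = +0.513 (SE 0.205) p = 0.0280*
       hiding_time ~ smr              r = +0.323 (SE 0.207) p = 0.1670
       hiding_time ~ standard_size    r = -0.238 (SE 0.181) p = 0.2523
    distance_moved ~ smr              r = +0.320 (SE 0.202) p = 0.1644
    distance_moved ~ standard_size    r = +0.403 (SE 0.165) p = 0.0453*
               smr ~ standard_size    r = -0.481 (SE 0.146) p = 0.0142*
overall POLS: chi2 = 26.95 (chi2_6), p = 0.00015
```

The generating truth for this population couples activity with body size
(+0.6), boldness with activity (+0.6) and metabolism with size (-0.6):
at 40 individuals the fit recovers the three generated correlations
(attenuated, as expected at this sample size), flags exactly those three
pairs as significant, and the overall six-df test rejects the
no-syndrome null. The same call on the fast-growing population (whose
generating correlations are zero) gives chi2 = 8.08, p = 0.23.

Repeatability of a single trait:

```python
res = pk.fit_trait_repeatability(panel, "standard_size", "SG")
print(f"R = {res.R:.3f} (SE {res.se_R:.3f}), LRT p = {res.lrt.p_value:.4g}")
```

The full pipeline (simulation or CSV input, respirometry, repeatability
gate, covariance stage, reports) runs from a YAML config:

```bash
polskit run-all config.yaml     # or: polskit simulate / smr / fit / pols / compare
```

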