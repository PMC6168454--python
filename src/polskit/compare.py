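"""Between-population mean comparisons.

Life-history traits measured once per fish are compared with ordinary
linear models (optionally adjusting for standard size or body weight).
Behavioural traits and metabolic rate, measured repeatedly, are compared
with individual-random-intercept mixed models carrying age, sex, trial
and the occasion-level life-history covariates; estimated marginal means
evaluate each population at the covariate reference point (centred
continuous covariates at 0, coded factors at their midpoint), so the
reported difference is the population effect net of body-size and
condition differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lmm import MixedModelFit, fit_lm, fit_univariate_reml, wald_f_test

__all__ = ["MeanComparison", "compare_lht_means", "compare_behaviour_smr"]


@dataclass
class MeanComparison:
    trait: str
    populations: tuple[str, str]
    means: tuple[float, float]  # estimated (marginal) means, same order
    ses: tuple[float, float]
    difference: float
    difference_se: float
    p_value: float
    covariate_adjustment: str
    n_obs: int
    model: str  # "lm" | "lmm"
    fit: MixedModelFit | None = None

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "populations": list(self.populations),
            "means": list(self.means),
            "ses": list(self.ses),
            "difference": self.difference,
            "difference_se": self.difference_se,
            "p_value": self.p_value,
            "covariate_adjustment": self.covariate_adjustment,
            "n_obs": self.n_obs,
            "model": self.model,
        }


def _marginal_means(fit: MixedModelFit, pop_codes: dict[str, float]):
    """Population means at the covariate reference point.

    With population coded +-0.5 and every other covariate at 0, the mean
    for population g is intercept + code_g * beta_pop; SEs follow from
    the coefficient covariance.
    """
    g = fit.groups[0]
    names = fit.fixed_names[g]
    i_int = names.index("intercept")
    i_pop = names.index("population")
    beta, cov = fit.beta[g], fit.beta_cov[g]
    pops = sorted(pop_codes)
    means, ses = [], []
    for p in pops:
        c = np.zeros(len(names))
        c[i_int] = 1.0
        c[i_pop] = pop_codes[p]
        means.append(float(c @ beta))
        ses.append(float(np.sqrt(c @ cov @ c)))
    diff = beta[i_pop] * (pop_codes[pops[1]] - pop_codes[pops[0]])
    diff_se = float(fit.beta_se[g][i_pop] * abs(pop_codes[pops[1]] - pop_codes[pops[0]]))
    return pops, means, ses, float(diff), diff_se


def compare_lht_means(
    panel: pd.DataFrame,
    trait: str,
    adjust_for: str | None = None,
    sex: float | None = None,
) -> MeanComparison:
    """Linear-model comparison of a life-history trait between populations.

    ``adjust_for`` optionally names another trait (e.g. standard size or
    body weight) whose per-individual value is added as a covariate, so
    the population coefficient is the mean difference at equal covariate
    value.  ``sex`` restricts to one sex (coded value) for sex-specific
    traits; the subset size is reported in ``n_obs``.
    """
    df = panel.copy()
    if sex is not None:
        df = df[df["sex"] == sex]
    if adjust_for is not None:
        cov = (
            df[df["trait"] == adjust_for]
            .groupby("individual_id")["value"]
            .mean()
            .rename(adjust_for)
        )
        rows = df[df["trait"] == trait].merge(cov, on="individual_id", how="inner")
        # collinearity guard: covariate vs population coding
        pops = sorted(rows["population"].unique())
        codes = rows["population"].map({p: c for p, c in zip(pops, (-0.5, 0.5))})
        x = rows[adjust_for].to_numpy(dtype=float)
        if np.std(x) > 0 and abs(np.corrcoef(codes, x)[0, 1]) > 0.99:
            import logging

            logging.getLogger(__name__).warning(
                "covariate %s is nearly collinear with population", adjust_for
            )
        df = rows
        terms = ["intercept", "population", adjust_for]
    else:
        df = df[df["trait"] == trait]
        terms = ["intercept", "population"]
    fit = fit_lm(df, trait, terms)
    pop_codes = fit.extra["population_codes"]
    pops, means, ses, diff, diff_se = _marginal_means(fit, pop_codes)
    p = fit.extra["p_values"]["population"]
    return MeanComparison(
        trait=trait,
        populations=tuple(pops),
        means=tuple(means),
        ses=tuple(ses),
        difference=diff,
        difference_se=diff_se,
        p_value=float(p),
        covariate_adjustment=adjust_for or "none",
        n_obs=fit.n_obs,
        model="lm",
        fit=fit,
    )


def _merge_occasion_covariates(
    panel: pd.DataFrame, trait: str, covariates: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Attach per-(individual, stage) life-history covariates to the
    response rows; covariates missing from the panel are dropped."""
    rows = panel[panel["trait"] == trait].copy()
    used = []
    for cov in covariates:
        cv = panel[panel["trait"] == cov]
        if cv.empty:
            continue
        per_stage = (
            cv.groupby(["individual_id", "age_stage"])["value"].mean().rename(cov)
        )
        rows = rows.merge(per_stage, on=["individual_id", "age_stage"], how="left")
        rows[cov] = rows[cov] - rows[cov].mean()  # centre at the reference grid
        used.append(cov)
    return rows.dropna(subset=used or None), used


def compare_behaviour_smr(
    panel: pd.DataFrame,
    trait: str,
    covariates: Sequence[str] = ("standard_size", "fulton_k"),
) -> MeanComparison:
    """Mixed-model population comparison for a repeatedly measured trait.

    Fixed effects: population, age, sex, the within-stage trial sequence
    (when the trait has one), and the centred occasion-level covariates
    available in the panel (standard size and condition factor by
    default); individual as random intercept.  The population term is
    tested with a Wald F at containment df.
    """
    rows, used = _merge_occasion_covariates(panel, trait, covariates)
    if rows.empty:
        raise ValueError(f"no usable rows for trait {trait!r}")
    has_trial = bool((rows["trial"] > 0).any())
    terms = ["intercept", "population", "age_stage", "sex"]
    if has_trial:
        terms.append("trial")
    terms.extend(used)
    fit = fit_univariate_reml(rows, trait, terms, compute_se=False)
    pop_codes = fit.extra["population_codes"]
    pops, means, ses, diff, diff_se = _marginal_means(fit, pop_codes)
    wald = wald_f_test(fit, "population")
    return MeanComparison(
        trait=trait,
        populations=tuple(pops),
        means=tuple(means),
        ses=tuple(ses),
        difference=diff,
        difference_se=diff_se,
        p_value=wald["p_value"],
        covariate_adjustment=",".join(used) if used else "none",
        n_obs=fit.n_obs,
        model="lmm",
        fit=fit,
    )
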