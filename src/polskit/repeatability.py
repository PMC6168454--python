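"""Adjusted repeatability and boundary-mixture likelihood-ratio tests.

Repeatability R = sigma2_ind / (sigma2_ind + sigma2_res) is the share of
phenotypic variance (net of fixed effects) explained by consistent
among-individual differences.  Its significance is tested by a
likelihood-ratio test of the individual random intercept; because a
variance is constrained to be non-negative, the null reference
distribution is the equal mixture {1/2 chi2_0, 1/2 chi2_1} rather than a
plain chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import MixedModelFit, fit_univariate_reml
from .preprocess import TraitSpec

__all__ = [
    "LRTResult",
    "RepeatabilityResult",
    "mixture_lrt_p",
    "adjusted_repeatability",
    "fit_trait_repeatability",
    "repeatability_table",
]

#: reference mixtures for common boundary cases
VARIANCE_MIXTURE = ((0.5, 0), (0.5, 1))


@dataclass
class LRTResult:
    """A likelihood-ratio statistic with its reference distribution."""

    statistic: float
    mixture: tuple[tuple[float, int], ...]
    p_value: float
    df_label: str = ""
    loglik_full: float = float("nan")
    loglik_reduced: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "mixture": [list(m) for m in self.mixture],
            "p_value": self.p_value,
            "df_label": self.df_label,
            "loglik_full": self.loglik_full,
            "loglik_reduced": self.loglik_reduced,
        }


def mixture_lrt_p(statistic: float, mixture: Sequence[tuple[float, int]]) -> float:
    """Upper-tail probability of a chi-square mixture at ``statistic``.

    ``mixture`` is a sequence of (weight, df) pairs with weights summing
    to one.  A df = 0 component is a point mass at zero: it contributes
    nothing to the tail for t > 0 and makes p = 1 at t = 0.
    """
    t = float(statistic)
    if t < -1e-8:
        raise ValueError(f"likelihood-ratio statistic must be >= 0, got {t}")
    t = max(t, 0.0)
    weights = np.array([w for w, _ in mixture], dtype=float)
    dfs = [df for _, df in mixture]
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("mixture weights must be non-negative and sum to 1")
    if t == 0.0:
        return 1.0
    p = 0.0
    for w, df in zip(weights, dfs):
        if df == 0:
            continue  # point mass at zero has no upper tail beyond t > 0
        p += w * float(stats.chi2.sf(t, df))
    return min(p, 1.0)


def lrt_from_logliks(
    loglik_full: float,
    loglik_reduced: float,
    mixture: Sequence[tuple[float, int]],
    df_label: str = "",
) -> LRTResult:
    """2 * (l_full - l_reduced), floored at zero, with its mixture p-value."""
    stat = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    return LRTResult(
        statistic=stat,
        mixture=tuple((float(w), int(df)) for w, df in mixture),
        p_value=mixture_lrt_p(stat, mixture),
        df_label=df_label,
        loglik_full=loglik_full,
        loglik_reduced=loglik_reduced,
    )


@dataclass
class RepeatabilityResult:
    trait: str
    population: str
    R: float
    se_R: float
    sigma_ind: float
    sigma_res: float
    lrt: LRTResult
    fit: MixedModelFit | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "population": self.population,
            "R": self.R,
            "se_R": self.se_R,
            "sigma_ind": self.sigma_ind,
            "sigma_res": self.sigma_res,
            "lrt": self.lrt.to_dict(),
        }


def repeatability_from_components(sigma_ind: float, sigma_res: float) -> float:
    """R = sigma2_ind / (sigma2_ind + sigma2_res)."""
    if sigma_ind < 0 or sigma_res < 0:
        raise ValueError("variance components must be non-negative")
    total = sigma_ind + sigma_res
    if total == 0:
        return 0.0
    return sigma_ind / total


def adjusted_repeatability(
    fit: MixedModelFit,
    trait: str,
    population: str = "",
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "bootstrap",
) -> tuple[float, float]:
    """R and its standard error from a univariate mixed-model fit.

    The SE comes from a parametric bootstrap over the asymptotic normal
    distribution of (sigma2_ind, sigma2_res) (draws with negative
    components are projected to the boundary), or from the delta method
    when ``method="delta"``.  At the boundary sigma2_ind = 0 the point
    estimate is R = 0 and the bootstrap spread is one-sided.
    """
    if not fit.converged:
        raise ValueError("cannot compute repeatability from a non-converged fit")
    if trait not in fit.responses:
        raise ValueError(f"trait {trait!r} not in fit responses {fit.responses}")
    g = fit.groups[0]
    s2i = float(fit.sigma_ind[g][0, 0])
    s2r = float(fit.sigma_res[g][0, 0])
    R = repeatability_from_components(s2i, s2r)
    cov = fit.theta_cov
    if cov is None or not np.all(np.isfinite(cov)):
        return R, float("nan")
    if method == "delta":
        tot = s2i + s2r
        grad = np.array([s2r, -s2i]) / tot**2
        var = float(grad @ cov @ grad)
        return R, float(np.sqrt(max(var, 0.0)))
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal([s2i, s2r], cov, size=n_boot)
    draws[:, 0] = np.maximum(draws[:, 0], 0.0)
    draws = draws[draws[:, 1] > 1e-12]
    rs = draws[:, 0] / (draws[:, 0] + draws[:, 1])
    return R, float(np.std(rs, ddof=1))


def fit_trait_repeatability(
    panel: pd.DataFrame,
    trait: str,
    population: str,
    spec: TraitSpec | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> RepeatabilityResult:
    """Per-population repeatability of one trait over ontogeny.

    Fixed effects are age and sex, plus the within-stage trial sequence
    for traits measured repeatedly within a stage; the individual enters
    as a random intercept.  The random effect is tested against the
    {1/2 chi2_0, 1/2 chi2_1} boundary mixture.
    """
    sub = panel[(panel["population"] == population) & (panel["trait"] == trait)]
    if sub.empty:
        raise ValueError(f"no data for trait {trait!r} in population {population!r}")
    repeated_within_stage = (
        spec.measured_per_stage > 1 if spec is not None else bool((sub["trial"] > 0).any())
    )
    terms = ["intercept", "age_stage", "sex"] + (["trial"] if repeated_within_stage else [])
    fit = fit_univariate_reml(sub, trait, terms, compute_se=True)
    lrt = lrt_from_logliks(
        fit.reml_loglik,
        fit.extra["loglik_null"],
        VARIANCE_MIXTURE,
        df_label="mix(chi2_0, chi2_1)",
    )
    s2i = float(fit.sigma_ind[""][0, 0])
    s2r = float(fit.sigma_res[""][0, 0])
    R, se_R = adjusted_repeatability(fit, trait, population, n_boot=n_boot, seed=seed)
    return RepeatabilityResult(
        trait=trait,
        population=population,
        R=R,
        se_R=se_R,
        sigma_ind=s2i,
        sigma_res=s2r,
        lrt=lrt,
        fit=fit,
    )


def repeatability_table(
    panel: pd.DataFrame,
    traits: Sequence[str],
    populations: Sequence[str] | None = None,
    specs: Sequence[TraitSpec] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Trait x population table of components, repeatability and LRT p.

    Mirrors the layout of a univariate variance-partitioning table:
    fixed-effect estimates (SE), sigma2 (SE) per component, R (SE), and
    the boundary-mixture LRT p-value for the individual effect.
    """
    if populations is None:
        populations = sorted(panel["population"].unique())
    spec_map = {s.trait: s for s in specs} if specs else {}
    rows = []
    for pop in populations:
        for i, trait in enumerate(traits):
            res = fit_trait_repeatability(
                panel, trait, pop, spec_map.get(trait), n_boot=n_boot,
                seed=seed + 1000 * i,
            )
            fit = res.fit
            row = {
                "population": pop,
                "trait": trait,
                "sigma_ind": res.sigma_ind,
                "sigma_ind_se": float(fit.sigma_ind_se[""][0, 0]) if fit.sigma_ind_se[""] is not None else np.nan,
                "sigma_res": res.sigma_res,
                "sigma_res_se": float(fit.sigma_res_se[""][0, 0]) if fit.sigma_res_se[""] is not None else np.nan,
                "repeatability": res.R,
                "repeatability_se": res.se_R,
                "lrt_statistic": res.lrt.statistic,
                "lrt_p": res.lrt.p_value,
            }
            for name, b, se in zip(fit.fixed_names[""], fit.beta[""], fit.beta_se[""]):
                row[f"beta_{name}"] = float(b)
                row[f"beta_{name}_se"] = float(se)
            rows.append(row)
    return pd.DataFrame(rows)
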