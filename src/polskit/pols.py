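"""Among- vs within-individual covariance decomposition and POLS tests.

A pace-of-life syndrome (POLS) shows up as non-zero among-individual
covariance between life-history, behavioural and physiological traits.
This module fits the multivariate individual-random-intercept model to
the repeatable trait set, derives among-individual and residual
correlation matrices, and runs the likelihood-ratio tests:

* per covariance element: full model vs the same model with that single
  among-individual covariance fixed to zero (covariances are unbounded,
  so the reference is a plain chi2 with 1 df);
* per trait: among-individual variance plus all its covariances removed
  (boundary mixture {1/2 chi2_k, 1/2 chi2_{k+1}} with k the number of
  covariances dropped);
* overall structure: all among-individual covariances zero, chi2 with
  one df per trait pair;
* population equality: pairwise among-individual covariances constrained
  equal across two populations, chi2 with one df per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .lmm import (
    BlockDiagonal,
    DropTrait,
    IndependentMap,
    MixedModelFit,
    ModelSpec,
    PairZero,
    SharedCovMap,
    Unstructured,
    Diagonal,
    _make_blocks,
    _fit_from_map,
    _moment_start,
    fit_reml,
)
from .repeatability import LRTResult, lrt_from_logliks

__all__ = [
    "CovarianceDecomposition",
    "decompose",
    "test_variance_and_covariance",
    "test_population_equality",
    "test_overall_structure",
]


@dataclass
class CovarianceDecomposition:
    population: str
    traits: list[str]
    sigma_ind: np.ndarray
    sigma_res: np.ndarray
    sigma_ind_se: np.ndarray | None
    sigma_res_se: np.ndarray | None
    corr_ind: np.ndarray
    corr_res: np.ndarray
    corr_ind_se: np.ndarray | None
    corr_res_se: np.ndarray | None
    per_element_lrt: dict[tuple[str, str], LRTResult]
    fixed_zero_residual_pairs: list[tuple[str, str]]
    fit: MixedModelFit = field(repr=False, default=None)

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "population": self.population,
            "traits": self.traits,
            "sigma_ind": arr(self.sigma_ind),
            "sigma_res": arr(self.sigma_res),
            "sigma_ind_se": arr(self.sigma_ind_se),
            "sigma_res_se": arr(self.sigma_res_se),
            "corr_ind": arr(self.corr_ind),
            "corr_res": arr(self.corr_res),
            "corr_ind_se": arr(self.corr_ind_se),
            "corr_res_se": arr(self.corr_res_se),
            "per_element_lrt": {
                f"{a}~{b}": r.to_dict() for (a, b), r in self.per_element_lrt.items()
            },
            "fixed_zero_residual_pairs": [list(p) for p in self.fixed_zero_residual_pairs],
        }

    def report(self) -> str:
        """Plain-text pairwise among-individual correlation report."""
        lines = [f"Among-individual correlations — population {self.population}"]
        q = len(self.traits)
        for i in range(q):
            for j in range(i + 1, q):
                r = self.corr_ind[i, j]
                se = self.corr_ind_se[i, j] if self.corr_ind_se is not None else np.nan
                lrt = self.per_element_lrt.get((self.traits[i], self.traits[j]))
                flag = "*" if lrt is not None and lrt.p_value < 0.05 else " "
                p = lrt.p_value if lrt is not None else np.nan
                lines.append(
                    f"  {self.traits[i]:>16s} ~ {self.traits[j]:<16s} "
                    f"r = {r:+.3f} (SE {se:.3f}) p = {p:.4f}{flag}"
                )
        return "\n".join(lines)


def _pols_terms(panel: pd.DataFrame, traits: Sequence[str]) -> dict[str, list[str]]:
    terms = {}
    for t in traits:
        rows = panel[panel["trait"] == t]
        has_trial = bool((rows["trial"] > 0).any())
        terms[t] = ["intercept", "age_stage", "sex"] + (["trial"] if has_trial else [])
    return terms


def _pols_spec(panel, traits, groups=None, among="unstructured"):
    return ModelSpec(
        responses=list(traits),
        fixed_terms=_pols_terms(panel, traits),
        among_structure=among,
        residual_structure="auto",
        groups=groups,
    )


def _corr_from_cov(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(S), 1e-300, None))
    C = S / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def _bootstrap_corr_se(fit: MixedModelFit, group_index: int, q: int, n_boot: int, seed: int):
    """Parametric bootstrap SEs of both correlation matrices from the
    asymptotic distribution of the variance parameters."""
    pmap = fit.extra.get("param_map")
    if pmap is None or fit.theta is None or fit.theta_cov is None:
        return None, None
    cov = fit.theta_cov
    if not np.all(np.isfinite(cov)):
        return None, None
    # symmetrize and project to PSD for sampling
    cov = 0.5 * (cov + cov.T)
    w, U = np.linalg.eigh(cov)
    cov = (U * np.maximum(w, 0.0)) @ U.T
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.theta, cov, size=n_boot)
    ci_samples, cr_samples = [], []
    for th in draws:
        try:
            Si, Sr, _ = pmap.unpack(th)[group_index]
        except Exception:
            continue
        if np.any(np.diag(Si) <= 0) or np.any(np.diag(Sr) <= 0):
            continue
        ci_samples.append(_corr_from_cov(Si))
        cr_samples.append(_corr_from_cov(Sr))
    if len(ci_samples) < 10:
        return None, None
    return (
        np.std(np.stack(ci_samples), axis=0, ddof=1),
        np.std(np.stack(cr_samples), axis=0, ddof=1),
    )


def decompose(
    panel: pd.DataFrame,
    traits: Sequence[str],
    population: str | None = None,
    element_tests: bool = True,
    compute_se: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
    n_restarts: int = 3,
) -> CovarianceDecomposition:
    """Among-individual vs residual covariance for one population.

    Fits the unstructured multivariate model, derives correlation
    matrices, and (optionally) tests every among-individual covariance
    element with a chi2(1) likelihood-ratio test against the model with
    that element fixed to zero.  Residual covariances between traits that
    are never measured on a common occasion are structurally zero and are
    reported as such, not tested.
    """
    traits = list(traits)
    sub = panel if population is None else panel[panel["population"] == population]
    if sub.empty:
        raise ValueError(f"no data for population {population!r}")
    spec = _pols_spec(sub, traits)
    fit = fit_reml(sub, spec, compute_se=compute_se, n_restarts=n_restarts)
    g = fit.groups[0]
    Si, Sr = fit.sigma_ind[g], fit.sigma_res[g]
    corr_i, corr_r = _corr_from_cov(Si), _corr_from_cov(Sr)
    ci_se = cr_se = None
    if compute_se:
        ci_se, cr_se = _bootstrap_corr_se(fit, 0, len(traits), n_boot, seed)

    elements: dict[tuple[str, str], LRTResult] = {}
    if element_tests:
        blocks = _make_blocks(sub, spec)
        for i in range(len(traits)):
            for j in range(i + 1, len(traits)):
                pmap = IndependentMap(
                    [(PairZero(len(traits), (i, j)), _resolve_res(spec, blocks[0]))]
                )
                theta0 = pmap.init([_moment_start(blocks[0])])
                red = _fit_from_map(blocks, pmap, theta0, False, n_restarts, 1000)
                elements[(traits[i], traits[j])] = lrt_from_logliks(
                    fit.reml_loglik, red.reml_loglik, ((1.0, 1),), df_label="chi2_1"
                )
    return CovarianceDecomposition(
        population=population if population is not None else "pooled",
        traits=traits,
        sigma_ind=Si,
        sigma_res=Sr,
        sigma_ind_se=fit.sigma_ind_se[g],
        sigma_res_se=fit.sigma_res_se[g],
        corr_ind=corr_i,
        corr_res=corr_r,
        corr_ind_se=ci_se,
        corr_res_se=cr_se,
        per_element_lrt=elements,
        fixed_zero_residual_pairs=fit.block_info[g].get("fixed_zero_residual_pairs", []),
        fit=fit,
    )


def _resolve_res(spec: ModelSpec, block) -> object:
    q = len(spec.responses)
    if spec.residual_structure == "auto":
        return BlockDiagonal(q, block.res_groups)
    if spec.residual_structure == "unstructured":
        return Unstructured(q)
    if spec.residual_structure == "diagonal":
        return Diagonal(q)
    return spec.residual_structure


def test_variance_and_covariance(
    panel: pd.DataFrame,
    traits: Sequence[str],
    target_trait: str,
    population: str | None = None,
    n_restarts: int = 3,
    full_fit: MixedModelFit | None = None,
) -> LRTResult:
    """Test one trait's among-individual variance together with its
    covariances: full model vs the model with that trait's row/column of
    the among matrix removed.

    The removed set contains one bounded variance and k = q-1 unbounded
    covariances, so the reference is the equal boundary mixture
    {1/2 chi2_k, 1/2 chi2_{k+1}} (for two traits: {1/2 chi2_1, 1/2 chi2_2}).
    """
    traits = list(traits)
    if target_trait not in traits:
        raise ValueError(f"target trait {target_trait!r} not in {traits}")
    sub = panel if population is None else panel[panel["population"] == population]
    spec = _pols_spec(sub, traits)
    if full_fit is None:
        full_fit = fit_reml(sub, spec, n_restarts=n_restarts)
    blocks = _make_blocks(sub, spec)
    q = len(traits)
    pmap = IndependentMap(
        [(DropTrait(q, traits.index(target_trait)), _resolve_res(spec, blocks[0]))]
    )
    theta0 = pmap.init([_moment_start(blocks[0])])
    red = _fit_from_map(blocks, pmap, theta0, False, n_restarts, 1000)
    k = q - 1
    return lrt_from_logliks(
        full_fit.reml_loglik,
        red.reml_loglik,
        ((0.5, k), (0.5, k + 1)),
        df_label=f"mix(chi2_{k}, chi2_{k + 1})",
    )


def test_overall_structure(
    panel: pd.DataFrame,
    traits: Sequence[str],
    population: str | None = None,
    n_restarts: int = 3,
    full_fit: MixedModelFit | None = None,
) -> LRTResult:
    """Overall POLS test: all among-individual covariances zero at once.

    Full model vs diagonal among-individual matrix (variances stay free);
    the reference is chi2 with one df per trait pair (6 for four traits).
    """
    traits = list(traits)
    sub = panel if population is None else panel[panel["population"] == population]
    spec = _pols_spec(sub, traits)
    if full_fit is None:
        full_fit = fit_reml(sub, spec, n_restarts=n_restarts)
    blocks = _make_blocks(sub, spec)
    q = len(traits)
    pmap = IndependentMap([(Diagonal(q), _resolve_res(spec, blocks[0]))])
    theta0 = pmap.init([_moment_start(blocks[0])])
    red = _fit_from_map(blocks, pmap, theta0, False, n_restarts, 1000)
    npairs = q * (q - 1) // 2
    return lrt_from_logliks(
        full_fit.reml_loglik, red.reml_loglik, ((1.0, npairs),), df_label=f"chi2_{npairs}"
    )


def test_population_equality(
    panel: pd.DataFrame,
    traits: Sequence[str],
    n_restarts: int = 3,
) -> LRTResult:
    """Do the two populations share their among-individual covariances?

    The joint two-population model keeps population-specific mean
    structures, among-individual variances and residual structures
    throughout; the constrained model additionally ties each pairwise
    among-individual covariance to be equal across populations, so the
    two fits differ by exactly one parameter per trait pair and the
    reference is chi2 with that many df.
    """
    traits = list(traits)
    pops = sorted(panel["population"].unique())
    if len(pops) != 2:
        raise ValueError(f"need exactly 2 populations, found {pops}")
    for pop in pops:
        have = set(panel.loc[panel["population"] == pop, "trait"])
        missing = set(traits) - have
        if missing:
            raise ValueError(f"population {pop!r} lacks trait(s) {sorted(missing)}")
    spec = _pols_spec(panel, traits, groups="population")
    blocks = _make_blocks(panel, spec)
    q = len(traits)
    starts = [_moment_start(b) for b in blocks]

    full_map = IndependentMap(
        [(Unstructured(q), _resolve_res(spec, b)) for b in blocks]
    )
    full = _fit_from_map(blocks, full_map, full_map.init(starts), False, n_restarts, 1000)

    shared_map = SharedCovMap(q, [_resolve_res(spec, b) for b in blocks])
    red = _fit_from_map(blocks, shared_map, shared_map.init(starts), False, n_restarts, 1500)

    npairs = q * (q - 1) // 2
    return lrt_from_logliks(
        full.reml_loglik, red.reml_loglik, ((1.0, npairs),), df_label=f"chi2_{npairs}"
    )
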