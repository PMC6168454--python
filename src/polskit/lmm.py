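"""Restricted-maximum-likelihood engine for linear and mixed models.

Implements the model family behind repeatability and among-individual
covariance decomposition:

    y_i = X_i beta + Z_i u_i + e_i,   u_i ~ MVN(0, Sigma_ind),
                                      e_i ~ blockwise MVN(0, Sigma_res)

where ``u_i`` is an individual's latent trait vector (random intercepts,
one per response trait) and residuals are correlated only between traits
measured on the same occasion.  The restricted log-likelihood

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ]

is maximized over the variance parameters with fixed effects profiled out
by generalized least squares.  Three paths are provided:

* ordinary least squares (no random term),
* a fast univariate random-intercept path that profiles the variance
  ratio lambda = sigma2_ind / sigma2_res down to a 1-D search, with the
  boundary lambda = 0 included in the search space,
* a general multivariate path on the log-Cholesky scale supporting
  unstructured, diagonal, single-element-zero, dropped-trait and
  block-diagonal covariance structures, and joint multi-group fits with
  group-specific mean structures.

Wald F statistics for fixed effects use a containment-style denominator
degrees of freedom, df = n_obs - rank(X) - n_individuals + 1, recorded on
the fit so reported p-values are reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "fit_lm",
    "fit_reml",
    "wald_f_test",
    "Unstructured",
    "Diagonal",
    "PairZero",
    "DropTrait",
    "BlockDiagonal",
]

_LOG_CHOL_MIN = math.log(1e-10)  # lower bound on Cholesky diagonal entries
_BOUNDARY_CHOL = 1e-9  # within 10x the bound counts as "at boundary"
_BASE_TERMS = ("intercept", "age_stage", "sex", "trial", "population")


# ---------------------------------------------------------------------------
# covariance structures (theta -> Sigma)


class Unstructured:
    """Full covariance via log-Cholesky: diagonal of L on the log scale."""

    smooth = True

    def __init__(self, q: int):
        self.q = q
        self.n_params = q * (q + 1) // 2
        self._rows, self._cols = np.tril_indices(q)
        self._is_diag = self._rows == self._cols

    def build(self, theta: np.ndarray) -> tuple[np.ndarray, float]:
        L = np.zeros((self.q, self.q))
        vals = np.asarray(theta, dtype=float).copy()
        vals[self._is_diag] = np.exp(np.clip(vals[self._is_diag], _LOG_CHOL_MIN, 50.0))
        L[self._rows, self._cols] = vals
        return L @ L.T, 0.0

    def init(self, S: np.ndarray) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        L = np.linalg.cholesky(S + 1e-8 * np.eye(self.q))
        vals = L[self._rows, self._cols]
        out = vals.copy()
        out[self._is_diag] = np.log(np.maximum(vals[self._is_diag], 1e-8))
        return out

    def bounds(self) -> list[tuple]:
        return [(_LOG_CHOL_MIN, None) if d else (None, None) for d in self._is_diag]

    def at_boundary(self, theta: np.ndarray) -> bool:
        return bool(np.any(np.exp(np.asarray(theta)[self._is_diag]) < _BOUNDARY_CHOL))


class Diagonal:
    """Independent traits: log variances only (all covariances zero)."""

    smooth = True

    def __init__(self, q: int):
        self.q = q
        self.n_params = q

    def build(self, theta):
        return np.diag(np.exp(np.asarray(theta, dtype=float))), 0.0

    def init(self, S):
        return np.log(np.maximum(np.diag(np.asarray(S, dtype=float)), 1e-8))

    def bounds(self):
        return [(2 * _LOG_CHOL_MIN, None)] * self.q

    def at_boundary(self, theta):
        return bool(np.any(np.exp(np.asarray(theta)) < _BOUNDARY_CHOL**2))


class PairZero:
    """Unstructured except one covariance element fixed to zero.

    The constrained pair is permuted to the leading 2x2 block, where
    Sigma[0,1] = 0 is exactly equivalent to L[1,0] = 0 in the Cholesky
    factor, keeping the parameterization smooth and positive definite.
    """

    smooth = True

    def __init__(self, q: int, pair: tuple[int, int]):
        a, b = pair
        if a == b or not (0 <= a < q and 0 <= b < q):
            raise ValueError(f"invalid trait pair {pair} for {q} traits")
        self.q = q
        self.pair = (min(a, b), max(a, b))
        order = [self.pair[0], self.pair[1]] + [
            i for i in range(q) if i not in self.pair
        ]
        self.order = np.array(order)
        self._inner = Unstructured(q)
        # position of L[1,0] in the lower-triangle parameter vector
        self._drop = 1  # row 1, col 0 is the second lower-tri element
        self.n_params = self._inner.n_params - 1

    def _expand(self, theta):
        full = np.insert(np.asarray(theta, dtype=float), self._drop, 0.0)
        return full

    def build(self, theta):
        S_perm, _ = self._inner.build(self._expand(theta))
        S = np.empty_like(S_perm)
        S[np.ix_(self.order, self.order)] = S_perm
        return S, 0.0

    def init(self, S):
        S_perm = np.asarray(S, dtype=float)[np.ix_(self.order, self.order)]
        full = self._inner.init(S_perm)
        return np.delete(full, self._drop)

    def bounds(self):
        return [
            b for i, b in enumerate(self._inner.bounds()) if i != self._drop
        ]

    def at_boundary(self, theta):
        return self._inner.at_boundary(self._expand(theta))


class DropTrait:
    """One trait's variance and all its covariances fixed to zero."""

    smooth = True

    def __init__(self, q: int, drop: int):
        self.q = q
        self.drop = drop
        self.keep = [i for i in range(q) if i != drop]
        self._inner = Unstructured(q - 1)
        self.n_params = self._inner.n_params

    def build(self, theta):
        S_small, _ = self._inner.build(theta)
        S = np.zeros((self.q, self.q))
        S[np.ix_(self.keep, self.keep)] = S_small
        return S, 0.0

    def init(self, S):
        return self._inner.init(np.asarray(S, dtype=float)[np.ix_(self.keep, self.keep)])

    def bounds(self):
        return self._inner.bounds()

    def at_boundary(self, theta):
        return self._inner.at_boundary(theta)


class BlockDiagonal:
    """Unstructured blocks on disjoint trait groups, zero elsewhere.

    Used for the residual covariance when some trait pairs are never
    measured on a common occasion: their residual covariance is not
    estimable and is structurally fixed to zero.
    """

    smooth = True

    def __init__(self, q: int, groups: Sequence[Sequence[int]]):
        flat = [i for g in groups for i in g]
        if sorted(flat) != list(range(q)):
            raise ValueError("groups must partition the trait indices")
        self.q = q
        self.groups = [list(g) for g in groups]
        self._inner = [Unstructured(len(g)) for g in self.groups]
        self.n_params = sum(s.n_params for s in self._inner)

    def _slices(self):
        off = 0
        for s in self._inner:
            yield slice(off, off + s.n_params), s
            off += s.n_params

    def build(self, theta):
        S = np.zeros((self.q, self.q))
        for (sl, s), g in zip(self._slices(), self.groups):
            S[np.ix_(g, g)] = s.build(np.asarray(theta)[sl])[0]
        return S, 0.0

    def init(self, S):
        S = np.asarray(S, dtype=float)
        return np.concatenate(
            [s.init(S[np.ix_(g, g)]) for (_, s), g in zip(self._slices(), self.groups)]
        )

    def bounds(self):
        return [b for _, s in self._slices() for b in s.bounds()]

    def at_boundary(self, theta):
        return any(
            s.at_boundary(np.asarray(theta)[sl]) for sl, s in self._slices()
        )


# ---------------------------------------------------------------------------
# parameter maps (theta -> per-group (Sigma_ind, Sigma_res))


class IndependentMap:
    """Each group has its own among/residual structures; disjoint slices."""

    def __init__(self, items: Sequence[tuple]):
        self.items = list(items)
        self.n_params = sum(si.n_params + sr.n_params for si, sr in self.items)
        self.smooth = all(si.smooth and sr.smooth for si, sr in self.items)

    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        out, off = [], 0
        for si, sr in self.items:
            Si, v1 = si.build(theta[off : off + si.n_params])
            off += si.n_params
            Sr, v2 = sr.build(theta[off : off + sr.n_params])
            off += sr.n_params
            out.append((Si, Sr, v1 + v2))
        return out

    def init(self, starts: Sequence[tuple[np.ndarray, np.ndarray]]):
        parts = []
        for (si, sr), (Si0, Sr0) in zip(self.items, starts):
            parts.append(si.init(Si0))
            parts.append(sr.init(Sr0))
        return np.concatenate(parts)

    def bounds(self):
        out = []
        for si, sr in self.items:
            out.extend(si.bounds())
            out.extend(sr.bounds())
        return out

    def at_boundary(self, theta):
        theta = np.asarray(theta, dtype=float)
        off, flags = 0, []
        for si, sr in self.items:
            flags.append(si.at_boundary(theta[off : off + si.n_params]))
            off += si.n_params + sr.n_params
        return any(flags)


class SharedCovMap:
    """Two groups share among-individual covariances; variances differ.

    theta = [log var_g1 (q), log var_g2 (q), shared covariances (q(q-1)/2),
    residual structure params per group].  Positive definiteness of each
    group's among matrix is enforced by an eigenvalue clip plus a smooth
    penalty on the violation, since a direct-element parameterization with
    cross-group ties has no exact Cholesky form.
    """

    def __init__(self, q: int, res_structs: Sequence):
        self.q = q
        self.npairs = q * (q - 1) // 2
        self.res_structs = list(res_structs)
        self.n_params = 2 * q + self.npairs + sum(s.n_params for s in self.res_structs)
        self.smooth = True
        self._iu = np.triu_indices(q, k=1)

    def _among(self, logvar, covs):
        S = np.zeros((self.q, self.q))
        S[self._iu] = covs
        S = S + S.T + np.diag(np.exp(logvar))
        w, U = np.linalg.eigh(S)
        viol = float(max(0.0, 1e-10 - w.min()))
        if viol > 0:
            S = (U * np.maximum(w, 1e-10)) @ U.T
        return S, viol

    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        q, npairs = self.q, self.npairs
        covs = theta[2 * q : 2 * q + npairs]
        off = 2 * q + npairs
        out = []
        for g, sres in enumerate(self.res_structs):
            Si, viol = self._among(theta[g * q : (g + 1) * q], covs)
            Sr, v2 = sres.build(theta[off : off + sres.n_params])
            off += sres.n_params
            out.append((Si, Sr, viol + v2))
        return out

    def init(self, starts):
        (Si1, Sr1), (Si2, Sr2) = starts
        covs = 0.5 * (Si1 + Si2)[self._iu] * 0.8  # shrink toward zero for PD safety
        parts = [
            np.log(np.maximum(np.diag(Si1), 1e-8)),
            np.log(np.maximum(np.diag(Si2), 1e-8)),
            covs,
            self.res_structs[0].init(Sr1),
            self.res_structs[1].init(Sr2),
        ]
        return np.concatenate(parts)

    def bounds(self):
        out = [(2 * _LOG_CHOL_MIN, None)] * (2 * self.q)
        out += [(None, None)] * self.npairs
        for s in self.res_structs:
            out.extend(s.bounds())
        return out

    def at_boundary(self, theta):
        theta = np.asarray(theta, dtype=float)
        return bool(np.any(np.exp(theta[: 2 * self.q]) < _BOUNDARY_CHOL**2))


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _Pattern:
    t_idx: np.ndarray  # trait index per row (n_i,)
    occ_same: np.ndarray  # (n_i, n_i) bool, same-occasion mask
    X: np.ndarray  # (m, n_i, p)
    y: np.ndarray  # (m, n_i)
    ind_labels: list


@dataclass
class _Block:
    label: str
    responses: list[str]
    fixed_names: list[str]
    patterns: list[_Pattern]
    n_obs: int
    n_individuals: int
    rank_x: int
    fixed_zero_residual_pairs: list[tuple[str, str]]
    res_groups: list[list[int]]


def _term_column(rows: pd.DataFrame, term: str, trial_center: float, pop_code: float):
    if term == "intercept":
        return np.ones(len(rows))
    if term == "trial":
        return rows["trial"].to_numpy(dtype=float) - trial_center
    if term == "population":
        return np.full(len(rows), pop_code)
    if term in rows.columns:
        return rows[term].to_numpy(dtype=float)
    raise ValueError(f"fixed-effect term {term!r} not found in panel columns")


def prepare_block(
    panel: pd.DataFrame,
    responses: Sequence[str],
    fixed_terms: Mapping[str, Sequence[str]],
    label: str = "",
    pop_code: float = 0.0,
) -> _Block:
    """Index a long panel into per-individual design/response arrays.

    Rows are grouped by identical (trait layout, occasion layout) pattern
    so the marginal covariance V is assembled and factorized once per
    pattern per likelihood evaluation.
    """
    df = panel[panel["trait"].isin(responses)].dropna(subset=["value"]).copy()
    if df.empty:
        raise ValueError(f"no observations for responses {list(responses)}")
    responses = list(responses)
    t_map = {t: i for i, t in enumerate(responses)}
    df["_t"] = df["trait"].map(t_map)
    df = df.sort_values(["individual_id", "age_stage", "trial", "_t"], kind="mergesort")

    # centred trial covariate, computed over rows of repeat-measured traits
    rep_rows = df["trial"] > 0
    trial_center = float(df.loc[rep_rows, "trial"].mean()) if rep_rows.any() else 0.0

    fixed_names, col_of = [], {}
    for r in responses:
        for term in fixed_terms[r]:
            col_of[(r, term)] = len(fixed_names)
            fixed_names.append(f"{r}:{term}" if len(responses) > 1 else term)
    p = len(fixed_names)

    X = np.zeros((len(df), p))
    for r in responses:
        mask = (df["trait"] == r).to_numpy()
        sub = df[df["trait"] == r]
        for term in fixed_terms[r]:
            X[mask, col_of[(r, term)]] = _term_column(sub, term, trial_center, pop_code)
    y = df["value"].to_numpy(dtype=float)

    occ_key = pd.factorize(
        pd.MultiIndex.from_arrays([df["age_stage"], df["trial"]]).to_numpy()
    )[0]
    t_arr = df["_t"].to_numpy()
    ind_codes, ind_labels = pd.factorize(df["individual_id"].to_numpy())

    # residual estimability: traits co-observed on at least one occasion
    co = np.zeros((len(responses), len(responses)), dtype=bool)
    occ_global = pd.factorize(
        pd.MultiIndex.from_arrays([df["individual_id"], df["age_stage"], df["trial"]]).to_numpy()
    )[0]
    for _, grp in pd.DataFrame({"occ": occ_global, "t": t_arr}).groupby("occ"):
        ts = grp["t"].to_numpy()
        co[np.ix_(ts, ts)] = True
    res_groups = _connected_components(co)
    fixed_zero = [
        (responses[i], responses[j])
        for i in range(len(responses))
        for j in range(i + 1, len(responses))
        if not co[i, j]
    ]

    # group individuals by pattern
    buckets: dict[tuple, list[int]] = {}
    spans: dict[int, tuple[int, int]] = {}
    for ind in range(len(ind_labels)):
        idx = np.flatnonzero(ind_codes == ind)
        spans[ind] = (idx[0], idx[-1] + 1)
    for ind, (a, b) in spans.items():
        occ_local = occ_key[a:b]
        occ_norm = tuple(pd.factorize(occ_local)[0])
        key = (tuple(t_arr[a:b]), occ_norm)
        buckets.setdefault(key, []).append(ind)

    patterns = []
    for (t_key, occ_norm), inds in buckets.items():
        t_idx = np.array(t_key)
        occ = np.array(occ_norm)
        occ_same = occ[:, None] == occ[None, :]
        Xs = np.stack([X[spans[i][0] : spans[i][1]] for i in inds])
        ys = np.stack([y[spans[i][0] : spans[i][1]] for i in inds])
        patterns.append(_Pattern(t_idx, occ_same, Xs, ys, [ind_labels[i] for i in inds]))

    rank_x = int(np.linalg.matrix_rank(X))
    if rank_x < p:
        raise ValueError(
            f"rank-deficient fixed-effect design ({rank_x} < {p}); "
            f"check for aliased terms among {fixed_names}"
        )
    return _Block(
        label=label,
        responses=responses,
        fixed_names=fixed_names,
        patterns=patterns,
        n_obs=len(df),
        n_individuals=len(ind_labels),
        rank_x=rank_x,
        fixed_zero_residual_pairs=fixed_zero,
        res_groups=res_groups,
    )


def _connected_components(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], []
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(np.flatnonzero(adj[v]).tolist())
        comps.append(sorted(comp))
    return comps


# ---------------------------------------------------------------------------
# restricted likelihood


def _block_cross_products(block: _Block, Si: np.ndarray, Sr: np.ndarray):
    """Accumulate GLS cross-products and log|V| over all individuals."""
    p = len(block.fixed_names)
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for pat in block.patterns:
        t = pat.t_idx
        V = Si[np.ix_(t, t)] + np.where(pat.occ_same, Sr[np.ix_(t, t)], 0.0)
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return None
        m = pat.X.shape[0]
        logdet += m * 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = cho_solve((c, low), np.eye(len(t)))
        XtViX += np.einsum("mip,ij,mjq->pq", pat.X, Vinv, pat.X, optimize=True)
        XtViy += np.einsum("mip,ij,mj->p", pat.X, Vinv, pat.y, optimize=True)
        ytViy += float(np.einsum("mi,ij,mj->", pat.y, Vinv, pat.y, optimize=True))
    return XtViX, XtViy, ytViy, logdet


def _block_reml_loglik(block: _Block, Si: np.ndarray, Sr: np.ndarray):
    out = _block_cross_products(block, Si, Sr)
    if out is None:
        return None
    XtViX, XtViy, ytViy, logdet = out
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - float(XtViy @ beta)
    n, p = block.n_obs, len(block.fixed_names)
    return -0.5 * ((n - p) * math.log(2 * math.pi) + logdet + logdet_x + quad)


def _block_gls(block: _Block, Si: np.ndarray, Sr: np.ndarray):
    XtViX, XtViy, _, _ = _block_cross_products(block, Si, Sr)
    beta_cov = np.linalg.inv(XtViX)
    beta = beta_cov @ XtViy
    return beta, beta_cov


# ---------------------------------------------------------------------------
# fit result container


@dataclass
class ModelSpec:
    """Declarative model description for :func:`fit_reml`.

    ``fixed_terms`` may be a single list (shared by all responses) or a
    mapping response -> term list.  ``among_structure`` and
    ``residual_structure`` accept the strings ``unstructured``,
    ``diagonal`` or ``auto`` (residual only: block-diagonal over trait
    sets that share occasions), or a structure object.
    """

    responses: Sequence[str]
    fixed_terms: Sequence[str] | Mapping[str, Sequence[str]] = ("intercept",)
    random_intercept: str | None = "individual_id"
    among_structure: object = "unstructured"
    residual_structure: object = "auto"
    groups: str | None = None  # e.g. "population": one block per level

    def terms_for(self, response: str) -> list[str]:
        if isinstance(self.fixed_terms, Mapping):
            return list(self.fixed_terms[response])
        return list(self.fixed_terms)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model-spec key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml
        from pathlib import Path

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class MixedModelFit:
    """Fixed effects, variance components and REML log-likelihood."""

    responses: list[str]
    groups: list[str]
    fixed_names: dict[str, list[str]]
    beta: dict[str, np.ndarray]
    beta_se: dict[str, np.ndarray]
    beta_cov: dict[str, np.ndarray]
    sigma_ind: dict[str, np.ndarray]
    sigma_res: dict[str, np.ndarray]
    sigma_ind_se: dict[str, np.ndarray | None]
    sigma_res_se: dict[str, np.ndarray | None]
    reml_loglik: float
    n_parameters: int
    converged: bool
    n_obs: int
    n_individuals: int
    at_boundary: bool = False
    df_method: str = "containment"
    block_info: dict[str, dict] = field(default_factory=dict)
    theta: np.ndarray | None = None
    theta_cov: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def single(self, key: str, group: str | None = None):
        g = group if group is not None else self.groups[0]
        return getattr(self, key)[g]

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "responses": self.responses,
            "groups": self.groups,
            "fixed_names": self.fixed_names,
            "beta": {g: arr(v) for g, v in self.beta.items()},
            "beta_se": {g: arr(v) for g, v in self.beta_se.items()},
            "sigma_ind": {g: arr(v) for g, v in self.sigma_ind.items()},
            "sigma_res": {g: arr(v) for g, v in self.sigma_res.items()},
            "sigma_ind_se": {g: arr(v) for g, v in self.sigma_ind_se.items()},
            "sigma_res_se": {g: arr(v) for g, v in self.sigma_res_se.items()},
            "reml_loglik": self.reml_loglik,
            "n_parameters": self.n_parameters,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_individuals": self.n_individuals,
            "at_boundary": self.at_boundary,
            "df_method": self.df_method,
            "block_info": self.block_info,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "MixedModelFit":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        return cls(
            responses=d["responses"],
            groups=d["groups"],
            fixed_names=d["fixed_names"],
            beta={g: arr(v) for g, v in d["beta"].items()},
            beta_se={g: arr(v) for g, v in d["beta_se"].items()},
            beta_cov={g: None for g in d["groups"]},
            sigma_ind={g: arr(v) for g, v in d["sigma_ind"].items()},
            sigma_res={g: arr(v) for g, v in d["sigma_res"].items()},
            sigma_ind_se={g: arr(v) for g, v in d["sigma_ind_se"].items()},
            sigma_res_se={g: arr(v) for g, v in d["sigma_res_se"].items()},
            reml_loglik=d["reml_loglik"],
            n_parameters=d["n_parameters"],
            converged=d["converged"],
            n_obs=d["n_obs"],
            n_individuals=d["n_individuals"],
            at_boundary=d["at_boundary"],
            df_method=d.get("df_method", "containment"),
            block_info=d.get("block_info", {}),
        )


# ---------------------------------------------------------------------------
# ordinary least squares (no random term)


def fit_lm(
    panel: pd.DataFrame,
    response: str,
    fixed_terms: Sequence[str] = ("intercept", "population"),
) -> MixedModelFit:
    """Ordinary least-squares fit of one response on the given terms.

    Population is coded -0.5/+0.5 in label-sorted order; the coefficient
    of ``population`` therefore equals the difference between group means
    in a two-group design.  t-based p-values live in ``extra['p_values']``.
    """
    df = panel[panel["trait"] == response].dropna(subset=["value"])
    if df.empty:
        raise ValueError(f"no observations for response {response!r}")
    pops = sorted(df["population"].unique())
    pop_codes = {p: c for p, c in zip(pops, np.linspace(-0.5, 0.5, max(len(pops), 2))[: len(pops)])}
    rep = df["trial"] > 0
    trial_center = float(df.loc[rep, "trial"].mean()) if rep.any() else 0.0
    cols = []
    for term in fixed_terms:
        if term == "population":
            cols.append(df["population"].map(pop_codes).to_numpy(dtype=float))
        else:
            cols.append(_term_column(df, term, trial_center, 0.0))
    X = np.column_stack(cols)
    y = df["value"].to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify aliased columns by testing rank drop
        aliased = []
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                aliased.append(fixed_terms[j])
        raise ValueError(f"rank-deficient design; aliased column(s): {aliased}")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    s2 = float(resid @ resid) / (n - p)
    beta_cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(beta_cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n - p)
    # REML convention (matches the mixed-model paths): with V = s2*I,
    # log|V| + log|X'V^-1 X| = (n-p) log s2 + log|X'X|.
    sign, logdet_xtx = np.linalg.slogdet(XtX)
    ll = -0.5 * (
        (n - p) * math.log(2 * math.pi)
        + (n - p) * math.log(s2)
        + logdet_xtx
        + (n - p)
    )
    g = ""
    return MixedModelFit(
        responses=[response],
        groups=[g],
        fixed_names={g: list(fixed_terms)},
        beta={g: beta},
        beta_se={g: se},
        beta_cov={g: beta_cov},
        sigma_ind={g: np.zeros((1, 1))},
        sigma_res={g: np.array([[s2]])},
        sigma_ind_se={g: None},
        sigma_res_se={g: np.array([[s2 * math.sqrt(2.0 / (n - p))]])},
        reml_loglik=ll,
        n_parameters=1,
        converged=True,
        n_obs=n,
        n_individuals=n,
        df_method="residual",
        block_info={g: {"n_obs": n, "n_individuals": n, "rank_x": int(rank)}},
        extra={"p_values": {t: float(pv) for t, pv in zip(fixed_terms, pvals)},
               "t_values": {t: float(tv) for t, tv in zip(fixed_terms, tvals)},
               "population_codes": pop_codes},
    )


# ---------------------------------------------------------------------------
# fast univariate random-intercept path


def _univariate_arrays(panel, response, fixed_terms, pop_codes=None):
    df = panel[panel["trait"] == response].dropna(subset=["value"]).copy()
    if df.empty:
        raise ValueError(f"no observations for response {response!r}")
    rep = df["trial"] > 0
    trial_center = float(df.loc[rep, "trial"].mean()) if rep.any() else 0.0
    cols = []
    for term in fixed_terms:
        if term == "population":
            cols.append(df["population"].map(pop_codes).to_numpy(dtype=float))
        else:
            cols.append(_term_column(df, term, trial_center, 0.0))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = [
            t for j, t in enumerate(fixed_terms)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"rank-deficient fixed-effect design; aliased term(s): {aliased}")
    y = df["value"].to_numpy(dtype=float)
    codes, labels = pd.factorize(df["individual_id"].to_numpy())
    return X, y, codes, len(labels)


class _UnivariateREML:
    """Profile REML over lambda = sigma2_ind / sigma2_res.

    With V_i = sigma2 (I + lambda J_i), both sigma2 and beta have closed
    forms given lambda, reducing the fit to a 1-D bounded search that
    includes the boundary lambda = 0.
    """

    def __init__(self, X, y, ind_codes, n_ind):
        self.X, self.y = X, y
        self.n, self.p = X.shape
        self.n_ind = n_ind
        m = n_ind
        self.k = np.bincount(ind_codes, minlength=m).astype(float)
        p = self.p
        self.A = np.zeros((m, p))  # a_i = X_i' 1
        np.add.at(self.A, ind_codes, X)
        self.b = np.bincount(ind_codes, weights=y, minlength=m)  # b_i = y_i' 1
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _parts(self, lam):
        w = lam / (1.0 + lam * self.k)
        XtViX = self.XtX - (self.A * w[:, None]).T @ self.A
        XtViy = self.Xty - self.A.T @ (w * self.b)
        ytViy = self.yty - float(w @ (self.b**2))
        return XtViX, XtViy, ytViy

    def loglik(self, lam):
        XtViX, XtViy, ytViy = self._parts(lam)
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf, np.nan, None, None
        beta = np.linalg.solve(XtViX, XtViy)
        quad = ytViy - float(XtViy @ beta)
        npp = self.n - self.p
        if quad <= 0:
            return -np.inf, np.nan, None, None
        s2 = quad / npp
        ll = -0.5 * (
            npp * math.log(2 * math.pi)
            + npp * math.log(s2)
            + float(np.sum(np.log1p(lam * self.k)))
            + logdet_x
            + npp
        )
        return ll, s2, beta, XtViX

    def loglik_at(self, s2i, s2r):
        """Unprofiled restricted log-likelihood at given components."""
        lam = s2i / s2r
        XtViX, XtViy, ytViy = self._parts(lam)
        sign, logdet_x = np.linalg.slogdet(XtViX)
        beta = np.linalg.solve(XtViX, XtViy)
        quad = (ytViy - float(XtViy @ beta)) / s2r
        npp = self.n - self.p
        logdet_v = self.n * math.log(s2r) + float(np.sum(np.log1p(lam * self.k)))
        logdet_x = logdet_x - self.p * math.log(s2r)
        return -0.5 * (npp * math.log(2 * math.pi) + logdet_v + logdet_x + quad)

    def fit(self):
        grid = np.concatenate([[0.0], np.logspace(-6, 4, 61)])
        lls = np.array([self.loglik(l)[0] for l in grid])
        j = int(np.nanargmax(lls))
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, len(grid) - 1)]
        if hi <= lo:
            hi = lo + 1e-6
        res = optimize.minimize_scalar(
            lambda l: -self.loglik(l)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12 * max(1.0, hi)},
        )
        lam = float(res.x) if -res.fun >= lls[j] else float(grid[j])
        if self.loglik(0.0)[0] >= self.loglik(lam)[0]:
            lam = 0.0  # boundary solution
        return lam


def fit_univariate_reml(
    panel: pd.DataFrame,
    response: str,
    fixed_terms: Sequence[str] = ("intercept", "age_stage", "sex"),
    compute_se: bool = True,
) -> MixedModelFit:
    """Univariate individual-random-intercept mixed model by profiled REML.

    Also records the restricted log-likelihood of the same model without
    the random intercept (``extra['loglik_null']``), the ingredient of the
    boundary-mixture likelihood-ratio test for the among-individual
    variance.
    """
    pops = sorted(panel["population"].unique()) if "population" in panel else []
    pop_codes = {p: c for p, c in zip(pops, [-0.5, 0.5] if len(pops) == 2 else np.linspace(-0.5, 0.5, max(len(pops), 1)))}
    X, y, codes, n_ind = _univariate_arrays(panel, response, fixed_terms, pop_codes)
    prob = _UnivariateREML(X, y, codes, n_ind)
    lam = prob.fit()
    ll, s2r, beta, XtViX = prob.loglik(lam)
    ll0 = prob.loglik(0.0)[0]
    s2i = lam * s2r
    beta_cov = np.linalg.inv(XtViX) * s2r
    se = np.sqrt(np.diag(beta_cov))
    at_boundary = lam <= 1e-8

    comp_se = None
    if compute_se:
        comp_se = _component_se_2x2(prob, s2i, s2r, at_boundary)

    g = ""
    fit = MixedModelFit(
        responses=[response],
        groups=[g],
        fixed_names={g: list(fixed_terms)},
        beta={g: beta},
        beta_se={g: se},
        beta_cov={g: beta_cov},
        sigma_ind={g: np.array([[s2i]])},
        sigma_res={g: np.array([[s2r]])},
        sigma_ind_se={g: None if comp_se is None else np.array([[comp_se[0]]])},
        sigma_res_se={g: None if comp_se is None else np.array([[comp_se[1]]])},
        reml_loglik=ll,
        n_parameters=2,
        converged=bool(np.isfinite(ll)),
        n_obs=prob.n,
        n_individuals=n_ind,
        at_boundary=at_boundary,
        block_info={g: {"n_obs": prob.n, "n_individuals": n_ind, "rank_x": prob.p}},
        extra={"loglik_null": ll0, "lambda": lam, "population_codes": pop_codes},
    )
    if compute_se:
        fit.theta = np.array([s2i, s2r])
        fit.theta_cov = _component_cov_2x2(prob, s2i, s2r, at_boundary)
    return fit


def _component_cov_2x2(prob, s2i, s2r, at_boundary):
    """Asymptotic covariance of (sigma2_ind, sigma2_res) by numeric Hessian."""
    base_i = max(s2i, 1e-6 * s2r)
    h_i = 1e-4 * max(base_i, s2r)
    h_r = 1e-4 * s2r

    def f(a, b):
        return prob.loglik_at(max(a, 0.0), max(b, 1e-12))

    if at_boundary:
        # one-sided curvature in the boundary direction
        pts_i = (0.0, h_i, 2 * h_i)
        f0, f1, f2 = (f(a, s2r) for a in pts_i)
        d2i = (f2 - 2 * f1 + f0) / h_i**2
    else:
        d2i = (f(s2i + h_i, s2r) - 2 * f(s2i, s2r) + f(s2i - h_i, s2r)) / h_i**2
    d2r = (f(max(s2i, 0.0), s2r + h_r) - 2 * f(max(s2i, 0.0), s2r) + f(max(s2i, 0.0), s2r - h_r)) / h_r**2
    a0 = max(s2i, 0.0) if not at_boundary else h_i
    dir_ = (
        f(a0 + h_i, s2r + h_r) - f(a0 + h_i, s2r - h_r) - f(a0 - h_i, s2r + h_r) + f(a0 - h_i, s2r - h_r)
    ) / (4 * h_i * h_r)
    H = -np.array([[d2i, dir_], [dir_, d2r]])
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
        return cov
    except np.linalg.LinAlgError:
        return np.full((2, 2), np.nan)


def _component_se_2x2(prob, s2i, s2r, at_boundary):
    cov = _component_cov_2x2(prob, s2i, s2r, at_boundary)
    return tuple(np.sqrt(np.abs(np.diag(cov))))


# ---------------------------------------------------------------------------
# general multivariate path


def _moment_start(block: _Block) -> tuple[np.ndarray, np.ndarray]:
    """Moment-based starting values: split each trait's variance between
    levels using individual means; among covariances from individual-mean
    cross-products (shrunk), residual covariances start at zero."""
    q = len(block.responses)
    rows = []
    for pi, pat in enumerate(block.patterns):
        for m in range(pat.y.shape[0]):
            for j, t in enumerate(pat.t_idx):
                rows.append((f"{pi}_{m}", t, pat.y[m, j]))
    df = pd.DataFrame(rows, columns=["ind", "t", "y"])
    means = df.pivot_table(index="ind", columns="t", values="y", aggfunc="mean")
    means = means.reindex(columns=range(q))
    B = means.cov().to_numpy()
    B = np.where(np.isfinite(B), B, 0.0)
    tot = df.groupby("t")["y"].var().reindex(range(q)).fillna(1.0).to_numpy()
    within = (
        df.assign(dev=lambda d: d["y"] - d.groupby(["ind", "t"])["y"].transform("mean"))
        .groupby("t")["dev"]
        .var()
        .reindex(range(q))
        .to_numpy()
    )
    within = np.where(np.isfinite(within) & (within > 1e-8), within, 0.5 * tot)
    Si0 = 0.6 * B
    d = np.maximum(np.diag(Si0).copy(), 0.1 * tot)
    np.fill_diagonal(Si0, d)
    # shrink to ensure PD
    w = np.linalg.eigvalsh(Si0)
    if w.min() < 1e-6:
        Si0 = Si0 + (1e-6 - w.min()) * np.eye(q)
    Sr0 = np.diag(np.maximum(within, 0.05 * tot))
    return Si0, Sr0


def _resolve_structure(name_or_obj, q: int, block: _Block | None = None, residual=False):
    if not isinstance(name_or_obj, str):
        return name_or_obj
    if name_or_obj == "unstructured":
        return Unstructured(q)
    if name_or_obj == "diagonal":
        return Diagonal(q)
    if name_or_obj == "auto" and residual:
        if block is None:
            return Unstructured(q)
        return BlockDiagonal(q, block.res_groups)
    raise ValueError(f"unknown covariance structure {name_or_obj!r}")


def fit_reml(
    panel: pd.DataFrame,
    spec: ModelSpec,
    compute_se: bool = False,
    n_restarts: int = 3,
    maxiter: int = 1000,
    param_map=None,
    blocks=None,
) -> MixedModelFit:
    """Maximize the restricted likelihood for the model in ``spec``.

    Univariate unconstrained fits are routed to the fast profiled path.
    For multivariate fits, variance parameters are optimized on the
    log-Cholesky scale by L-BFGS-B with numerical gradients, restarting
    from dispersed initializations; missing responses on an occasion are
    marginalized out by building each individual's covariance from its
    observed rows only.
    """
    responses = list(spec.responses)
    univariate_ok = (
        len(responses) == 1
        and spec.random_intercept is not None
        and spec.groups is None
        and param_map is None
        and spec.among_structure == "unstructured"
    )
    if univariate_ok:
        return fit_univariate_reml(
            panel, responses[0], spec.terms_for(responses[0]), compute_se=compute_se
        )

    if blocks is None:
        blocks = _make_blocks(panel, spec)
    q = len(responses)
    if param_map is None:
        items = []
        for b in blocks:
            si = _resolve_structure(spec.among_structure, q, b)
            sr = _resolve_structure(spec.residual_structure, q, b, residual=True)
            items.append((si, sr))
        param_map = IndependentMap(items)

    starts = [_moment_start(b) for b in blocks]
    theta0 = param_map.init(starts)
    return _fit_from_map(blocks, param_map, theta0, compute_se, n_restarts, maxiter)


def _make_blocks(panel: pd.DataFrame, spec: ModelSpec) -> list[_Block]:
    responses = list(spec.responses)
    fixed = {r: spec.terms_for(r) for r in responses}
    if spec.groups is None:
        return [prepare_block(panel, responses, fixed, label="")]
    levels = sorted(panel[spec.groups].unique())
    blocks = []
    for lev in levels:
        sub = panel[panel[spec.groups] == lev]
        blocks.append(prepare_block(sub, responses, fixed, label=str(lev)))
    return blocks


def _neg_reml(theta, blocks, pmap):
    total = 0.0
    for block, (Si, Sr, viol) in zip(blocks, pmap.unpack(theta)):
        ll = _block_reml_loglik(block, Si, Sr)
        if ll is None or not np.isfinite(ll):
            return 1e10
        total += -ll + 1e7 * viol
    return total


def _fit_from_map(blocks, pmap, theta0, compute_se, n_restarts, maxiter) -> MixedModelFit:
    fun = lambda th: _neg_reml(th, blocks, pmap)
    bounds = pmap.bounds()
    rng = np.random.default_rng(12345)
    starts = [theta0]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(theta0 + rng.normal(0.0, 0.25, size=len(theta0)))
    best = None
    for th in starts:
        res = optimize.minimize(
            fun,
            th,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    ll = -float(best.fun)
    converged = bool(best.success or np.max(np.abs(best.jac)) < 1e-3)

    unpacked = pmap.unpack(theta)
    groups = [b.label for b in blocks]
    beta, beta_se, beta_cov, si, sr = {}, {}, {}, {}, {}
    si_se = {g: None for g in groups}
    sr_se = {g: None for g in groups}
    fixed_names, block_info = {}, {}
    for b, (Si, Sr, _) in zip(blocks, unpacked):
        bb, bc = _block_gls(b, Si, Sr)
        g = b.label
        beta[g], beta_cov[g] = bb, bc
        beta_se[g] = np.sqrt(np.diag(bc))
        si[g], sr[g] = Si, Sr
        fixed_names[g] = b.fixed_names
        block_info[g] = {
            "n_obs": b.n_obs,
            "n_individuals": b.n_individuals,
            "rank_x": b.rank_x,
            "fixed_zero_residual_pairs": b.fixed_zero_residual_pairs,
        }

    theta_cov = None
    if compute_se:
        H = _num_hessian(fun, theta)
        theta_cov = _safe_inv(H)
        if theta_cov is not None:
            for gi, (b, _) in enumerate(zip(blocks, unpacked)):
                q = len(b.responses)
                se_i, se_r = _element_se(pmap, theta, theta_cov, gi, q)
                si_se[b.label], sr_se[b.label] = se_i, se_r

    fit = MixedModelFit(
        responses=list(blocks[0].responses),
        groups=groups,
        fixed_names=fixed_names,
        beta=beta,
        beta_se=beta_se,
        beta_cov=beta_cov,
        sigma_ind=si,
        sigma_res=sr,
        sigma_ind_se=si_se,
        sigma_res_se=sr_se,
        reml_loglik=ll,
        n_parameters=pmap.n_params,
        converged=converged,
        n_obs=sum(b.n_obs for b in blocks),
        n_individuals=sum(b.n_individuals for b in blocks),
        at_boundary=pmap.at_boundary(theta),
        block_info=block_info,
        theta=theta,
        theta_cov=theta_cov,
    )
    fit.extra["param_map"] = pmap
    return fit


def _num_hessian(fun, x, h=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = fun(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = steps[i]
            ej[j] = steps[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return H


def _safe_inv(H):
    try:
        cov = np.linalg.inv(H)
        return cov
    except np.linalg.LinAlgError:
        return None


def _element_se(pmap, theta, theta_cov, group_index, q, h=1e-5):
    """Delta-method SEs of covariance elements via the Jacobian d vech / d theta."""
    iu = np.tril_indices(q)

    def vechs(th):
        Si, Sr, _ = pmap.unpack(th)[group_index]
        return np.concatenate([Si[iu], Sr[iu]])

    n = len(theta)
    base = vechs(theta)
    J = np.zeros((len(base), n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = h * max(1.0, abs(theta[k]))
        J[:, k] = (vechs(theta + e) - vechs(theta - e)) / (2 * e[k])
    cov = J @ theta_cov @ J.T
    se = np.sqrt(np.abs(np.diag(cov)))
    m = len(iu[0])
    Si_se = np.zeros((q, q))
    Sr_se = np.zeros((q, q))
    Si_se[iu] = se[:m]
    Sr_se[iu] = se[m:]
    Si_se = Si_se + np.tril(Si_se, -1).T
    Sr_se = Sr_se + np.tril(Sr_se, -1).T
    return Si_se, Sr_se


# ---------------------------------------------------------------------------
# Wald tests


def wald_f_test(
    fit: MixedModelFit, term: str, group: str | None = None, response: str | None = None
) -> dict:
    """Wald F test for one fixed-effect term.

    For a single coefficient this reduces to F = (beta/SE)^2.  Denominator
    df uses the containment approximation recorded on the fit:
    n_obs - rank(X) - n_individuals + 1 (and the residual df for OLS fits).
    """
    g = group if group is not None else fit.groups[0]
    names = fit.fixed_names[g]
    if response is not None and len(fit.responses) > 1:
        want = f"{response}:{term}"
        idx = [i for i, nm in enumerate(names) if nm == want]
    else:
        idx = [i for i, nm in enumerate(names) if nm == term or nm.endswith(f":{term}")]
    if not idx:
        raise ValueError(f"term {term!r} not present in fit (have {names})")
    beta = fit.beta[g][idx]
    C = fit.beta_cov[g][np.ix_(idx, idx)]
    k = len(idx)
    F = float(beta @ np.linalg.solve(C, beta)) / k
    info = fit.block_info[g]
    if fit.df_method == "residual":
        ddf = info["n_obs"] - info["rank_x"]
    else:
        ddf = info["n_obs"] - info["rank_x"] - info["n_individuals"] + 1
    ddf = max(ddf, 1)
    p = float(stats.f.sf(F, k, ddf))
    return {"F": F, "num_df": k, "den_df": ddf, "p_value": p, "df_method": fit.df_method}
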