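"""Standard metabolic rate from intermittent-flow respirometry traces.

During a closed phase the chamber is sealed and dissolved O2 declines
linearly at the fish's respiration rate; open phases flush the chamber.
SMR extraction proceeds in three steps:

1. fit an ordinary least-squares line to each closed phase after trimming
   two minutes from each end, and keep only phases with R^2 >= 0.95 that
   start after the one-hour acclimation window;
2. convert the retained slopes to mass-specific rates,
   rate = |slope| * 60 * chamber_volume / fish_mass  (mg O2 kg^-1 h^-1);
3. fit a two-component normal mixture to the rates by EM.  The lower
   component mean is the SMR (resting metabolism); the upper component
   absorbs phases inflated by spontaneous activity.

Background (microbial) respiration is not corrected for; traces are
assumed blank-corrected upstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RespirometryTrace",
    "ClosedPhase",
    "SMREstimate",
    "extract_closed_phase_slopes",
    "estimate_smr",
    "fit_two_normal_mixture",
    "smr_from_trace",
]


@dataclass
class RespirometryTrace:
    """One overnight O2 trace for one fish.

    ``data`` columns: ``time_s`` (strictly increasing), ``o2_mg_per_l``,
    ``phase_id`` (integer, alternating open/closed), ``phase_type``.
    """

    data: pd.DataFrame
    fish_mass_kg: float
    chamber_volume_l: float
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        need = {"time_s", "o2_mg_per_l", "phase_id", "phase_type"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"trace is missing column(s): {sorted(missing)}")
        t = self.data["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace time must be strictly increasing")
        if self.fish_mass_kg <= 0 or self.chamber_volume_l <= 0:
            raise ValueError("fish mass and chamber volume must be positive")
        phases = self.data.drop_duplicates("phase_id")
        types = phases["phase_type"].to_numpy()
        if np.any(types[1:] == types[:-1]):
            raise ValueError("phase_type must alternate between open and closed")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        fish_mass_kg: float,
        chamber_volume_l: float,
        temperature_c: float | None = None,
    ) -> "RespirometryTrace":
        return cls(pd.read_csv(path), fish_mass_kg, chamber_volume_l, temperature_c)


@dataclass
class ClosedPhase:
    """OLS summary of one closed (sealed) measurement phase."""

    phase_id: int
    slope_mg_per_l_min: float
    r_squared: float
    start_time_s: float
    duration_s: float
    retained: bool
    reason: str = ""


@dataclass
class SMREstimate:
    """Two-normal mixture over mass-specific rates; SMR = lower mean."""

    smr_mass_specific: float  # mg O2 kg^-1 h^-1
    mixture_means: tuple[float, float]  # (lower, upper)
    mixture_sds: tuple[float, float]
    mixture_weights: tuple[float, float]
    n_phases_used: int
    loglik: float = float("nan")


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of an ordinary least-squares line."""
    tc = t - t.mean()
    denom = float(tc @ tc)
    slope = float(tc @ (y - y.mean())) / denom
    intercept = float(y.mean() - slope * t.mean())
    fitted = intercept + slope * t
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


def extract_closed_phase_slopes(
    trace: RespirometryTrace,
    trim_margin_s: float = 120.0,
    min_r2: float = 0.95,
    acclimation_cutoff_s: float = 3600.0,
) -> list[ClosedPhase]:
    """Fit and filter per-phase O2 decline slopes.

    Each closed phase loses ``trim_margin_s`` from both ends before the
    line fit (so only the linear core of the decline is used).  A phase is
    retained when its R^2 reaches ``min_r2`` and it starts at or after the
    acclimation cutoff.  Slopes are reported in mg L^-1 min^-1.
    """
    phases: list[ClosedPhase] = []
    closed = trace.data[trace.data["phase_type"] == "closed"]
    if closed.empty:
        logger.warning("trace contains no closed phases; nothing to extract")
        return phases
    for pid, grp in closed.groupby("phase_id", sort=True):
        t = grp["time_s"].to_numpy(dtype=float)
        y = grp["o2_mg_per_l"].to_numpy(dtype=float)
        start, end = t[0], t[-1]
        keep = (t >= start + trim_margin_s) & (t <= end - trim_margin_s)
        if keep.sum() < 3:
            phases.append(
                ClosedPhase(int(pid), float("nan"), 0.0, start, end - start, False,
                            "too short after trimming")
            )
            continue
        slope_s, _, r2 = _ols_line(t[keep], y[keep])
        slope = slope_s * 60.0
        ok_r2 = r2 >= min_r2
        ok_time = start >= acclimation_cutoff_s
        reason = ""
        if not ok_r2:
            reason = f"r_squared {r2:.3f} below {min_r2}"
        if not ok_time:
            reason = (reason + "; " if reason else "") + "within acclimation period"
        phases.append(
            ClosedPhase(int(pid), slope, r2, start, end - start, ok_r2 and ok_time, reason)
        )
    return phases


def fit_two_normal_mixture(
    x: np.ndarray,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Two-component normal mixture by EM with quantile-based restarts.

    Restarts initialize the component means around the 25th/75th
    percentiles (with deterministic jitter); the best final log-likelihood
    wins, ties broken in favour of the lower first mean.  Component SDs
    are floored at a small multiple of the data scale so a component
    cannot collapse onto a single point; if every restart degenerates an
    error is raised.

    Returns (means, sds, weights, loglik) with means sorted ascending.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("mixture fit needs at least 2 observations")
    scale = float(np.std(x))
    if scale == 0.0:
        # all observations identical: the mixture collapses
        return np.array([x[0], x[0]]), np.zeros(2), np.array([0.5, 0.5]), float("inf")
    sd_floor = max(1e-6 * scale, 1e-12)
    rng = np.random.default_rng(seed)
    q25, q75 = np.quantile(x, [0.25, 0.75])
    best = None
    for r in range(n_restarts):
        jitter = 0.0 if r == 0 else rng.normal(0.0, 0.25 * scale, size=2)
        mu = np.array([q25, q75]) + jitter
        sd = np.full(2, max(scale / 2.0, sd_floor))
        w = np.array([0.5, 0.5])
        ll_prev = -np.inf
        degenerate = False
        for _ in range(max_iter):
            # E step
            logp = (
                np.log(w)[None, :]
                - 0.5 * math_log_2pi
                - np.log(sd)[None, :]
                - 0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
            )
            m = logp.max(axis=1, keepdims=True)
            p = np.exp(logp - m)
            denom = p.sum(axis=1, keepdims=True)
            resp = p / denom
            ll = float(np.sum(m.ravel() + np.log(denom.ravel())))
            if ll + 1e-9 < ll_prev:
                raise AssertionError("EM log-likelihood decreased")
            # M step
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-10):
                degenerate = True
                break
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            sd = np.sqrt(np.maximum(var, sd_floor**2))
            if abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
                ll_prev = ll
                break
            ll_prev = ll
        if degenerate or not np.isfinite(ll_prev):
            continue
        key = (ll_prev, -min(mu))
        if best is None or key > best[0]:
            order = np.argsort(mu)
            best = (key, (mu[order], sd[order], w[order], ll_prev))
    if best is None:
        raise RuntimeError("all EM restarts degenerated; cannot fit mixture")
    return best[1]


math_log_2pi = float(np.log(2.0 * np.pi))


def estimate_smr(
    phases: list[ClosedPhase],
    fish_mass_kg: float,
    chamber_volume_l: float,
    min_phases: int = 4,
    n_restarts: int = 10,
    seed: int = 0,
) -> SMREstimate:
    """Mass-specific SMR from retained closed-phase slopes.

    Requires at least ``min_phases`` retained phases (a two-component
    mixture has five parameters; fewer phases should fall back to a
    simpler summary upstream).
    """
    rates = np.array(
        [
            abs(p.slope_mg_per_l_min) * 60.0 * chamber_volume_l / fish_mass_kg
            for p in phases
            if p.retained
        ]
    )
    if len(rates) < min_phases:
        raise ValueError(
            f"only {len(rates)} retained phases; at least {min_phases} are needed "
            "for the two-component mixture — consider the median rate as a fallback"
        )
    mu, sd, w, ll = fit_two_normal_mixture(rates, n_restarts=n_restarts, seed=seed)
    return SMREstimate(
        smr_mass_specific=float(mu[0]),
        mixture_means=(float(mu[0]), float(mu[1])),
        mixture_sds=(float(sd[0]), float(sd[1])),
        mixture_weights=(float(w[0]), float(w[1])),
        n_phases_used=int(len(rates)),
        loglik=float(ll),
    )


def smr_from_trace(
    trace: RespirometryTrace,
    trim_margin_s: float = 120.0,
    min_r2: float = 0.95,
    acclimation_cutoff_s: float = 3600.0,
    min_phases: int = 4,
    seed: int = 0,
) -> tuple[SMREstimate, list[ClosedPhase]]:
    """Full per-fish extraction: phases -> filter -> mixture -> SMR."""
    phases = extract_closed_phase_slopes(trace, trim_margin_s, min_r2, acclimation_cutoff_s)
    est = estimate_smr(
        phases, trace.fish_mass_kg, trace.chamber_volume_l, min_phases=min_phases, seed=seed
    )
    return est, phases


def write_diagnostics(phases: list[ClosedPhase], path: str | Path) -> None:
    rows = [
        {
            "phase_id": p.phase_id,
            "slope_mg_per_l_min": p.slope_mg_per_l_min,
            "r_squared": p.r_squared,
            "start_time_s": p.start_time_s,
            "duration_s": p.duration_s,
            "retained": p.retained,
            "reason": p.reason,
        }
        for p in phases
    ]
    Path(path).write_text(json.dumps(rows, indent=2))
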