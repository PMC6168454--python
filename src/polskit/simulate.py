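"""Synthetic trait panels and respirometry traces with known ground truth.

The generator emulates a two-population repeated-measures design: each
individual carries a latent among-individual trait vector u ~ MVN(0,
Sigma_ind) drawn once, and every measurement is ``beta . x + u_trait + e``
where the residual e is drawn jointly (from Sigma_res) across traits
measured on the same occasion and independently across occasions.
Behavioural traits are measured on two trial occasions per ontogenetic
stage; metabolic rate and size share a single "metabolic" occasion per
stage (trial index 0).  Individual-level attrition after stage 1 emulates
mortality between the immature and adult assays.

Respirometry traces are overnight dissolved-oxygen series in which each
closed (sealed-chamber) phase declines linearly with a slope drawn from a
two-state resting/active mixture, plus sampling noise; open phases flush
the chamber back toward air saturation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import PANEL_COLUMNS

__all__ = [
    "SimulationConfig",
    "default_study_config",
    "generate_trait_panel",
    "generate_respirometry_trace",
    "default_phase_plan",
    "write_panel_csv",
    "write_trace_csv",
]


def _as_psd(name: str, m, q: int) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.shape != (q, q):
        raise ValueError(f"{name} must be {q}x{q}, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(a)
    if w.min() < -1e-10:
        raise ValueError(
            f"{name} is not positive semi-definite (min eigenvalue {w.min():.3g}); "
            "covariance inputs must be valid covariance matrices"
        )
    return a


@dataclass
class SimulationConfig:
    """Ground-truth parameters for a two-population trait panel.

    ``sigma_ind`` / ``sigma_res`` map population label to the among-individual
    and residual covariance matrices (trait x trait, standardized trait
    units squared).  ``beta`` maps population -> trait -> fixed-effect
    coefficients for the terms intercept, age_stage, sex and trial (all
    covariates on the centred/coded scale, so trial enters as +-0.5).
    ``measurement_schedule`` gives measures per stage per trait: traits with
    2 occupy the two behavioural trial occasions, traits with 1 share the
    once-per-stage metabolic occasion.  ``missing_rate`` is the fraction of
    individuals lost after stage 1 (individual-level attrition).
    """

    n_individuals_per_population: int = 40
    trait_names: Sequence[str] = ("hiding_time", "distance_moved", "smr", "standard_size")
    populations: Sequence[str] = ("SG", "FG")
    sigma_ind: Mapping[str, np.ndarray] = field(default_factory=dict)
    sigma_res: Mapping[str, np.ndarray] = field(default_factory=dict)
    beta: Mapping[str, Mapping[str, Mapping[str, float]]] = field(default_factory=dict)
    measurement_schedule: Mapping[str, int] = field(default_factory=dict)
    missing_rate: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        q = len(self.trait_names)
        if self.n_individuals_per_population < 2:
            raise ValueError("need at least 2 individuals per population")
        if not self.measurement_schedule:
            self.measurement_schedule = {t: 2 for t in self.trait_names}
        for t, k in self.measurement_schedule.items():
            if k < 1:
                raise ValueError(f"measurement count for {t!r} must be >= 1")
        self.sigma_ind = {
            p: _as_psd(f"sigma_ind[{p}]", self.sigma_ind[p], q) for p in self.populations
        }
        self.sigma_res = {
            p: _as_psd(f"sigma_res[{p}]", self.sigma_res[p], q) for p in self.populations
        }
        for p in self.populations:
            rate = self.missing_rate.get(p, 0.0)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"missing_rate[{p}] must be in [0, 1)")


def _corr_to_cov(variances: Sequence[float], corr: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.asarray(variances, dtype=float))
    return corr * np.outer(sd, sd)


def default_study_config(seed: int = 0, include_nonrepeatable: bool = False) -> SimulationConfig:
    """The study-scale default: 2 populations x 40 fish, 4 core traits.

    Variance components and fixed effects follow the univariate estimates
    for the slow-growing (SG) and fast-growing (FG) populations; the SG
    among-individual correlation structure carries the pace-of-life
    signature (activity-size-metabolism coupling, |r| = 0.6) while FG has
    none.  ``include_nonrepeatable=True`` appends emergence latency and
    freezing time with zero among-individual variance, for exercising the
    repeatability gate.
    """
    traits = ["hiding_time", "distance_moved", "smr", "standard_size"]
    var_ind = {"SG": [0.196, 0.361, 0.222, 0.382], "FG": [0.226, 0.240, 0.114, 0.013]}
    var_res = {"SG": [0.775, 0.575, 0.185, 0.106], "FG": [0.721, 0.691, 0.300, 0.085]}
    # SG among-individual correlations: hiding-distance +, distance-size +,
    # smr-size - (pace-of-life structure); FG uncorrelated.
    corr_sg = np.eye(4)
    corr_sg[0, 1] = corr_sg[1, 0] = 0.6
    corr_sg[1, 3] = corr_sg[3, 1] = 0.6
    corr_sg[2, 3] = corr_sg[3, 2] = -0.6
    corr_fg = np.eye(4)
    # residual correlations: only the negative metabolism-size coupling
    rcorr = np.eye(4)
    rcorr[2, 3] = rcorr[3, 2] = -0.4
    sigma_ind = {
        "SG": _corr_to_cov(var_ind["SG"], corr_sg),
        "FG": _corr_to_cov(var_ind["FG"], corr_fg),
    }
    sigma_res = {
        "SG": _corr_to_cov(var_res["SG"], rcorr),
        "FG": _corr_to_cov(var_res["FG"], rcorr),
    }
    beta = {
        "SG": {
            "hiding_time": {"intercept": 0.314, "age_stage": 0.168, "sex": -0.235, "trial": -0.077},
            "distance_moved": {"intercept": 0.903, "age_stage": 0.093, "sex": -0.081, "trial": -0.613},
            "smr": {"intercept": -0.049, "age_stage": -1.536, "sex": 0.237},
            "standard_size": {"intercept": 0.186, "age_stage": 1.389, "sex": -0.263},
        },
        "FG": {
            "hiding_time": {"intercept": -0.825, "age_stage": 0.113, "sex": 0.139, "trial": 0.452},
            "distance_moved": {"intercept": 0.181, "age_stage": -0.481, "sex": 0.351, "trial": -0.138},
            "smr": {"intercept": -0.018, "age_stage": -1.475, "sex": 0.438},
            "standard_size": {"intercept": -0.108, "age_stage": 1.820, "sex": -0.440},
        },
    }
    schedule = {"hiding_time": 2, "distance_moved": 2, "smr": 1, "standard_size": 1}
    if include_nonrepeatable:
        extra = ["emergence_latency", "freezing_time"]
        traits = traits + extra
        for p in ("SG", "FG"):
            si = np.zeros((6, 6))
            si[:4, :4] = sigma_ind[p]
            sr = np.eye(6)
            sr[:4, :4] = sigma_res[p]
            sigma_ind[p], sigma_res[p] = si, sr
            for t in extra:
                beta[p][t] = {"intercept": 0.0, "age_stage": 0.1, "sex": 0.0, "trial": 0.0}
        schedule |= {t: 2 for t in extra}
    return SimulationConfig(
        n_individuals_per_population=40,
        trait_names=traits,
        populations=("SG", "FG"),
        sigma_ind=sigma_ind,
        sigma_res=sigma_res,
        beta=beta,
        measurement_schedule=schedule,
        # mortality between stages: 8/40 SG fish, 1/40 FG fish
        missing_rate={"SG": 8 / 40, "FG": 1 / 40},
        seed=seed,
    )


def _occasions(config: SimulationConfig) -> list[tuple[int, list[int]]]:
    """Occasions within one stage: (trial index, trait indices measured).

    Trial 0 is the shared once-per-stage (metabolic/size) occasion; trials
    1..k are behavioural trial occasions.
    """
    traits = list(config.trait_names)
    once = [i for i, t in enumerate(traits) if config.measurement_schedule[t] == 1]
    occ: list[tuple[int, list[int]]] = []
    if once:
        occ.append((0, once))
    max_rep = max((config.measurement_schedule[t] for t in traits), default=1)
    for trial in range(1, max_rep + 1):
        idx = [
            i
            for i, t in enumerate(traits)
            if config.measurement_schedule[t] >= 2 and trial <= config.measurement_schedule[t]
        ]
        if idx:
            occ.append((trial, idx))
    return occ


def generate_trait_panel(config: SimulationConfig) -> pd.DataFrame:
    """Draw one long-format trait panel under the configured ground truth.

    Deterministic for a fixed ``config.seed``.  Returns a DataFrame with
    the canonical columns ``individual_id, population, sex, age_stage,
    trial, trait, value``.
    """
    rng = np.random.default_rng(config.seed)
    traits = list(config.trait_names)
    rows: list[tuple] = []
    for pop in config.populations:
        n = config.n_individuals_per_population
        u_all = rng.multivariate_normal(np.zeros(len(traits)), config.sigma_ind[pop], size=n,
                                        method="cholesky" if _is_pd(config.sigma_ind[pop]) else "eigh")
        sexes = rng.choice([-0.5, 0.5], size=n)
        n_drop = int(round(config.missing_rate.get(pop, 0.0) * n))
        dropped = set(rng.choice(n, size=n_drop, replace=False)) if n_drop else set()
        occ_plan = _occasions(config)
        mean_trial = _mean_trial(occ_plan)
        for i in range(n):
            ind_id = f"{pop}_{i + 1:03d}"
            for stage in (-0.5, 0.5):
                if stage > 0 and i in dropped:
                    continue
                for trial, t_idx in occ_plan:
                    e = rng.multivariate_normal(np.zeros(len(traits)), config.sigma_res[pop],
                                                method="cholesky" if _is_pd(config.sigma_res[pop]) else "eigh")
                    for t in t_idx:
                        trait = traits[t]
                        b = config.beta.get(pop, {}).get(trait, {})
                        x = (
                            b.get("intercept", 0.0)
                            + b.get("age_stage", 0.0) * stage
                            + b.get("sex", 0.0) * sexes[i]
                            + (b.get("trial", 0.0) * (trial - mean_trial) if trial > 0 else 0.0)
                        )
                        rows.append(
                            (ind_id, pop, sexes[i], stage, trial, trait, x + u_all[i, t] + e[t])
                        )
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def _is_pd(m: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


def _mean_trial(occ_plan: list[tuple[int, list[int]]]) -> float:
    trials = [t for t, _ in occ_plan if t > 0]
    return float(np.mean(trials)) if trials else 0.0


# ---------------------------------------------------------------------------
# respirometry traces


def default_phase_plan(
    total_hours: float = 12.0, closed_s: float = 600.0, open_s: float = 300.0
) -> list[tuple[str, float]]:
    """Alternating open/closed phase plan spanning ``total_hours``."""
    plan: list[tuple[str, float]] = []
    t = 0.0
    while t < total_hours * 3600.0:
        plan.append(("closed", closed_s))
        plan.append(("open", open_s))
        t += closed_s + open_s
    return plan


def generate_respirometry_trace(
    smr_slope: float,
    active_slope: float,
    p_active: float,
    phase_plan: Sequence[tuple[str, float]] | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    sample_dt: float = 5.0,
    o2_saturation: float = 8.0,
    curvature: Mapping[int, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one overnight dissolved-oxygen trace.

    ``smr_slope`` and ``active_slope`` are closed-phase O2 decline rates in
    mg L^-1 min^-1 (non-positive; the active slope is the steeper one).
    Each closed phase draws its state from the resting/active mixture with
    activity probability ``p_active``; ``curvature`` optionally injects a
    quadratic component (mg L^-1 min^-2) into selected phases to emulate
    non-linear decline.  Returns the trace table
    (``time_s, o2_mg_per_l, phase_id, phase_type``) and a ground-truth dict
    with per-phase state and slope.
    """
    if abs(active_slope) <= abs(smr_slope):
        raise ValueError("|active_slope| must exceed |smr_slope|")
    if not 0.0 <= p_active < 1.0:
        raise ValueError("p_active must be in [0, 1)")
    if phase_plan is None:
        phase_plan = default_phase_plan()
    for ptype, dur in phase_plan:
        if ptype == "closed" and dur <= 2 * 120.0:
            raise ValueError(
                f"closed phase of {dur} s cannot survive the 2-min trims at each end"
            )
    rng = np.random.default_rng(seed)
    times, o2, pids, ptypes = [], [], [], []
    truth_phases = []
    t0 = 0.0
    level = o2_saturation
    for pid, (ptype, dur) in enumerate(phase_plan):
        tt = np.arange(0.0, dur, sample_dt)
        if ptype == "closed":
            active = rng.random() < p_active
            slope = active_slope if active else smr_slope  # mg/L per minute
            quad = (curvature or {}).get(pid, 0.0)
            vals = level + slope * tt / 60.0 + quad * (tt / 60.0) ** 2
            truth_phases.append(
                {"phase_id": pid, "state": "active" if active else "resting",
                 "slope_mg_per_l_min": float(slope), "curvature": float(quad)}
            )
            level = float(vals[-1] + slope * sample_dt / 60.0)
        else:
            # flush: exponential recovery toward saturation
            tau = max(dur / 4.0, 1.0)
            vals = o2_saturation + (level - o2_saturation) * np.exp(-tt / tau)
            level = float(vals[-1])
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=len(vals))
        times.append(t0 + tt)
        o2.append(vals)
        pids.append(np.full(len(tt), pid))
        ptypes.extend([ptype] * len(tt))
        t0 += dur
    trace = pd.DataFrame(
        {
            "time_s": np.concatenate(times),
            "o2_mg_per_l": np.concatenate(o2),
            "phase_id": np.concatenate(pids).astype(int),
            "phase_type": ptypes,
        }
    )
    truth = {
        "smr_slope_mg_per_l_min": float(smr_slope),
        "active_slope_mg_per_l_min": float(active_slope),
        "p_active": float(p_active),
        "noise_sd": float(noise_sd),
        "phases": truth_phases,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# writers


def write_panel_csv(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False, columns=PANEL_COLUMNS)


def write_trace_csv(
    trace: pd.DataFrame, path: str | Path, truth: dict | None = None
) -> None:
    trace.to_csv(path, index=False)
    if truth is not None:
        Path(path).with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))
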