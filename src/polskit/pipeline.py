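"""End-to-end orchestration: data -> SMR -> preprocess -> repeatability
gate -> covariance decomposition -> population comparison.

The pipeline follows the analysis order of the study design it emulates:
population mean comparisons first, then per-population repeatability
with boundary-mixture LRTs, then the multivariate covariance stage
restricted to traits found repeatable in *both* populations, and finally
the cross-population structure tests.  Every exclusion and boundary
event is logged into the report, and the whole run is deterministic
given the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import compare as compare_mod
from . import pols as pols_mod
from .preprocess import (
    TraitSpec,
    code_covariates,
    default_trait_specs,
    specs_from_frame,
    transform_and_standardize,
    validate_panel,
)
from .repeatability import repeatability_table
from .respirometry import RespirometryTrace, smr_from_trace
from .simulate import SimulationConfig, default_study_config, generate_trait_panel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineConfigError", "ConvergenceError", "run_pipeline"]


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class ConvergenceError(RuntimeError):
    """A model stage failed to converge (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """Exactly one of ``panel_csv`` (real data, plus optional traces) or
    ``simulation`` (a ground-truth generator block) must be provided."""

    panel_csv: str | None = None
    traces: list[dict] = field(default_factory=list)
    simulation: dict | None = None
    trait_specs_csv: str | None = None
    gate_alpha: float = 0.05
    bootstrap_draws: int = 1000
    seed: int = 0
    output_dir: str = "polskit_out"

    def __post_init__(self) -> None:
        if (self.panel_csv is None) == (self.simulation is None):
            raise PipelineConfigError(
                "provide exactly one of 'panel_csv' (real data) or 'simulation'"
            )
        if not 0 < self.gate_alpha < 1:
            raise PipelineConfigError("gate_alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise PipelineConfigError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _simulation_config(block: dict, seed: int) -> SimulationConfig:
    block = dict(block or {})
    use_default = block.pop("default", True)
    include_nr = block.pop("include_nonrepeatable", False)
    if use_default:
        cfg = default_study_config(seed=block.pop("seed", seed), include_nonrepeatable=include_nr)
        if "n_individuals_per_population" in block:
            cfg.n_individuals_per_population = int(block.pop("n_individuals_per_population"))
        if block:
            raise PipelineConfigError(f"unsupported simulation key(s): {sorted(block)}")
        return cfg
    try:
        return SimulationConfig(seed=block.pop("seed", seed), **block)
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(f"invalid simulation block: {exc}") from exc


def _specs_for(panel: pd.DataFrame, config: PipelineConfig, simulated: bool) -> list[TraitSpec]:
    if config.trait_specs_csv is not None:
        specs = specs_from_frame(pd.read_csv(config.trait_specs_csv))
    elif simulated:
        # simulated values live on the standardized latent scale already;
        # no normalising transform applies
        counts = panel.groupby("trait")["trial"].max()
        specs = [
            TraitSpec(t, "none",
                      "life_history" if t == "standard_size" else
                      ("physiology" if t == "smr" else "behaviour"),
                      2 if counts.get(t, 0) > 0 else 1)
            for t in panel["trait"].unique()
        ]
    else:
        specs = default_trait_specs()
    have = set(panel["trait"].unique())
    return [s for s in specs if s.trait in have]


def _run_respirometry(config: PipelineConfig, report: dict) -> list[dict]:
    rows = []
    for tr in config.traces:
        trace = RespirometryTrace.from_csv(
            tr["path"], tr["fish_mass_kg"], tr["chamber_volume_l"], tr.get("temperature_c")
        )
        est, phases = smr_from_trace(trace, seed=config.seed)
        rows.append(
            {
                "individual_id": tr["individual_id"],
                "population": tr.get("population", ""),
                "sex": tr.get("sex", 0.0),
                "age_stage": tr["age_stage"],
                "trial": 0,
                "trait": "smr",
                "value": est.smr_mass_specific,
            }
        )
        report["respirometry"].append(
            {
                "individual_id": tr["individual_id"],
                "age_stage": tr["age_stage"],
                "smr": est.smr_mass_specific,
                "n_phases_used": est.n_phases_used,
                "n_phases_total": len(phases),
                "excluded_phases": [
                    {"phase_id": p.phase_id, "reason": p.reason}
                    for p in phases
                    if not p.retained
                ],
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the machine-readable report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "gate_alpha": config.gate_alpha,
        "respirometry": [],
        "exclusions": [],
        "boundary_events": [],
    }

    # --- stage 0: data
    simulated = config.simulation is not None
    if simulated:
        sim_cfg = _simulation_config(config.simulation, config.seed)
        panel = generate_trait_panel(sim_cfg)
        report["data_source"] = "simulation"
        report["simulation"] = {
            "n_individuals_per_population": sim_cfg.n_individuals_per_population,
            "traits": list(sim_cfg.trait_names),
            "seed": sim_cfg.seed,
        }
    else:
        panel = pd.read_csv(config.panel_csv)
        report["data_source"] = str(config.panel_csv)
        smr_rows = _run_respirometry(config, report)
        if smr_rows:
            panel = pd.concat([panel, pd.DataFrame(smr_rows)], ignore_index=True)
    validate_panel(panel)
    panel = code_covariates(panel)
    specs = _specs_for(panel, config, simulated)
    spec_traits = [s.trait for s in specs]

    # --- stage 1: preprocessing (two scopes)
    panel_pooled, scalers_pooled = transform_and_standardize(panel, specs, "pooled")
    panel_perpop, _ = transform_and_standardize(panel, specs, "per_population")
    populations = sorted(panel["population"].unique())

    # --- stage 2: population mean comparisons
    comparisons = []
    for s in specs:
        try:
            if s.role == "life_history":
                comparisons.append(compare_mod.compare_lht_means(panel_pooled, s.trait))
            else:
                comparisons.append(compare_mod.compare_behaviour_smr(panel_pooled, s.trait))
        except ValueError as exc:
            report["exclusions"].append({"stage": "compare", "trait": s.trait, "reason": str(exc)})
    report["comparisons"] = [c.to_dict() for c in comparisons]
    pd.DataFrame([c.to_dict() for c in comparisons]).to_csv(out / "comparisons.csv", index=False)

    # --- stage 3: repeatability + gate
    rep = repeatability_table(
        panel_perpop, spec_traits, populations, specs,
        n_boot=config.bootstrap_draws, seed=config.seed + 1,
    )
    rep.to_csv(out / "repeatability.csv", index=False)
    report["repeatability"] = rep.to_dict(orient="records")
    for r in rep.itertuples():
        if r.sigma_ind < 1e-8:
            report["boundary_events"].append(
                {"stage": "repeatability", "population": r.population, "trait": r.trait,
                 "event": "sigma_ind at boundary 0"}
            )
    gated = []
    for t in spec_traits:
        ps = rep.loc[rep["trait"] == t, "lrt_p"]
        if (ps < config.gate_alpha).all():
            gated.append(t)
        else:
            report["exclusions"].append(
                {"stage": "repeatability_gate", "trait": t,
                 "reason": f"LRT p >= {config.gate_alpha} in at least one population"}
            )
    report["repeatable_traits"] = gated

    # --- stage 4: covariance decomposition per population
    report["decompositions"] = {}
    report["structure_tests"] = {}
    if len(gated) >= 2:
        for pop in populations:
            dec = pols_mod.decompose(
                panel_perpop, gated, pop,
                n_boot=config.bootstrap_draws, seed=config.seed + 2,
            )
            if not dec.fit.converged:
                raise ConvergenceError(f"multivariate fit for population {pop} did not converge")
            report["decompositions"][pop] = dec.to_dict()
            overall = pols_mod.test_overall_structure(
                panel_perpop, gated, pop, full_fit=dec.fit
            )
            report["structure_tests"][pop] = overall.to_dict()
            pd.DataFrame(dec.corr_ind, index=gated, columns=gated).to_csv(
                out / f"corr_ind_{pop}.csv"
            )
            (out / f"decomposition_{pop}.json").write_text(
                json.dumps(dec.to_dict(), indent=2, sort_keys=True)
            )
            (out / f"report_{pop}.txt").write_text(dec.report() + "\n")
        if len(populations) == 2:
            eq = pols_mod.test_population_equality(panel_perpop, gated)
            report["population_equality"] = eq.to_dict()
    else:
        report["exclusions"].append(
            {"stage": "pols", "reason": f"fewer than 2 repeatable traits ({gated})"}
        )

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
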