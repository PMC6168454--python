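"""Trait transformations, covariate coding and derived life-history quantities.

Behavioural, physiological and life-history measurements arrive as a long
panel (one row per measurement).  Before any mixed-model fitting the panel
is put on the analysis scale: skewed traits are log- or square-root
transformed, every response is mean-centred and scaled to unit variance
(so variance components are comparable across traits), and the two-level
design covariates sex and ontogenetic stage are coded as -0.5 / +0.5 so
that main effects are evaluated at the design midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "default_trait_specs",
    "transform_and_standardize",
    "code_covariates",
    "fulton_k",
    "PANEL_COLUMNS",
]

#: canonical long-format panel columns
PANEL_COLUMNS = [
    "individual_id",
    "population",
    "sex",
    "age_stage",
    "trial",
    "trait",
    "value",
]

SEX_CODES = {"female": -0.5, "male": 0.5, "f": -0.5, "m": 0.5}
STAGE_CODES = {"immature": -0.5, "adult": 0.5}
_CODED = (-0.5, 0.5)


@dataclass(frozen=True)
class TraitSpec:
    """How one trait is handled before modelling.

    Parameters
    ----------
    trait
        Trait label as it appears in the panel.
    transform
        Normalising transform applied before standardization. ``log``
        requires strictly positive values, ``sqrt`` non-negative ones.
    role
        Broad trait class (behaviour / physiology / life_history); used to
        decide which fixed effects apply (behavioural traits carry a
        within-stage trial covariate).
    measured_per_stage
        Number of repeat measures per ontogenetic stage.
    """

    trait: str
    transform: Literal["none", "log", "sqrt"] = "none"
    role: Literal["behaviour", "physiology", "life_history"] = "behaviour"
    measured_per_stage: int = 1


def default_trait_specs() -> list[TraitSpec]:
    """Specs for the seven modelled traits of the mosquitofish design.

    Emergence latency is log-transformed; hiding time, freezing time and
    mass-specific SMR are square-root transformed; behavioural traits are
    measured twice per stage, SMR and the size traits once per stage.
    """
    return [
        TraitSpec("emergence_latency", "log", "behaviour", 2),
        TraitSpec("hiding_time", "sqrt", "behaviour", 2),
        TraitSpec("freezing_time", "sqrt", "behaviour", 2),
        TraitSpec("distance_moved", "none", "behaviour", 2),
        TraitSpec("smr", "sqrt", "physiology", 1),
        TraitSpec("standard_size", "none", "life_history", 1),
        TraitSpec("fulton_k", "none", "life_history", 1),
    ]


def specs_to_frame(specs: Iterable[TraitSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.trait, s.transform, s.role, s.measured_per_stage) for s in specs],
        columns=["trait", "transform", "role", "measured_per_stage"],
    )


def specs_from_frame(df: pd.DataFrame) -> list[TraitSpec]:
    return [
        TraitSpec(r.trait, r.transform, r.role, int(r.measured_per_stage))
        for r in df.itertuples()
    ]


def _apply_transform(values: pd.Series, transform: str, trait: str) -> pd.Series:
    if transform == "none":
        return values
    if transform == "log":
        bad = values <= 0
        if bad.any():
            idx = values.index[bad][0]
            raise ValueError(
                f"log transform of trait {trait!r} requires positive values; "
                f"record at panel index {idx} has value {values.loc[idx]!r}"
            )
        return np.log(values)
    if transform == "sqrt":
        bad = values < 0
        if bad.any():
            idx = values.index[bad][0]
            raise ValueError(
                f"sqrt transform of trait {trait!r} requires non-negative values; "
                f"record at panel index {idx} has value {values.loc[idx]!r}"
            )
        return np.sqrt(values)
    raise ValueError(f"unknown transform {transform!r}")


def transform_and_standardize(
    panel: pd.DataFrame,
    specs: Iterable[TraitSpec],
    scope: Literal["pooled", "per_population"] = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transform trait values, then mean-centre and scale to unit variance.

    Standardization is computed either pooled across populations (so that
    population mean differences survive centring and can be tested) or
    within each population (for within-population covariance models).

    Returns
    -------
    (panel, scalers)
        A copy of the panel with transformed, standardized ``value``s and a
        table of the applied means and SDs (per trait, and per population
        when ``scope="per_population"``) for back-transformation.
    """
    if scope not in ("pooled", "per_population"):
        raise ValueError(f"scope must be 'pooled' or 'per_population', got {scope!r}")
    spec_map = {s.trait: s for s in specs}
    missing = set(panel["trait"].unique()) - set(spec_map)
    if missing:
        raise ValueError(f"no TraitSpec for panel trait(s): {sorted(missing)}")

    out = panel.copy()
    keys = ["trait"] if scope == "pooled" else ["trait", "population"]
    scaler_rows = []
    for group_key, idx in out.groupby(keys, sort=True).groups.items():
        if not isinstance(group_key, tuple):
            group_key = (group_key,)
        trait = group_key[0]
        spec = spec_map[trait]
        vals = _apply_transform(out.loc[idx, "value"].astype(float), spec.transform, trait)
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            sd = 1.0  # constant trait: centre only
        out.loc[idx, "value"] = (vals - mu) / sd
        scaler_rows.append(dict(zip(keys, group_key)) | {"mean": mu, "sd": sd})
    scalers = pd.DataFrame(scaler_rows)
    return out, scalers


def _code_column(col: pd.Series, mapping: dict[str, float], name: str) -> pd.Series:
    def code_one(v):
        if isinstance(v, str):
            key = v.strip().lower()
            if key in mapping:
                return mapping[key]
            raise ValueError(
                f"unknown {name} label {v!r}; accepted labels: "
                f"{sorted(set(mapping))} or already-coded values {_CODED}"
            )
        fv = float(v)
        if fv not in _CODED:
            raise ValueError(
                f"{name} value {v!r} is neither a label in {sorted(set(mapping))} "
                f"nor one of the coded values {_CODED}"
            )
        return fv

    return col.map(code_one).astype(float)


def code_covariates(panel: pd.DataFrame) -> pd.DataFrame:
    """Code sex and ontogenetic stage as -0.5 / +0.5.

    Immature fish and females are coded -0.5; adults and males +0.5.
    Already-coded panels pass through unchanged (the mapping is a
    projection: applying it twice equals applying it once).
    """
    out = panel.copy()
    out["sex"] = _code_column(out["sex"], SEX_CODES, "sex")
    out["age_stage"] = _code_column(out["age_stage"], STAGE_CODES, "age_stage")
    return out


def fulton_k(weight_g, length_mm):
    """Fulton's condition factor K = 1e4 * weight / length**3 (g mm^-3 1e4).

    A nutritional-state index: the weight of the fish relative to the cube
    of its standard length. Accepts scalars or arrays.
    """
    weight = np.asarray(weight_g, dtype=float)
    length = np.asarray(length_mm, dtype=float)
    if np.any(weight <= 0) or np.any(length <= 0):
        raise ValueError("fulton_k requires positive weight (g) and length (mm)")
    k = 1e4 * weight / length**3
    return float(k) if k.ndim == 0 else k


def validate_panel(panel: pd.DataFrame) -> None:
    """Check the long-format panel schema and record uniqueness."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing column(s): {missing}")
    dup = panel.duplicated(subset=["individual_id", "age_stage", "trial", "trait"])
    if dup.any():
        first = panel[dup].iloc[0]
        raise ValueError(
            "duplicate measurement record: individual "
            f"{first['individual_id']!r}, stage {first['age_stage']!r}, "
            f"trial {first['trial']!r}, trait {first['trait']!r}"
        )
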