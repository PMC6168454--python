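import numpy as np
import pandas as pd
import pytest

from polskit.simulate import (
    SimulationConfig,
    default_study_config,
    generate_trait_panel,
)


@pytest.fixture(scope="session")
def study_panel() -> pd.DataFrame:
    """One study-scale panel (2 populations x 40 fish, 4 core traits)."""
    return generate_trait_panel(default_study_config(seed=20240901))


def univariate_config(
    sigma_ind: float,
    sigma_res: float,
    n: int = 100,
    per_stage: int = 1,
    seed: int = 0,
    populations: tuple[str, ...] = ("SG",),
    beta: dict | None = None,
) -> SimulationConfig:
    """Single-trait generator config used across the model tests."""
    return SimulationConfig(
        n_individuals_per_population=n,
        trait_names=["x"],
        populations=populations,
        sigma_ind={p: np.array([[sigma_ind]]) for p in populations},
        sigma_res={p: np.array([[sigma_res]]) for p in populations},
        beta={p: (beta or {}) for p in populations},
        measurement_schedule={"x": per_stage},
        missing_rate={},
        seed=seed,
    )


def bivariate_config(
    corr_ind: float,
    n: int = 40,
    var_ind: tuple[float, float] = (0.3, 0.3),
    var_res: tuple[float, float] = (0.7, 0.7),
    res_corr: float = 0.1,
    seed: int = 0,
    populations: tuple[str, ...] = ("SG",),
    sign_by_pop: dict | None = None,
    per_stage: int = 2,
) -> SimulationConfig:
    """Two behavioural traits sharing occasions, 2 trials x 2 stages."""
    def cov(c):
        sd = np.sqrt(np.array(var_ind))
        S = np.eye(2) * np.array(var_ind)
        S[0, 1] = S[1, 0] = c * sd[0] * sd[1]
        return S

    sr = np.eye(2) * np.array(var_res)
    sr[0, 1] = sr[1, 0] = res_corr * np.sqrt(var_res[0] * var_res[1])
    return SimulationConfig(
        n_individuals_per_population=n,
        trait_names=["a", "b"],
        populations=populations,
        sigma_ind={
            p: cov((sign_by_pop or {}).get(p, corr_ind)) for p in populations
        },
        sigma_res={p: sr for p in populations},
        beta={p: {} for p in populations},
        measurement_schedule={"a": per_stage, "b": per_stage},
        missing_rate={},
        seed=seed,
    )
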