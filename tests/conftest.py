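import numpy as np
import pandas as pd
import pytest

from trimtrack import SimulationConfig, simulate_cohort


def growth_sim_config(n_women=1457, psi00=1.0, psi11=0.25, psi01=0.0,
                      theta=0.5, seed=0, **kwargs):
    """One-measure cohort with known growth parameters and no covariate or
    outcome effects; the workhorse configuration for parameter-recovery and
    calibration simulations."""
    defaults = dict(
        n_women=n_women,
        measures=("PLATE",),
        latent_mean_intercept=10.0,
        latent_mean_slope=0.5,
        psi00=psi00, psi11=psi11, psi01=psi01, theta=theta,
        age_effect=0.0,
        origin_effects={"EUR": 0.0, "AFR": 0.0, "ASI": 0.0, "OTH": 0.0},
        gamma_path={},
        draws_per_trimester=1,
        missing_rate=0.0,
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Default-parameter cohort of 300 women used by preprocessing tests."""
    return simulate_cohort(SimulationConfig(n_women=300, seed=1))


@pytest.fixture(scope="session")
def growth_matrix() -> pd.DataFrame:
    """Complete trimester matrix simulated under known growth parameters."""
    from trimtrack import aggregate_trimesters, filter_complete_three_trimester
    table = simulate_cohort(growth_sim_config(n_women=600, seed=7))
    return filter_complete_three_trimester(aggregate_trimesters(table, "PLATE"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
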