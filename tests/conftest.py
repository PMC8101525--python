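import numpy as np
import pytest

from curefrail import (
    CureModelParams,
    Dataset,
    registry_like_scenario,
    simulate_dataset,
)


@pytest.fixture
def toy_dataset() -> Dataset:
    """Two records without covariates: one event at t=1, one censored at
    t=2."""
    return Dataset(time=[1.0, 2.0], event=[1, 0], covariates=np.empty((2, 0)),
                   covariate_names=[])


@pytest.fixture
def toy_params() -> CureModelParams:
    """Near-no-frailty exponential latency with a 50% cure fraction."""
    return CureModelParams(b0=0.0, b=[], beta=[], shape=1.0, scale=0.5,
                           theta=1e8)


@pytest.fixture
def registry_cohort():
    """Factory for simulated registry-like cohorts."""

    def make(n: int = 1000, seed: int = 3) -> Dataset:
        return simulate_dataset(registry_like_scenario(n=n, seed=seed))

    return make


@pytest.fixture
def one_covariate_scenario():
    """Small single-covariate scenario used for recovery simulations:
    true (b0=-0.8, b=0.6, beta=0.5, shape=1.2, scale=0.05, theta=2)."""
    from curefrail import CensoringConfig, CovariateSpec, ScenarioConfig

    def make(n: int = 2000, seed: int = 0, theta: float = 2.0) -> "ScenarioConfig":
        return ScenarioConfig(
            n=n,
            covariates=[CovariateSpec("group", ("a", "b"), (0.5, 0.5))],
            true_params=CureModelParams(b0=-0.8, b=[0.6], beta=[0.5],
                                        shape=1.2, scale=0.05, theta=theta),
            censoring=CensoringConfig(horizon=168.0, rate=0.008),
            seed=seed,
            name="one-covariate",
        )

    return make
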