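import numpy as np
import pytest
from hypothesis import settings

from woodocc.inference import McmcConfig, fit_dataset
from woodocc.model import ModelConfig
from woodocc.synthetic import SimulationConfig, generate_dataset

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def reduced_model() -> ModelConfig:
    """Intercept + 4 occupancy predictors + 1 interaction, 2 detection
    covariates, no spatial term — the scaled-down recovery model."""
    return ModelConfig(
        occupancy_mains=["age", "area", "current_woodland", "arable"],
        occupancy_interactions=[("area", "arable")],
        include_country=False,
        detection_covariates=["day", "year"],
        detection_quadratic=[],
        n_factors=0,
        perfect_detection=False,
    )


@pytest.fixture(scope="session")
def recovery_dataset():
    """15 species x 60 sites x 3 visits simulated under the reduced model."""
    config = SimulationConfig(
        n_species=15, n_sites=60, n_visits=3, model=reduced_model(), seed=11
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def recovery_posterior(recovery_dataset):
    """4-chain fit of the recovery dataset at the desk-scale protocol."""
    mcmc = McmcConfig(n_chains=4, n_burnin=2000, n_samples=500, thin=2, seed=5)
    return fit_dataset(recovery_dataset, mcmc)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small dataset for fast non-acceptance inference tests."""
    model = ModelConfig(
        occupancy_mains=["age", "area"],
        occupancy_interactions=[],
        include_country=False,
        detection_covariates=["day"],
        detection_quadratic=[],
        n_factors=0,
    )
    config = SimulationConfig(n_species=8, n_sites=40, n_visits=3, model=model, seed=2)
    return generate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
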