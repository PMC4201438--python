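import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mangal import SimConfig, SpeciesParams, spinup

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> SpeciesParams:
    return SpeciesParams()


@pytest.fixture(scope="session")
def config() -> SimConfig:
    return SimConfig()


#: Seeds of the replicated spinup pool (the study's stochastic conditions).
POOL_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def spinup_pool(config):
    """Ten full 300-year spinups from a bare domain (shared by slow tests)."""
    return {seed: spinup(config, seed, trace_every=25) for seed in POOL_SEEDS}


@pytest.fixture(scope="session")
def equilibrium_stand(spinup_pool):
    """One equilibrium snapshot reused across impact-scenario tests."""
    return spinup_pool[POOL_SEEDS[0]].stand


def rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))
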