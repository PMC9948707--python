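import numpy as np
import pytest

from seaphage.simulate import ScenarioConfig, simulate_scenario


@pytest.fixture(scope="session")
def default_config() -> ScenarioConfig:
    return ScenarioConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    """The reference synthetic scenario (seed 1), shared across tests."""
    return simulate_scenario(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
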