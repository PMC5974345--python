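import numpy as np
import pytest

from chlorolake import default_lotus_parameters, lotus_scenario, simulate


@pytest.fixture(scope="session")
def default_ps():
    return default_lotus_parameters()


@pytest.fixture(scope="session")
def lotus():
    """The packaged scenario with its parameter set (seed 1, noiseless forcing)."""
    scenario, ps_set = lotus_scenario(seed=1)
    return scenario, ps_set


@pytest.fixture(scope="session")
def lotus_traj(lotus):
    scenario, ps_set = lotus
    return simulate(scenario, ps_set)


@pytest.fixture
def rng():
    return np.random.default_rng(20150315)
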