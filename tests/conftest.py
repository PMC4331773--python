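import numpy as np
import pytest

import epidrift as ed


@pytest.fixture(scope="session")
def params():
    return ed.RegulationParams()


@pytest.fixture(scope="session")
def genome():
    """The default fixture genome used by the simulation presets."""
    return ed.default_genome()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def isolated_trajectory():
    """One age-independent run without exchange, shared across tests."""
    return ed.run_from_spec(
        ed.ScenarioSpec(preset="no-arp-isolated", steps=6000, seed=1)
    )


@pytest.fixture(scope="session")
def exchange_trajectory():
    """One age-independent run with exchange, shared across tests."""
    return ed.run_from_spec(
        ed.ScenarioSpec(preset="no-arp-exchange", steps=6000, seed=1)
    )
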