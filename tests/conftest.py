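import numpy as np
import pytest

from n15scape import SimulationConfig, build_scenario
from n15scape.gamm import GAMMSpec, fit


def small_config(seed=7, **kw):
    """A cheap but fully featured scenario configuration for unit tests."""
    params = dict(extent_m=(340.0, 340.0), canopy_area_range_m2=(8.3, 150.0),
                  n_canopies=10, seed=seed)
    params.update(kw)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def default_scenario():
    """Scenario generated with the all-default configuration."""
    return build_scenario(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_scenario():
    return build_scenario(small_config())


@pytest.fixture(scope="session")
def default_fit(default_scenario):
    return fit(default_scenario.table, GAMMSpec())


@pytest.fixture(scope="session")
def small_fit(small_scenario):
    return fit(small_scenario.table, GAMMSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
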