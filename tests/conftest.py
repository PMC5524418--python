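import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from isrnet import (
    HHParams,
    NeuronState,
    find_resting_equilibrium,
    deterministic_orbit,
)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(12345))


@pytest.fixture(scope="session")
def params():
    return HHParams()


@pytest.fixture(scope="session")
def resting_state():
    return find_resting_equilibrium()


@pytest.fixture(scope="session")
def limit_cycle_state(resting_state):
    """A point on the stable spiking limit cycle, found by kicking the
    voltage well above threshold and integrating past the transient."""
    eq = resting_state
    kicked = NeuronState(
        np.array([60.0]), np.array([eq.m]), np.array([eq.h]), np.array([eq.n])
    )
    res = deterministic_orbit(kicked, 500.0)
    assert res.raster.n_spikes > 10  # must actually be spiking
    return res.final_state


@pytest.fixture(scope="session")
def deterministic_rate(limit_cycle_state):
    """Deterministic firing rate (Hz) on the limit cycle."""
    res = deterministic_orbit(limit_cycle_state, 2000.0)
    return res.raster.n_spikes / 2.0
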