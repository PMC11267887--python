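import numpy as np
import pytest

from ssbmd import phantoms, physics
from ssbmd.pipeline import default_imaging_setup

TEST_PITCH = 0.15  # cm; 24 x 12 cm field -> 80 x 160 pixels


@pytest.fixture(scope="session")
def imaging_setup():
    """(ForearmParams, SystemModel) at the desk-scale test resolution."""
    return default_imaging_setup(TEST_PITCH)


@pytest.fixture(scope="session")
def system(imaging_setup):
    return imaging_setup[1]


@pytest.fixture(scope="session")
def forearm_population(imaging_setup):
    """20 seeded forearm phantoms with their ground-truth geometry."""
    params, _ = imaging_setup
    return [phantoms.make_forearm_phantom(params, seed=s) for s in range(20)]


@pytest.fixture(scope="session")
def forearm_exposure(imaging_setup):
    """One phantom with its noiseless radiograph."""
    params, system = imaging_setup
    model, geometry = phantoms.make_forearm_phantom(params, seed=7)
    radiograph = physics.simulate_radiograph(model, system, mas=2.0, noiseless=True)
    return model, geometry, radiograph


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
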