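import numpy as np
import pytest

from invasionfill.betareg import MCMCSettings
from invasionfill.niche import build_climate_space
from invasionfill.synthetic_world import (SpeciesTruth, WorldConfig,
                                          make_species, make_world)


@pytest.fixture(scope="session")
def world():
    """Default-sized synthetic world shared by fast tests."""
    return make_world(WorldConfig(seed=1))


@pytest.fixture(scope="session")
def space(world):
    return build_climate_space(world, native_realm=1, introduced_realm=2)


@pytest.fixture(scope="session")
def truth(world):
    clim = world.realm_climate(1)[:, [0, 2]]
    centre = np.median(clim, axis=0)
    sd = clim.std(axis=0) * 0.5
    return SpeciesTruth("testsp", centre, np.diag(sd ** 2),
                        native_realm=1, introduced_realm=2, f_true=0.5)


@pytest.fixture(scope="session")
def occurrences(world, truth):
    return make_species(world, truth, n_native=150, rng=np.random.default_rng(3))


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short chains for tests that exercise machinery, not posterior accuracy."""
    return MCMCSettings(n_burn=4000, n_draws=8000, max_extensions=1)
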