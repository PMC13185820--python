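import warnings

import numpy as np
import pytest

from stabcouple import WorldConfig, generate_world, sample_sites
from stabcouple.composite_indices import extract_at_sites

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def coupled_world():
    return generate_world(WorldConfig(grid_rows=30, grid_cols=30, seed=11))


@pytest.fixture(scope="session")
def decoupled_world():
    return generate_world(
        WorldConfig(grid_rows=30, grid_cols=30, coupling_mode="decoupled", seed=11)
    )


@pytest.fixture(scope="session")
def small_world():
    return generate_world(WorldConfig(grid_rows=16, grid_cols=16, n_ecosystems=4, seed=2))


@pytest.fixture(scope="session")
def site_design(coupled_world):
    tab = sample_sites(coupled_world, n_sites=300, max_years_per_site=8,
                       obs_noise_sd=40.0, seed=3)
    return extract_at_sites(coupled_world.indices, tab)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
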