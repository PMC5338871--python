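import numpy as np
import pytest

import reefspawn as rs


@pytest.fixture(scope="session")
def small_config():
    return rs.SimulationConfig(seed=11, n_sets_per_year=40, n_years=6)


@pytest.fixture(scope="session")
def small_survey(small_config):
    """One modest synthetic survey shared by read-only tests."""
    bathy = rs.generate_bathymetry(small_config)
    stack = rs.compute_terrain(bathy)
    table = rs.generate_survey(small_config, bathy, stack)
    return small_config, bathy, stack, table


@pytest.fixture(scope="session")
def random_grid():
    """Random 25x25 depth grid for oracle-equivalence tests."""
    rng = np.random.default_rng(42)
    depth = 50.0 + 10.0 * rng.standard_normal((25, 25))
    return rs.BathymetryGrid(values=np.abs(depth) + 5.0, cell_size=90.0)
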