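import warnings

import numpy as np
import pytest

from megnet import (HeadModel, build_source_grid, compute_leadfield,
                    make_sensor_cap)


@pytest.fixture(scope="session")
def head():
    return HeadModel(radius=0.09)


@pytest.fixture(scope="session")
def grid(head):
    """93-node test grid: 3 cm lattice inside the 9 cm sphere."""
    return build_source_grid(head, 0.03)


@pytest.fixture(scope="session")
def sensors(head):
    return make_sensor_cap(head, n_sensors=64)


@pytest.fixture(scope="session")
def leadfield(grid, sensors, head):
    with warnings.catch_warnings():
        # the grid contains the sphere-centre node, which is silent
        warnings.simplefilter("ignore", RuntimeWarning)
        return compute_leadfield(grid, sensors, head)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
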