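import numpy as np
import pytest

from megfocus import (
    SphereModel,
    build_sensor_array,
    build_source_grid,
    compute_leadfield,
)


@pytest.fixture(scope="session")
def sphere():
    return SphereModel(center=np.zeros(3), radius=0.09)


@pytest.fixture(scope="session")
def sensors():
    """Compact 32-channel array for fast unit tests."""
    return build_sensor_array(32, 0.12, 0.55, 0.05)


@pytest.fixture(scope="session")
def sensors160():
    return build_sensor_array(160, 0.12, 0.55, 0.05)


@pytest.fixture(scope="session")
def grid(sphere):
    """Coarse grid (~430 voxels, 34 regions)."""
    return build_source_grid(sphere, spacing=0.018, n_regions=34, margin=0.005)


@pytest.fixture(scope="session")
def leadfield(grid, sensors, sphere):
    return compute_leadfield(grid, sensors, sphere)


@pytest.fixture(scope="session")
def leadfield160(grid, sensors160, sphere):
    return compute_leadfield(grid, sensors160, sphere)


@pytest.fixture(scope="session")
def grid12(sphere):
    """Benchmark-scale grid (~1470 voxels, 12 mm spacing)."""
    return build_source_grid(sphere, spacing=0.012, n_regions=34, margin=0.005)


@pytest.fixture(scope="session")
def leadfield12(grid12, sensors160, sphere):
    return compute_leadfield(grid12, sensors160, sphere)
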