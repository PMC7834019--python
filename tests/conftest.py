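import numpy as np
import pytest
from hypothesis import settings

from saltnav import PlateGeometry, Trajectory, build_field, field_from_function

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_geometry():
    return PlateGeometry()


@pytest.fixture(scope="session")
def default_field(default_geometry):
    """The standard 19-h gradient on the standard plate (1-mm grid)."""
    return build_field(default_geometry)


@pytest.fixture
def planar_field():
    """C = 2x mM on an off-plate-free square grid (gradient (2, 0))."""
    return field_from_function(lambda x, y: 2.0 * x + 100.0, extent=50.0)


def make_track(positions, dt=1.0, track_id="t0", t0=0.0):
    positions = np.asarray(positions, dtype=float)
    times = t0 + dt * np.arange(len(positions))
    return Trajectory(track_id, times, positions)


@pytest.fixture
def straight_track():
    """Eastward at 0.1 mm/s for 60 s."""
    xs = 0.1 * np.arange(61)
    return make_track(np.column_stack([xs, np.zeros(61)]))
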