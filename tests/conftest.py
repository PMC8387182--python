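import numpy as np
import pytest

from asdmetry.core import CartesianVolume
from asdmetry.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Reduced-size phantom used by unit tests (fast to acquire/segment)."""
    return PhantomSpec(
        grid_shape=(80, 80, 48),
        chamber_radius=9.0,
        wall_thickness=2.5,
        defect_long=8.0,
        defect_short=6.0,
        defect_angle=30.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def study_spec() -> PhantomSpec:
    """Phantom at the resolution used by the replication study."""
    return PhantomSpec(defect_long=10.0, defect_short=7.0, defect_angle=25.0)


@pytest.fixture(scope="session")
def study_phantom(study_spec):
    return generate_phantom(study_spec)


@pytest.fixture()
def smooth_volume() -> CartesianVolume:
    """Smooth non-symmetric test volume for resampling checks."""
    ax = np.arange(64) - 31.5
    az = np.arange(32) - 15.5
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    data = 100 + 80 * np.sin(X / 6) * np.cos(Y / 7) + 20 * np.cos(Z / 5)
    return CartesianVolume(data, (1.0, 1.0, 1.0))
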