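import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ringtomo as rt

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geom():
    return rt.RingGeometry()


@pytest.fixture(scope="session")
def medium():
    return rt.Medium()


@pytest.fixture(scope="session")
def pulse():
    return rt.Pulse()


@pytest.fixture(scope="session")
def centered_cylinder():
    """20 mm diameter cylinder on the rotation axis, spanning z=-30..30."""
    return rt.Phantom(reflectors=(rt.Cylinder((0.0, 0.0, 0.0), 10.0, 60.0),))


@pytest.fixture(scope="session")
def cylinder_sinogram(geom, medium, pulse, centered_cylinder):
    """Noise-free 8-angle sinogram of the centered cylinder (fast)."""
    plan = rt.build_full_circle_plan(geom, 45.0, [1])
    return rt.simulate_sinogram(
        geom, centered_cylinder, medium, pulse, plan, noise_sigma=0.0, seed=0
    )


def coarse_grid():
    return rt.GridSpec(pixel_size_mm=2.0, extent_mm=180.0)


@pytest.fixture
def flat_disk_image():
    """Synthetic perfect disk of diameter 20 mm at 0.5 mm pixels (no DR
    metadata, so the caliper thresholds pixel values directly)."""
    n = 101
    c0 = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r_mm = np.hypot(yy - c0, xx - c0) * 0.5
    pixels = (r_mm <= 10.0).astype(float)
    return rt.SliceImage(
        pixels=pixels,
        pixel_size_mm=0.5,
        element=1,
        mask=np.ones((n, n), dtype=bool),
    )
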