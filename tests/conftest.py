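import numpy as np
import pytest

from zebra3d.body import FishPose, FixedBodyParameters
from zebra3d.camera import fit_refractive_projection
from zebra3d.optics import TankOptics, default_rig, simulate_dot_grid
from zebra3d.render import LookupTableP


@pytest.fixture(scope="session")
def optics():
    return TankOptics()


@pytest.fixture(scope="session")
def rig(optics):
    return default_rig(optics)


@pytest.fixture(scope="session")
def dot_obs(optics, rig):
    """Ray-traced calibration dot grid (shared across the session)."""
    return simulate_dot_grid(optics, rig)


@pytest.fixture(scope="session")
def proj(dot_obs, rig):
    """Separable cubic projection fitted to the simulated refracted dots."""
    return fit_refractive_projection(dot_obs.dots3d, dot_obs.pixels_water,
                                     cams=rig)


@pytest.fixture(scope="session")
def lookup_table():
    return LookupTableP()


@pytest.fixture
def fixed():
    return FixedBodyParameters()


@pytest.fixture
def bent_pose():
    return FishPose(x0=1.0, y0=-2.0, z0=0.5, theta0=0.4, phi0=0.15,
                    gamma0=0.1, dtheta=np.linspace(0.05, 0.3, 8),
                    dphi=np.full(8, 0.02), length=4.0)


def random_pose(rng, position_scale=5.0, lateral=0.25, dorsal=0.06,
                length=4.0):
    """A random valid pose inside the central imaging volume."""
    return FishPose(
        x0=rng.uniform(-position_scale, position_scale),
        y0=rng.uniform(-position_scale, position_scale),
        z0=rng.uniform(-position_scale, position_scale),
        theta0=rng.uniform(-np.pi, np.pi),
        phi0=rng.uniform(-0.3, 0.3), gamma0=rng.uniform(-0.3, 0.3),
        dtheta=rng.uniform(-lateral, lateral, 8),
        dphi=rng.uniform(-dorsal, dorsal, 8), length=length)
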