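"""Ray-tracing simulator of the tank optics.

Models the flat water -> glass -> air path from a point inside a cubic
water tank to each of three orthogonal pinhole cameras, applying Snell's
law at the two planar interfaces normal to the camera's principal axis.
Used to synthesize calibration dot grids and as an independent oracle for
the empirical cubic projection fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .camera import PinholeCamera, project_linear

__all__ = [
    "TankOptics",
    "default_rig",
    "simulate_refraction",
    "simulate_dot_grid",
    "DotGridObservation",
]


@dataclass
class TankOptics:
    """Geometry and refractive indices of the imaging tank.

    ``tank_side`` is the inner side length of the cube (mm); interfaces sit
    at +-tank_side/2 along each camera's principal axis, with a glass slab
    of ``glass_thickness`` outside.
    """

    tank_side: float = 70.0
    glass_thickness: float = 2.5
    n_air: float = 1.0
    n_glass: float = 1.52
    n_water: float = 1.33
    camera_distance: float = 180.0  # optical center to tank center, mm

    def __post_init__(self) -> None:
        if self.n_air != 1.0:
            raise ValueError("n_air must be 1.0")
        if self.n_glass <= 1.0 or self.n_water <= 1.0:
            raise ValueError("glass and water indices must exceed 1")


def default_rig(optics: TankOptics | None = None,
                focal_px: float = 2100.0,
                sensor_shape: tuple[int, int] = (488, 648)) -> list[PinholeCamera]:
    """Three orthogonal pinhole cameras looking at the tank center.

    Camera 0 is the bottom camera viewing along +z; cameras 1 and 2 view
    along +x and +y. Principal points sit at the sensor center.
    """
    optics = optics or TankOptics()
    d = optics.camera_distance
    ny, nx = sensor_shape
    pp = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    rigs = [
        # rows of R are the camera axes (x_cam, y_cam, z_cam) in lab coords
        np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]),          # view +z
        np.array([[0, 1.0, 0], [0, 0, 1.0], [1.0, 0, 0]]),          # view +x
        np.array([[0, 0, 1.0], [1.0, 0, 0], [0, 1.0, 0]]),          # view +y
    ]
    cams = []
    for R in rigs:
        center = -d * R[2]  # camera sits on the negative principal axis
        t = -R @ center
        cams.append(PinholeCamera((focal_px, focal_px), pp, R, t))
    return cams


def _snell_path_offset(s_air: float, rho: float, d_w: float, d_g: float,
                       d_a: float, n_w: float, n_g: float, n_a: float) -> float:
    """Transverse distance covered by a ray exiting at air-side sine s_air,
    minus the required offset rho (root function for the shooting solve)."""
    s_g = n_a * s_air / n_g
    s_w = n_a * s_air / n_w
    t = (d_w * s_w / np.sqrt(1 - s_w**2)
         + d_g * s_g / np.sqrt(1 - s_g**2)
         + d_a * s_air / np.sqrt(1 - s_air**2))
    return t - rho


def simulate_refraction(optics: TankOptics, cam: PinholeCamera,
                        point: np.ndarray) -> np.ndarray:
    """Pixel coordinates of a point in water seen through the tank wall.

    Solves the two-interface Snell problem by a 1-D shooting solve on the
    exit-angle sine (the path lies in the plane spanned by the principal
    axis and the transverse offset), then projects the emergent ray through
    the linear camera model. Raises on total internal reflection and for
    points outside the water volume.
    """
    point = np.asarray(point, dtype=float)
    half = optics.tank_side / 2.0
    if np.any(np.abs(point) > half):
        raise ValueError("point outside water volume")
    axis = cam.principal_axis  # unit lab vector, camera views along +axis
    C = cam.center
    # axial coordinates measured along the viewing direction
    p_ax = float(point @ axis)
    c_ax = float(C @ axis)
    # interfaces on the camera side (camera sits at negative axial coord)
    inner = -half
    outer = -half - optics.glass_thickness
    d_w = p_ax - inner          # water path length along axis
    d_g = optics.glass_thickness
    d_a = inner - optics.glass_thickness - c_ax
    if d_w < 0 or d_a <= 0:
        raise ValueError("point/camera on wrong side of the interfaces")
    trans = (point - p_ax * axis) - (C - c_ax * axis)
    rho = float(np.linalg.norm(trans))
    n_w, n_g, n_a = optics.n_water, optics.n_glass, optics.n_air
    if rho < 1e-12:
        # normal incidence: ray is undeviated
        return project_linear(cam, point)
    s_max = min(n_w / n_a, n_g / n_a, 1.0) - 1e-12
    f_hi = _snell_path_offset(s_max, rho, d_w, d_g, d_a, n_w, n_g, n_a)
    if f_hi < 0:
        raise ValueError("total internal reflection: no refracted path")
    s = brentq(_snell_path_offset, 0.0, s_max,
               args=(rho, d_w, d_g, d_a, n_w, n_g, n_a), xtol=1e-14)
    # exit point on the outer glass face
    u = trans / rho
    s_w = n_a * s / n_w
    s_g = n_a * s / n_g
    t_w = d_w * s_w / np.sqrt(1 - s_w**2)
    t_g = d_g * s_g / np.sqrt(1 - s_g**2)
    p_trans = point - p_ax * axis
    exit_pt = p_trans - (t_w + t_g) * u + outer * axis
    return project_linear(cam, exit_pt)


def _grid_points(n: int, pitch: float) -> np.ndarray:
    half = (n - 1) / 2.0
    return (np.arange(n) - half) * pitch


@dataclass
class DotGridObservation:
    """Dot-grid correspondences with and without refraction.

    ``dots3d`` are the true lab positions; ``pixels_air``/``pixels_water``
    are per-camera (N, 2) projections without / with the tank in place.
    """

    dots3d: np.ndarray
    pixels_air: list[np.ndarray]
    pixels_water: list[np.ndarray]
    dot_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.dot_ids is None:
            self.dot_ids = np.arange(len(self.dots3d))
        for pa, pw in zip(self.pixels_air, self.pixels_water):
            if len(pa) != len(self.dots3d) or len(pw) != len(self.dots3d):
                raise ValueError("air and water sets must have the same dot count")


def simulate_dot_grid(
    optics: TankOptics | None = None,
    cams: list[PinholeCamera] | None = None,
    n_dots: int = 9,
    pitch: float = 3.75,
    plane_offsets: tuple[float, ...] = (-12.0, -4.0, 4.0, 12.0),
    noise_px: float = 0.0,
    seed: int | None = None,
) -> DotGridObservation:
    """Ray-trace a planar dot grid at several depths through the tank.

    The grid lies in the x-y plane of the lab frame and is replicated at
    ``plane_offsets`` along z (three target orientations are emulated by
    the three orthogonal cameras seeing the same volume of dots). Returns
    refracted (water) and unrefracted (air) pixel observations.
    """
    optics = optics or TankOptics()
    cams = cams or default_rig(optics)
    g = _grid_points(n_dots, pitch)
    xs, ys, zs = np.meshgrid(g, g, np.asarray(plane_offsets), indexing="ij")
    dots = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
    rng = np.random.default_rng(seed)
    pixels_air, pixels_water = [], []
    for cam in cams:
        air = project_linear(cam, dots)
        water = np.array([simulate_refraction(optics, cam, X) for X in dots])
        if noise_px > 0:
            air = air + rng.normal(0, noise_px, air.shape)
            water = water + rng.normal(0, noise_px, water.shape)
        pixels_air.append(air)
        pixels_water.append(water)
    return DotGridObservation(dots, pixels_air, pixels_water)
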