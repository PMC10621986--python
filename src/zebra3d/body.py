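"""The 22-parameter articulated larva model.

A larval pose is a chain of 9 rigid segments of equal length L/9 with two
bending degrees of freedom per joint, plus the head position and the three
Euler angles of the head. The pose vector follows the ordering
(x0, y0, z0, theta0, dtheta1..8, phi0, dphi1..8, gamma0); the length L is
a fixed parameter carried alongside.

Fish frame: X runs along the first backbone segment (head toward tail),
Y along the eye-to-eye axis and Z dorsal, so XY is the plane of the eyes
and lateral bending (dtheta) happens in XY while dorso-ventral bending
(dphi) tilts segments toward Z. Head orientation applies yaw, inclination
and roll in Z-Y-X order: R0 = Rz(theta0) @ Ry(-phi0) @ Rx(gamma0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FishPose",
    "FixedBodyParameters",
    "PoseCoordinates3D",
    "N_SEGMENTS",
    "N_BACKBONE",
    "head_rotation",
    "pose_to_coordinates",
    "coordinates_to_pose",
]

N_SEGMENTS = 9
N_BACKBONE = 10


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def head_rotation(theta0: float, phi0: float, gamma0: float) -> np.ndarray:
    """Rotation whose columns are the fish axes (X, Y, Z) in lab coordinates."""
    return _rot_z(theta0) @ _rot_y(-phi0) @ _rot_x(gamma0)


def euler_from_rotation(R: np.ndarray) -> tuple[float, float, float]:
    """Invert head_rotation: (theta0, phi0, gamma0) from a rotation matrix."""
    X = R[:, 0]
    theta0 = float(np.arctan2(X[1], X[0]))
    phi0 = float(np.arcsin(np.clip(X[2], -1.0, 1.0)))
    Rres = _rot_y(phi0) @ _rot_z(-theta0) @ R
    gamma0 = float(np.arctan2(Rres[2, 1], Rres[1, 1]))
    return theta0, phi0, gamma0


@dataclass
class FishPose:
    """One larva configuration: 22 adjustable parameters plus length L (mm)."""

    x0: float = 0.0
    y0: float = 0.0
    z0: float = 0.0
    theta0: float = 0.0
    phi0: float = 0.0
    gamma0: float = 0.0
    dtheta: np.ndarray = field(default_factory=lambda: np.zeros(8))
    dphi: np.ndarray = field(default_factory=lambda: np.zeros(8))
    length: float = 4.0

    def __post_init__(self) -> None:
        self.dtheta = np.asarray(self.dtheta, dtype=float)
        self.dphi = np.asarray(self.dphi, dtype=float)
        if self.dtheta.shape != (8,) or self.dphi.shape != (8,):
            raise ValueError("dtheta and dphi must each have 8 entries")
        if self.length <= 0:
            raise ValueError("length must be positive")
        # wrap yaw into (-pi, pi]
        self.theta0 = float(-((-self.theta0 + np.pi) % (2 * np.pi) - np.pi))
        if np.any(np.abs(self.dtheta) >= np.pi / 2) or np.any(np.abs(self.dphi) >= np.pi / 2):
            raise ValueError("per-joint bending angles must satisfy |angle| < pi/2")

    def to_vector(self) -> np.ndarray:
        """The 22-parameter vector (x0, y0, z0, theta0, dtheta1..8, phi0,
        dphi1..8, gamma0)."""
        return np.concatenate([
            [self.x0, self.y0, self.z0, self.theta0], self.dtheta,
            [self.phi0], self.dphi, [self.gamma0]])

    @classmethod
    def from_vector(cls, p: np.ndarray, length: float = 4.0) -> "FishPose":
        p = np.asarray(p, dtype=float)
        if p.shape != (22,):
            raise ValueError("pose vector must have exactly 22 entries")
        return cls(x0=p[0], y0=p[1], z0=p[2], theta0=p[3], dtheta=p[4:12],
                   phi0=p[12], dphi=p[13:21], gamma0=p[21], length=length)

    @property
    def head(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.z0])

    def with_(self, **kw) -> "FishPose":
        return replace(self, **kw)


@dataclass
class FixedBodyParameters:
    """Fixed (per-larva, not per-frame) body parameters.

    Organ dimensions are (length, width, height) in the fish frame, mm.
    Placements locate organ centers relative to the head point: a distance
    along the first scaffold segment and a perpendicular (dorsal) offset.
    These defaults are working values chosen to produce plausible larva
    images; on real data they would be estimated by template-based
    optimization, and everything downstream treats them as configuration.
    """

    brightness_eye: float = 255.0
    brightness_head: float = 180.0
    brightness_belly: float = 200.0
    eye_separation: float = 0.4
    dims_eye: tuple[float, float, float] = (0.25, 0.20, 0.20)
    dims_head: tuple[float, float, float] = (0.60, 0.40, 0.40)
    dims_belly: tuple[float, float, float] = (0.70, 0.40, 0.40)
    eye_along: float = 0.25
    eye_off: float = 0.05
    head_along: float = 0.35
    head_off: float = 0.0
    belly_along: float = 0.75
    belly_off: float = -0.05
    tail_width_scale: float = 1.0
    cov_scale: float = 16.0  # Sigma_k = diag(dims)^2 / cov_scale

    def __post_init__(self) -> None:
        vals = [self.brightness_eye, self.brightness_head, self.brightness_belly,
                self.eye_separation, *self.dims_eye, *self.dims_head,
                *self.dims_belly, self.tail_width_scale, self.cov_scale]
        if any(v <= 0 for v in vals):
            raise ValueError("brightness, dimensions and scales must be positive")

    def jittered(self, rng: np.random.Generator, frac: float = 0.05) -> "FixedBodyParameters":
        """Copy with every intrinsic parameter varied uniformly by +-frac."""
        def j(v):
            if isinstance(v, tuple):
                return tuple(x * rng.uniform(1 - frac, 1 + frac) for x in v)
            return v * rng.uniform(1 - frac, 1 + frac)
        kw = {}
        for name in ("brightness_eye", "brightness_head", "brightness_belly",
                     "eye_separation", "dims_eye", "dims_head", "dims_belly",
                     "eye_along", "head_along", "belly_along",
                     "tail_width_scale"):
            kw[name] = j(getattr(self, name))
        # perpendicular offsets may be ~0; jitter additively on a small scale
        for name in ("eye_off", "head_off", "belly_off"):
            kw[name] = getattr(self, name) + rng.uniform(-frac, frac) * 0.1
        return replace(self, **kw)


@dataclass
class PoseCoordinates3D:
    """12 lab-frame coordinates: 10 backbone points and 2 eye centroids (mm)."""

    backbone: np.ndarray  # (10, 3)
    eyes: np.ndarray      # (2, 3)

    def __post_init__(self) -> None:
        self.backbone = np.asarray(self.backbone, dtype=float)
        self.eyes = np.asarray(self.eyes, dtype=float)
        if self.backbone.shape != (N_BACKBONE, 3) or self.eyes.shape != (2, 3):
            raise ValueError("need 10 backbone points and 2 eye points")

    @property
    def points(self) -> np.ndarray:
        """(12, 3): backbone then eyes."""
        return np.vstack([self.backbone, self.eyes])


def _segment_directions_fish(dtheta: np.ndarray, dphi: np.ndarray) -> np.ndarray:
    """Unit directions of the 9 segments in the fish frame.

    Segment 1 runs along +X; each joint adds (dtheta_i, dphi_i) to the
    cumulative azimuth (in the eye plane) and elevation (dorsal)."""
    alpha = np.concatenate([[0.0], np.cumsum(dtheta)])
    beta = np.concatenate([[0.0], np.cumsum(dphi)])
    return np.column_stack([np.cos(beta) * np.cos(alpha),
                            np.cos(beta) * np.sin(alpha),
                            np.sin(beta)])


def pose_to_coordinates(pose: FishPose,
                        fixed: FixedBodyParameters | None = None) -> PoseCoordinates3D:
    """Forward kinematics: pose parameters -> 12 lab-frame coordinates."""
    fixed = fixed or FixedBodyParameters()
    R0 = head_rotation(pose.theta0, pose.phi0, pose.gamma0)
    dirs = _segment_directions_fish(pose.dtheta, pose.dphi)
    seg = pose.length / N_SEGMENTS
    backbone = np.empty((N_BACKBONE, 3))
    backbone[0] = pose.head
    backbone[1:] = pose.head + np.cumsum(seg * dirs @ R0.T, axis=0)
    half = fixed.eye_separation / 2.0
    eyes_fish = np.array([[fixed.eye_along, -half, fixed.eye_off],
                          [fixed.eye_along, half, fixed.eye_off]])
    eyes = pose.head + eyes_fish @ R0.T
    return PoseCoordinates3D(backbone, eyes)


def coordinates_to_pose(coords: PoseCoordinates3D,
                        length: float | None = None) -> FishPose:
    """Inverse kinematics: 12 coordinates -> pose parameters.

    Backbone points are assumed equidistant (resample along a spline
    first otherwise). The roll angle follows the never-belly-up
    convention: the eye labelling is chosen so the dorsal axis has a
    positive lab-z component (gamma0 in (-pi/2, pi/2]).
    """
    b = coords.backbone
    seg_vecs = np.diff(b, axis=0)
    seg_len = np.linalg.norm(seg_vecs, axis=1)
    if np.any(seg_len < 1e-9):
        raise ValueError("degenerate backbone: coincident consecutive points")
    L = float(length) if length is not None else float(seg_len.sum())
    X = seg_vecs[0] / seg_len[0]
    e = coords.eyes[1] - coords.eyes[0]
    if np.linalg.norm(e) < 1e-9:
        raise ValueError("degenerate eyes: coincident points")
    Y = e - (e @ X) * X
    ny = np.linalg.norm(Y)
    if ny < 1e-9:
        raise ValueError("eye axis parallel to the first segment")
    Y = Y / ny
    Z = np.cross(X, Y)
    if Z[2] < 0:  # never belly up: flip the eye labelling
        Y, Z = -Y, -Z
    R0 = np.column_stack([X, Y, Z])
    theta0 = float(np.arctan2(X[1], X[0]))
    phi0 = float(np.arcsin(np.clip(X[2], -1.0, 1.0)))
    Rres = _rot_y(phi0) @ _rot_z(-theta0) @ R0  # should equal Rx(gamma0)
    gamma0 = float(np.arctan2(Rres[2, 1], Rres[1, 1]))
    dirs_fish = (seg_vecs / seg_len[:, None]) @ R0
    alpha = np.unwrap(np.arctan2(dirs_fish[:, 1], dirs_fish[:, 0]))
    beta = np.arcsin(np.clip(dirs_fish[:, 2], -1.0, 1.0))
    return FishPose(x0=b[0, 0], y0=b[0, 1], z0=b[0, 2],
                    theta0=theta0, phi0=phi0, gamma0=gamma0,
                    dtheta=np.diff(alpha), dphi=np.diff(beta), length=L)
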