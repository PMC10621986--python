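"""Annotated synthetic training data.

Each training example is a rendered view triplet with the larva displaced
0-20 px from the crop center, the fixed body parameters jittered by +-5%,
and background Gaussian noise whose mean and variance are themselves
random per image (a hierarchical model mimicking recorded backgrounds:
bottom and side cameras have different noise statistics). Noise is added
on the unit intensity scale and the result rescaled to unsigned 8-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body import FishPose, FixedBodyParameters
from .ensemble import AngleKDE, PoseEnsemble
from .render import IMAGE_SIZE, render_views

__all__ = [
    "NoiseModel",
    "TrainingExample",
    "SwimBout",
    "generate_training_example",
    "generate_training_set",
    "generate_synthetic_bout",
]


@dataclass
class NoiseModel:
    """Hierarchical background-noise model on the unit intensity scale.

    Per image the background mean is m = X_mu * Y_mu with X_mu uniform on
    ``x_mu_range`` and Y_mu Gaussian; the background variance is uniform on
    ``var_range``. Bottom and side cameras carry separate statistics.
    """

    x_mu_range_bottom: tuple[float, float] = (0.0, 1.0 / 255.0)
    y_mu_bottom: tuple[float, float] = (50.0, 10.0)
    var_range_bottom: tuple[float, float] = (20.0 / 255.0**2, 70.0 / 255.0**2)
    x_mu_range_side: tuple[float, float] = (0.0, 1.0 / 255.0)
    y_mu_side: tuple[float, float] = (20.0, 10.0)
    var_range_side: tuple[float, float] = (10.0 / 255.0**2, 60.0 / 255.0**2)
    bottom_cameras: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        for rng_ in (self.x_mu_range_bottom, self.var_range_bottom,
                     self.x_mu_range_side, self.var_range_side):
            if rng_[0] < 0 or rng_[1] < rng_[0]:
                raise ValueError("noise ranges must be non-negative and ordered")

    def sample_mean(self, camera: int, rng: np.random.Generator) -> float:
        """Draw the background mean m for one image."""
        if camera in self.bottom_cameras:
            x = rng.uniform(*self.x_mu_range_bottom)
            y = rng.normal(*self.y_mu_bottom)
        else:
            x = rng.uniform(*self.x_mu_range_side)
            y = rng.normal(*self.y_mu_side)
        return float(x * y)

    def sample_variance(self, camera: int, rng: np.random.Generator) -> float:
        rngs = (self.var_range_bottom if camera in self.bottom_cameras
                else self.var_range_side)
        return float(rng.uniform(*rngs))

    def apply(self, image_unit: np.ndarray, camera: int,
              rng: np.random.Generator) -> np.ndarray:
        """Overlay Gaussian background noise on a unit-scale image.

        Background pixels take values drawn from N(m, s); larva pixels
        keep their rendered brightness (max-combine, so soft larva edges
        emerge smoothly from the noise floor).
        """
        m = self.sample_mean(camera, rng)
        var = self.sample_variance(camera, rng)
        field = rng.normal(m, np.sqrt(var), image_unit.shape)
        return np.maximum(image_unit, np.clip(field, 0.0, None))


@dataclass
class TrainingExample:
    """View triplet plus per-view 2-D annotations of the 12 keypoints."""

    images: np.ndarray            # (3, 141, 141) uint8
    keypoints: np.ndarray         # (3, 12, 2) px, crop coordinates
    pose: FishPose | None = None
    crop_origins: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.keypoints.shape[-2:] != (12, 2):
            raise ValueError("need 12 keypoints per view")
        if (self.keypoints.min() < 0
                or self.keypoints.max() > IMAGE_SIZE):
            raise ValueError("keypoints outside the image frame")


def generate_training_example(
    pose: FishPose,
    proj,
    fixed: FixedBodyParameters | None = None,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    max_displacement_px: float = 20.0,
    jitter_fixed: float = 0.05,
    mode: str = "accurate",
    table=None,
    voxel_pitch: float = 0.03,
    max_tries: int = 10,
) -> TrainingExample:
    """Render one annotated, noisy training triplet.

    Displacements are uniform on [0, max_displacement_px] per axis with
    random sign, applied identically to image and annotation; a
    displacement that pushes keypoints out of frame is redrawn up to
    ``max_tries`` times. Pass ``noise=None`` plus ``max_displacement_px=0``
    and ``jitter_fixed=0`` for the identity configuration (images equal the
    plain render).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fixed = fixed or FixedBodyParameters()
    if jitter_fixed > 0:
        fixed = fixed.jittered(rng, jitter_fixed)
    from .render import OrthographicProjection
    proj = proj if proj is not None else OrthographicProjection()

    # base crop centers (centered larva), then displace
    base_trip, _ = render_views(pose, fixed, proj, mode=mode, table=table,
                                voxel_pitch=voxel_pitch, return_keypoints=True)
    centers = base_trip.crop_origins + (IMAGE_SIZE - 1) // 2
    for attempt in range(max_tries):
        disp = (rng.uniform(0.0, max_displacement_px, size=(proj.n_cameras, 2))
                * rng.choice([-1.0, 1.0], size=(proj.n_cameras, 2)))
        disp = np.round(disp)
        trip, kp = render_views(pose, fixed, proj, mode=mode, table=table,
                                voxel_pitch=voxel_pitch,
                                crop_centers=centers + disp,
                                return_keypoints=True)
        if kp.min() >= 0 and kp.max() <= IMAGE_SIZE:
            break
    else:
        raise ValueError("could not place displaced larva inside the frame")
    images = trip.images.astype(float) / 255.0
    if noise is not None:
        images = np.stack([noise.apply(images[c], c, rng)
                           for c in range(len(images))])
    # rescale to 8-bit
    peak = images.reshape(len(images), -1).max(axis=1)
    peak[peak <= 0] = 1.0
    out = np.round(images / peak[:, None, None] * 255.0).astype(np.uint8)
    return TrainingExample(out, kp, pose, trip.crop_origins)


def generate_training_set(
    poses: PoseEnsemble | list[FishPose],
    proj,
    n: int | None = None,
    fixed: FixedBodyParameters | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    **kwargs,
) -> list[TrainingExample]:
    """Convenience batch wrapper around generate_training_example."""
    pose_list = poses.poses if isinstance(poses, PoseEnsemble) else list(poses)
    if n is not None:
        pose_list = pose_list[:n]
    rng = np.random.default_rng(seed)
    noise = noise if noise is not None else NoiseModel()
    return [generate_training_example(p, proj, fixed, noise, rng, **kwargs)
            for p in pose_list]


@dataclass
class SwimBout:
    """Time series of poses (one swim bout) with optional per-frame scores."""

    times: np.ndarray
    poses: list[FishPose]
    scores: np.ndarray | None = None
    context: str = "synthetic"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.poses):
            raise ValueError("times and poses must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def generate_synthetic_bout(
    kde: AngleKDE,
    n_frames: int,
    smoothness: float = 5.0,
    seed: int = 0,
    fps: float = 500.0,
    max_speed: float = 100.0,  # mm/s
    start: np.ndarray | None = None,
) -> SwimBout:
    """Temporally correlated synthetic bout.

    Angle trajectories are Gaussian-smoothed (sigma = ``smoothness``
    frames) sequences of KDE samples; the centroid follows a smoothed
    random walk with per-frame displacement capped at max_speed / fps.
    As smoothness grows the bout tends to a constant pose.
    """
    from scipy.ndimage import gaussian_filter1d

    if n_frames < 2:
        raise ValueError("a bout needs at least 2 frames")
    rng = np.random.default_rng(seed)
    angles, lengths = kde.sample(n_frames, rng)

    def smooth(x):
        # in the infinite-smoothness limit the filter is the series mean
        if smoothness >= 10 * n_frames:
            return np.broadcast_to(x.mean(axis=0), x.shape).copy()
        return gaussian_filter1d(x, sigma=smoothness, axis=0, mode="nearest")

    angles = smooth(angles)
    theta0 = smooth(rng.normal(0, 0.4, n_frames)) + rng.uniform(-np.pi, np.pi)
    start = np.zeros(3) if start is None else np.asarray(start, dtype=float)
    steps = smooth(rng.normal(0, 1.0, (n_frames - 1, 3)))
    max_step = max_speed / fps
    norms = np.linalg.norm(steps, axis=1, keepdims=True)
    steps = np.where(norms > max_step, steps / norms * max_step, steps)
    path = np.vstack([start, start + np.cumsum(steps, axis=0)])
    length = float(lengths[0])
    poses = []
    for i in range(n_frames):
        a = angles[i]
        poses.append(FishPose(
            x0=path[i, 0], y0=path[i, 1], z0=path[i, 2], theta0=float(theta0[i]),
            dtheta=np.clip(a[0:8], -1.5, 1.5), dphi=np.clip(a[8:16], -1.5, 1.5),
            phi0=float(a[16]), gamma0=float(a[17]), length=length))
    times = np.arange(n_frames) / fps
    return SwimBout(times, poses)
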