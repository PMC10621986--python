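"""Pose ensembles and kernel-density resampling.

Raw pose collections from swim recordings are dominated by nearly straight
larvae. To build a balanced training distribution, poses are resampled
with probability inversely proportional to a kernel density estimate in
the 2-D space of mean absolute lateral and dorsal curvature, and an
18-dimensional Gaussian KDE over (dtheta1..8, dphi1..8, phi0, gamma0) is
then used as a generative prior for new poses: positions are drawn
uniformly in the imaging volume and theta0 uniformly in (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KernelDensity

from .body import FishPose

__all__ = [
    "PoseEnsemble",
    "CurvatureSummary",
    "AngleKDE",
    "curvature_summary",
    "select_bandwidth",
    "resample_uniform",
    "fit_angle_kde",
    "sample_pose_ensemble",
    "prior_pose_ensemble",
    "DEFAULT_IMAGING_VOLUME",
]

# central cubic imaging region of the tank (mm, half-sides); the spot all
# three camera fields of view overlap
DEFAULT_IMAGING_VOLUME = np.array([[-15.0, -15.0, -15.0], [15.0, 15.0, 15.0]])


@dataclass
class PoseEnsemble:
    poses: list[FishPose]
    scores: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.poses)

    def angle_matrix(self) -> np.ndarray:
        """(N, 18) matrix of (dtheta1..8, dphi1..8, phi0, gamma0)."""
        return np.array([np.concatenate([p.dtheta, p.dphi, [p.phi0, p.gamma0]])
                         for p in self.poses])

    def curvature_matrix(self) -> np.ndarray:
        """(N, 2) matrix of (mean |dtheta|, mean |dphi|)."""
        return np.array([[np.mean(np.abs(p.dtheta)), np.mean(np.abs(p.dphi))]
                         for p in self.poses])


@dataclass
class CurvatureSummary:
    mean_abs_dtheta: float
    mean_abs_dphi: float

    def __post_init__(self) -> None:
        if self.mean_abs_dtheta < 0 or self.mean_abs_dphi < 0:
            raise ValueError("curvature summaries are non-negative")


def curvature_summary(pose: FishPose) -> CurvatureSummary:
    """Mean absolute lateral and dorsal bending over the 8 joints."""
    return CurvatureSummary(float(np.mean(np.abs(pose.dtheta))),
                            float(np.mean(np.abs(pose.dphi))))


def select_bandwidth(
    samples: np.ndarray,
    candidates: np.ndarray | None = None,
    folds: int = 20,
    seed: int = 0,
) -> float:
    """Cross-validated Gaussian-KDE bandwidth.

    Scans 50 bandwidths uniformly spaced in [0.01, 0.1] rad by default,
    splitting the samples 1:9 (20-fold cross-validation) and selecting the
    candidate that maximizes the mean held-out log-likelihood.
    """
    from sklearn.model_selection import KFold

    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < folds:
        raise ValueError("need at least `folds` samples")
    if candidates is None:
        candidates = np.linspace(0.01, 0.1, 50)
    if np.allclose(samples, samples[0]):
        import warnings
        warnings.warn("degenerate (all-identical) samples; returning the "
                      "smallest candidate bandwidth")
        return float(np.min(candidates))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(candidates))
    splits = list(kf.split(samples))
    for i, bw in enumerate(candidates):
        ll = []
        for train, test in splits:
            kde = KernelDensity(bandwidth=bw).fit(samples[train])
            ll.append(kde.score(samples[test]) / len(test))
        scores[i] = np.mean(ll)
    return float(candidates[int(np.argmax(scores))])


def resample_uniform(
    ensemble: PoseEnsemble,
    n: int = 2500,
    bandwidth: float | None = None,
    seed: int = 0,
    clip_quantile: float = 0.001,
    replace: bool = False,
) -> PoseEnsemble:
    """Resample poses uniformly over curvature space.

    Each pose is selected with probability inversely proportional to the
    KDE density of (mean |dtheta|, mean |dphi|); densities are floored at
    the ``clip_quantile`` quantile before inversion to avoid underflow
    blow-ups.
    """
    rng = np.random.default_rng(seed)
    curv = ensemble.curvature_matrix()
    if bandwidth is None:
        bandwidth = select_bandwidth(curv, seed=seed)
    kde = KernelDensity(bandwidth=bandwidth).fit(curv)
    dens = np.exp(kde.score_samples(curv))
    floor = np.quantile(dens, clip_quantile)
    w = 1.0 / np.maximum(dens, max(floor, 1e-300))
    w /= w.sum()
    if n > len(ensemble) and not replace:
        import warnings
        warnings.warn("requested more poses than available; sampling with "
                      "replacement")
        replace = True
    idx = rng.choice(len(ensemble), size=n, replace=replace, p=w)
    scores = ensemble.scores[idx] if ensemble.scores is not None else None
    return PoseEnsemble([ensemble.poses[i] for i in idx], scores)


@dataclass
class AngleKDE:
    """Gaussian KDE over the 18 angle dimensions (shared scalar bandwidth)."""

    samples: np.ndarray
    bandwidth: float
    lengths: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 18:
            raise ValueError("angle KDE lives in exactly 18 dimensions")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.lengths is None:
            self.lengths = np.full(len(self.samples), 4.0)

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw n angle vectors (data point + Gaussian jitter) and the
        lengths of the source poses."""
        idx = rng.integers(0, len(self.samples), size=n)
        jitter = rng.normal(0.0, self.bandwidth, size=(n, 18))
        return self.samples[idx] + jitter, self.lengths[idx]


def fit_angle_kde(ensemble: PoseEnsemble, bandwidth: float | None = None,
                  seed: int = 0) -> AngleKDE:
    """Fit the 18-D angle KDE to an ensemble (bandwidth cross-validated
    when not given)."""
    X = ensemble.angle_matrix()
    if bandwidth is None:
        bandwidth = select_bandwidth(X, seed=seed)
    lengths = np.array([p.length for p in ensemble.poses])
    return AngleKDE(X, bandwidth, lengths)


def sample_pose_ensemble(
    kde: AngleKDE,
    n: int,
    volume: np.ndarray | None = None,
    seed: int = 0,
    max_joint_angle: float = np.pi / 2 - 1e-6,
) -> PoseEnsemble:
    """Generate n model poses from the angle KDE.

    The angle block comes from the KDE; (x0, y0, z0) are uniform in the
    imaging ``volume`` ((2, 3) [lo; hi], mm) and theta0 uniform in
    (-pi, pi]. Joint angles are clipped to the model's validity range.
    """
    rng = np.random.default_rng(seed)
    volume = DEFAULT_IMAGING_VOLUME if volume is None else np.asarray(volume)
    angles, lengths = kde.sample(n, rng)
    pos = rng.uniform(volume[0], volume[1], size=(n, 3))
    theta0 = -rng.uniform(-np.pi, np.pi, size=n)  # uniform on (-pi, pi]
    poses = []
    for i in range(n):
        a = angles[i]
        poses.append(FishPose(
            x0=pos[i, 0], y0=pos[i, 1], z0=pos[i, 2], theta0=theta0[i],
            dtheta=np.clip(a[0:8], -max_joint_angle, max_joint_angle),
            dphi=np.clip(a[8:16], -max_joint_angle, max_joint_angle),
            phi0=a[16], gamma0=a[17], length=float(lengths[i])))
    return PoseEnsemble(poses)


def prior_pose_ensemble(n: int, seed: int = 0,
                        lateral_scale: float = 0.18,
                        dorsal_scale: float = 0.035,
                        phi0_scale: float = 0.25,
                        gamma0_scale: float = 0.12,
                        length_range: tuple[float, float] = (3.5, 4.2)) -> PoseEnsemble:
    """Synthetic stand-in for a template-fit pose ensemble.

    Emulates the qualitative structure of real swim-bout poses: mostly
    straight backbones with occasional strong C-bends, smooth bending along
    the body (low-pass filtered joint noise), small dorso-ventral bending,
    and modest inclination/roll. Used to bootstrap the KDE pipeline when no
    recordings are available.
    """
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    poses = []
    for _ in range(n):
        # heavy-tailed bend amplitude: many straight poses, some C-bends
        amp = lateral_scale * rng.exponential()
        base = gaussian_filter1d(rng.normal(0, 1, 8), sigma=1.2, mode="nearest")
        dtheta = np.clip(amp * base + rng.normal(0, 0.01, 8), -1.2, 1.2)
        dphi = np.clip(dorsal_scale * rng.exponential()
                       * gaussian_filter1d(rng.normal(0, 1, 8), 1.2, mode="nearest"),
                       -0.3, 0.3)
        poses.append(FishPose(
            x0=rng.uniform(-10, 10), y0=rng.uniform(-10, 10), z0=rng.uniform(-10, 10),
            theta0=rng.uniform(-np.pi, np.pi),
            phi0=phi0_scale * rng.normal(), gamma0=gamma0_scale * rng.normal(),
            dtheta=dtheta, dphi=dphi,
            length=rng.uniform(*length_range)))
    return PoseEnsemble(poses)
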