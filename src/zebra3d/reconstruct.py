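"""3-D pose reconstruction from per-view keypoints, and prediction scoring.

Backbone keypoints are triangulated independently by nonlinear least
squares against the empirical projection; the eye labels, ambiguous
because the training loss is symmetric in the two eyes, are resolved by
enumerating all 8 per-view assignments and keeping the one with the least
total triangulation residual. The roll angle follows the never-belly-up
convention. Predictions are scored per frame as the minimum over views of
the Pearson correlation between the input image and a re-render of the
predicted pose, computed over the rendered image's non-zero mask.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .body import (FishPose, FixedBodyParameters, PoseCoordinates3D,
                   coordinates_to_pose)
from .camera import triangulate_point
from .render import render_views
from .synthesis import SwimBout

__all__ = [
    "PredictedPose",
    "triangulate_backbone",
    "resolve_eyes",
    "assign_roll",
    "resample_spline",
    "reconstruct_pose",
    "prediction_score",
    "filter_bouts",
]


@dataclass
class PredictedPose:
    coords: PoseCoordinates3D
    residuals_px: np.ndarray        # per backbone point RMS reprojection
    eye_residual_px: float
    eye_assignment: tuple
    score: float | None = None      # min-over-views masked Pearson r
    flags: list[str] | None = None


def triangulate_backbone(
    keypoints: np.ndarray,
    proj,
    residual_flag_px: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Triangulate the 10 backbone points independently.

    ``keypoints`` is (n_views, >=10, 2) in sensor pixels. Returns the
    (10, 3) lab points, per-point RMS residuals (px) and the indices of
    points whose residual exceeds the flag threshold.
    """
    keypoints = np.asarray(keypoints, dtype=float)
    pts = np.zeros((10, 3))
    res = np.zeros(10)
    flagged = []
    for k in range(10):
        pix = [keypoints[c, k] for c in range(keypoints.shape[0])]
        pts[k], res[k], ok = triangulate_point(proj, pix)
        if res[k] > residual_flag_px or not ok:
            flagged.append(k)
    return pts, res, flagged


def eye_assignments(n_views: int = 3) -> list[tuple]:
    """The per-view eye index assignments enumerated during eye
    disambiguation (2^n_views combinations; 8 for three cameras)."""
    return list(itertools.product((0, 1), repeat=n_views))


def resolve_eyes(
    eye_keypoints: np.ndarray,
    proj,
    tie_tol: float = 1e-9,
) -> tuple[np.ndarray, tuple, float, list[str]]:
    """Triangulate the two eyes, resolving per-view label ambiguity.

    ``eye_keypoints`` is (n_views, 2, 2). All 2^n_views per-view index
    assignments are enumerated; eye 1 is triangulated from the selected
    keypoint per view and eye 2 from the complementary one, and the
    assignment with the smallest total residual wins (ties break to the
    lexicographically smallest assignment and are flagged).
    """
    eye_keypoints = np.asarray(eye_keypoints, dtype=float)
    n_views = eye_keypoints.shape[0]
    best = None
    results = []
    for assign in eye_assignments(n_views):
        pix1 = [eye_keypoints[c, assign[c]] for c in range(n_views)]
        pix2 = [eye_keypoints[c, 1 - assign[c]] for c in range(n_views)]
        e1, r1, _ = triangulate_point(proj, pix1)
        e2, r2, _ = triangulate_point(proj, pix2)
        results.append((r1 + r2, assign, np.vstack([e1, e2])))
    results.sort(key=lambda t: (t[0], t[1]))
    best = results[0]
    flags = []
    if len(results) > 1 and results[1][0] - best[0] < tie_tol:
        flags.append("eye-assignment-tie")
    return best[2], best[1], float(best[0]), flags


def assign_roll(eyes: np.ndarray, backbone: np.ndarray) -> float:
    """Roll angle gamma0 from the 3-D eye axis, assuming never belly-up.

    The eye axis is projected perpendicular to the heading (first
    backbone segment); the eye labelling giving a dorsal-up fish fixes the
    sign, so gamma0 lies in (-pi/2, pi/2].
    """
    eyes = np.asarray(eyes, dtype=float)
    if np.linalg.norm(eyes[1] - eyes[0]) < 1e-9:
        raise ValueError("coincident eyes")
    X = backbone[1] - backbone[0]
    X = X / np.linalg.norm(X)
    e = eyes[1] - eyes[0]
    Y = e - (e @ X) * X
    if np.linalg.norm(Y) < 1e-9:
        raise ValueError("eye axis parallel to the heading")
    coords = PoseCoordinates3D(np.asarray(backbone, float), eyes)
    return coordinates_to_pose(coords).gamma0


def resample_spline(backbone: np.ndarray, n_dense: int = 100001,
                    spacing: str = "arc") -> np.ndarray:
    """Resample 10 backbone points to equal spacing along a cubic spline.

    ``spacing='arc'`` distributes the points at equal arc length (the
    conventional midline parameterization); ``spacing='chord'`` makes the
    straight-line distances between consecutive output points equal,
    which matches the rigid-segment body model exactly and is what the
    pose reconstruction uses. Endpoints are preserved.
    """
    from scipy.interpolate import CubicSpline

    backbone = np.asarray(backbone, dtype=float)
    d = np.linalg.norm(np.diff(backbone, axis=0), axis=1)
    if np.any(d < 1e-12):
        raise ValueError("degenerate backbone: coincident points")
    t = np.concatenate([[0.0], np.cumsum(d)])  # chord-length parameter
    cs = CubicSpline(t, backbone, axis=0)
    tt = np.linspace(0.0, t[-1], n_dense)
    dense = cs(tt)
    if spacing == "arc":
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, arc[-1], 10)
        t_eq = np.interp(targets, arc, tt)
        out = cs(t_eq)
    elif spacing == "chord":
        out = _equal_chord_walk(cs, dense, tt)
    else:
        raise ValueError("spacing must be 'arc' or 'chord'")
    out[0], out[-1] = backbone[0], backbone[-1]
    return out


def _chord_walk(dense: np.ndarray, tt: np.ndarray, c: float) -> np.ndarray:
    """Parameters of 9 successive chords of length c along the dense curve
    (the last entry is tt[-1] + overshoot distance when c is too long)."""
    params = [tt[0]]
    j = 0
    window = max(len(dense) // 4, 64)  # a chord spans ~1/9 of the curve
    point = dense[0]
    for _ in range(9):
        dist = np.linalg.norm(dense[j:j + window] - point, axis=1)
        if dist[-1] < c and j + window < len(dense):
            dist = np.linalg.norm(dense[j:] - point, axis=1)
        hit = np.argmax(dist >= c)
        if dist[hit] < c:  # never reached: chord too long
            params.append(tt[-1] + (c - dist[-1]))
            return np.array(params)
        lo = j + hit - 1
        # linear refinement between dense samples
        f = (c - dist[hit - 1]) / max(dist[hit] - dist[hit - 1], 1e-15)
        tpar = tt[lo] + f * (tt[lo + 1] - tt[lo])
        params.append(tpar)
        j = j + hit
        point = dense[lo] + f * (dense[lo + 1] - dense[lo])
    return np.array(params)


def _equal_chord_walk(cs, dense: np.ndarray, tt: np.ndarray) -> np.ndarray:
    """10 points on the spline with equal consecutive chord lengths,
    ending exactly at the curve's endpoint (bisection on the chord)."""
    total_chord = np.linalg.norm(dense[-1] - dense[0])
    lo, hi = total_chord / 9.0 * 0.98, tt[-1] / 9.0 * 1.02
    for _ in range(45):
        c = 0.5 * (lo + hi)
        params = _chord_walk(dense, tt, c)
        if params[-1] > tt[-1]:
            hi = c
        else:
            lo = c
    c = 0.5 * (lo + hi)
    params = np.clip(_chord_walk(dense, tt, c), tt[0], tt[-1])
    return cs(params)


def reconstruct_pose(
    keypoints: np.ndarray,
    proj,
    length: float | None = None,
) -> tuple[FishPose, PredictedPose]:
    """Full keypoints -> pose pipeline: triangulate, resolve eyes, spline-
    resample, convert to the 22-parameter form (roll via never-belly-up)."""
    backbone, res, flagged = triangulate_backbone(keypoints, proj)
    eyes, assign, eres, flags = resolve_eyes(keypoints[:, 10:12], proj)
    # chord spacing matches the rigid-segment model, so the angle
    # conversion that follows is exact for noise-free inputs
    backbone_eq = resample_spline(backbone, spacing="chord", n_dense=15001)
    coords = PoseCoordinates3D(backbone_eq, eyes)
    pose = coordinates_to_pose(coords, length=length)
    pred = PredictedPose(coords, res, eres, assign,
                         flags=flags + [f"point-{k}" for k in flagged])
    return pose, pred


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def masked_pearson(image: np.ndarray, rendered: np.ndarray,
                   mask: np.ndarray) -> float:
    """Pearson correlation over the masked pixels; NaN for degenerate
    masks (empty, or constant intensity within the mask)."""
    a = np.asarray(image, dtype=float)[mask]
    b = np.asarray(rendered, dtype=float)[mask]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    if np.array_equal(a, b):
        return 1.0  # identical images correlate exactly
    return float(np.corrcoef(a, b)[0, 1])


def prediction_score(
    images: np.ndarray,
    pose: FishPose,
    proj,
    fixed: FixedBodyParameters | None = None,
    crop_origins: np.ndarray | None = None,
    voxel_pitch: float = 0.03,
) -> tuple[float, np.ndarray]:
    """Frame score: minimum over views of the masked Pearson correlation.

    The model triplet is re-rendered from ``pose``; per view the mask is
    the rendered image's non-zero support (the rendered background is
    exactly zero). Undefined per-view scores (empty mask) propagate as
    NaN and are excluded from the minimum with a warning.
    """
    images = np.asarray(images)
    fixed = fixed or FixedBodyParameters()
    centers = None
    if crop_origins is not None:
        from .render import IMAGE_SIZE
        centers = np.asarray(crop_origins) + (IMAGE_SIZE - 1) // 2
    trip = render_views(pose, fixed, proj, mode="accurate",
                        voxel_pitch=voxel_pitch, crop_centers=centers)
    scores = np.array([masked_pearson(images[c], trip.images[c],
                                      trip.images[c] > 0)
                       for c in range(len(images))])
    valid = ~np.isnan(scores)
    if not valid.any():
        import warnings
        warnings.warn("no view produced a usable mask; score undefined")
        return float("nan"), scores
    if not valid.all():
        import warnings
        warnings.warn("some views had empty/degenerate masks; excluded "
                      "from the frame minimum")
    return float(np.min(scores[valid])), scores


def filter_bouts(bouts: list[SwimBout] | list[np.ndarray],
                 threshold: float = 0.85) -> tuple[list, list]:
    """Split bouts into (accepted, rejected): a bout is accepted iff every
    frame's prediction score is at least ``threshold``."""
    accepted, rejected = [], []
    for bout in bouts:
        scores = np.asarray(bout.scores if isinstance(bout, SwimBout) else bout,
                            dtype=float)
        ok = np.nanmin(scores) >= threshold if len(scores) else False
        (accepted if ok else rejected).append(bout)
    return accepted, rejected
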