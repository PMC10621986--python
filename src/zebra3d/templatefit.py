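"""Template-based pose estimation.

Frames are background-subtracted (per-pixel 90th-percentile background),
Gaussian-filtered, thresholded (scaled Otsu) and cropped; the pose is then
found by minimizing the summed squared difference between rendered model
views and the preprocessed crops, first with a coarse derivative-free
pattern search using the sprite renderer, then with a fine three-phase
(anterior, posterior, joint) search using the accurate voxel renderer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .body import FishPose, FixedBodyParameters
from .camera import triangulate_point
from .render import (IMAGE_SIZE, LookupTableP, render_component_images,
                     render_views)

__all__ = [
    "PreprocessedFrame",
    "FitResult",
    "compute_background",
    "preprocess_frame",
    "track_larva",
    "estimate_length",
    "cost_function",
    "pattern_search",
    "coarse_optimize",
    "fine_optimize",
]


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def compute_background(frames: np.ndarray, percentile: float = 90.0) -> np.ndarray:
    """Per-pixel percentile background over a video (linear-interpolation
    percentile definition, numpy's default)."""
    frames = np.asarray(frames)
    if len(frames) < 10:
        raise ValueError("need at least 10 frames for a stable background")
    return np.percentile(frames, percentile, axis=0)


@dataclass
class PreprocessedFrame:
    """One background-subtracted, cropped larva detection in one camera."""

    image: np.ndarray          # (<=141, <=141) uint8 crop, padded
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    mask: np.ndarray           # binary mask within the crop
    centroid: np.ndarray       # (x, y) px in full-frame coordinates
    crop_origin: np.ndarray    # (x, y) of the crop's (0, 0) pixel


def _pad_with_border_noise(crop: np.ndarray, mask: np.ndarray, size: int,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center ``crop`` on a size x size canvas, filling the padding with
    samples drawn from the crop's 5-px border (values above mean + 3 sd of
    the border are excluded, so stray bright objects are not replicated)."""
    h, w = crop.shape
    border = np.concatenate([crop[:5].ravel(), crop[-5:].ravel(),
                             crop[:, :5].ravel(), crop[:, -5:].ravel()])
    mu, sd = border.mean(), border.std()
    pool = border[border <= mu + 3 * sd]
    if len(pool) == 0:
        pool = border
    canvas = rng.choice(pool, size=(size, size)).astype(crop.dtype)
    mask_canvas = np.zeros((size, size), dtype=bool)
    y0 = (size - h) // 2
    x0 = (size - w) // 2
    canvas[y0:y0 + h, x0:x0 + w] = crop
    mask_canvas[y0:y0 + h, x0:x0 + w] = mask
    return canvas, mask_canvas, np.array([x0, y0])


def preprocess_frame(
    frame: np.ndarray,
    background: np.ndarray,
    otsu_scale: float = 0.8,
    threshold: float | None = None,
    sigma: float = 1.0,
    min_area: int = 15,
    max_detections: int = 4,
    crop_size: int = IMAGE_SIZE,
    seed: int = 0,
) -> list[PreprocessedFrame]:
    """Background-subtract, filter, segment and crop larva detections.

    The binary threshold is Otsu's value scaled by ``otsu_scale`` unless a
    fixed ``threshold`` is given (both modes exist because a heuristic
    fixed threshold is sometimes preferable on low-contrast videos).
    Detections are returned largest-first; an empty list means no
    component exceeded ``min_area``.
    """
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    sub = np.clip(background.astype(float) - frame.astype(float), 0, 255)
    # 5x5 window at sigma 1
    smooth = ndimage.gaussian_filter(sub, sigma=sigma, radius=2)
    if threshold is None:
        if np.allclose(smooth, smooth.flat[0]):
            return []
        threshold = otsu_scale * filters.threshold_otsu(smooth)
    binary = smooth > threshold
    labels = measure.label(binary)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    props.sort(key=lambda p: p.area, reverse=True)
    rng = np.random.default_rng(seed)
    out = []
    for p in props[:max_detections]:
        r0, c0, r1, c1 = p.bbox
        crop = np.round(smooth[r0:r1, c0:c1]).astype(np.uint8)
        mask = labels[r0:r1, c0:c1] == p.label
        if crop.shape[0] > crop_size or crop.shape[1] > crop_size:
            crop = crop[:crop_size, :crop_size]
            mask = mask[:crop_size, :crop_size]
        canvas, mask_c, pad_off = _pad_with_border_noise(crop, mask, crop_size, rng)
        cy, cx = p.centroid
        out.append(PreprocessedFrame(
            image=canvas, bbox=p.bbox, mask=mask_c,
            centroid=np.array([cx, cy]),
            crop_origin=np.array([c0, r0]) - pad_off))
    return out


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------

def track_larva(
    frame_centroids: list[list[list[np.ndarray]]],
    proj,
    max_residual_px: float = 3.0,
    max_jump_mm: float = 5.0,
    max_gap: int = 5,
) -> list[dict]:
    """Track one larva across frames by 3-D nearest-neighbor association.

    ``frame_centroids[t][cam]`` lists candidate centroid pixels. Each
    frame's candidate triples are triangulated; the triple whose 3-D
    position is nearest the previous frame's position continues the track.
    Returns one record per frame with keys (indices, position, status).
    """
    import itertools

    track: list[dict] = []
    prev_pos = None
    gap = 0
    for t, cams in enumerate(frame_centroids):
        candidates = []
        if all(len(c) > 0 for c in cams):
            for combo in itertools.product(*[range(len(c)) for c in cams]):
                pix = [np.asarray(cams[c][i], float) for c, i in enumerate(combo)]
                X, rms, ok = triangulate_point(proj, pix)
                if ok and rms < max_residual_px:
                    candidates.append((combo, X))
        chosen = None
        if candidates:
            if prev_pos is None:
                chosen = min(candidates, key=lambda c: np.linalg.norm(c[1]))
            else:
                chosen = min(candidates,
                             key=lambda c: np.linalg.norm(c[1] - prev_pos))
                if np.linalg.norm(chosen[1] - prev_pos) > max_jump_mm:
                    chosen = None
        if chosen is None:
            gap += 1
            status = "lost" if gap > max_gap else "gap"
            track.append({"indices": None, "position": None, "status": status})
            if status == "lost":
                track.extend({"indices": None, "position": None,
                              "status": "terminated"}
                             for _ in range(t + 1, len(frame_centroids)))
                break
        else:
            gap = 0
            prev_pos = chosen[1]
            track.append({"indices": chosen[0], "position": chosen[1],
                          "status": "ok"})
    return track


# --------------------------------------------------------------------------
# cost and optimization
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    pose: FishPose
    cost: float
    per_view_cost: np.ndarray
    round: str  # {"coarse", "fine"}
    iterations: int
    n_evals: int = 0
    flag: str = ""


def _render_for_cost(pose, fixed, proj, crop_origins, mode, table, voxel_pitch,
                     component="both", static=None):
    imgs = render_component_images(pose, fixed, proj, crop_origins, mode=mode,
                                   table=table, voxel_pitch=voxel_pitch,
                                   component=component)
    if static is not None:
        imgs = np.maximum(imgs, static)
    peak = imgs.reshape(len(imgs), -1).max(axis=1)
    peak[peak <= 0] = 1.0
    # quantize like the 8-bit view contract so a re-render of the same
    # pose compares bit-identically
    return np.round(imgs / peak[:, None, None] * 255.0)


def cost_function(
    pose: FishPose,
    images: np.ndarray,
    proj,
    crop_origins: np.ndarray,
    fixed: FixedBodyParameters | None = None,
    mode: str = "accurate",
    table: LookupTableP | None = None,
    voxel_pitch: float = 0.03,
    component: str = "both",
    static: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Sum over views of squared pixel differences between the rendered
    model and the preprocessed crops. Returns (total, per-view)."""
    fixed = fixed or FixedBodyParameters()
    images = np.asarray(images, dtype=float)
    rendered = _render_for_cost(pose, fixed, proj, crop_origins, mode, table,
                                voxel_pitch, component, static)
    if rendered.shape != images.shape:
        raise ValueError("rendered/preprocessed shape mismatch")
    per_view = np.sum((rendered - images) ** 2, axis=(1, 2))
    return float(per_view.sum()), per_view


_ANGLE_IDX = np.r_[4:12, 13:21]  # dtheta, dphi positions in the 22-vector


def _clip_pose_vector(p: np.ndarray) -> np.ndarray:
    q = p.copy()
    lim = np.pi / 2 - 1e-6
    q[_ANGLE_IDX] = np.clip(q[_ANGLE_IDX], -lim, lim)
    q[12] = np.clip(q[12], -np.pi / 2 + 1e-6, np.pi / 2 - 1e-6)
    # never-belly-up: the body is nearly symmetric under a 180-degree
    # roll, so the upside-down cost basin is spurious; keep it out of the
    # search space, matching the reconstruction-side roll convention
    q[21] = np.clip(q[21], -1.9, 1.9)
    return q


def pattern_search(
    f,
    x0: np.ndarray,
    scales: np.ndarray,
    free: np.ndarray | None = None,
    mesh0: float = 1.0,
    mesh_tol: float = 1e-3,
    max_evals: int = 2000,
) -> tuple[np.ndarray, float, int, int]:
    """Coordinate-wise polling pattern search.

    Polls +-mesh * scales[i] along each free coordinate (opportunistic:
    restarts polling from the first improving point); the mesh doubles
    after a successful poll round and halves after a failed one, stopping
    at ``mesh_tol`` or the evaluation budget. The accepted cost sequence is
    non-increasing by construction.
    """
    x = np.asarray(x0, dtype=float).copy()
    scales = np.asarray(scales, dtype=float)
    free_idx = np.arange(len(x)) if free is None else np.flatnonzero(free)
    fx = f(x)
    evals = 1
    mesh = mesh0
    iterations = 0
    while mesh > mesh_tol and evals < max_evals:
        iterations += 1
        improved = False
        for i in free_idx:
            for sgn in (+1.0, -1.0):
                cand = x.copy()
                cand[i] += sgn * mesh * scales[i]
                fc = f(cand)
                evals += 1
                if fc < fx - 1e-12:
                    x, fx = cand, fc
                    improved = True
                    break
                if evals >= max_evals:
                    break
            if evals >= max_evals:
                break
        mesh = mesh * 2.0 if improved else mesh * 0.5
    return x, fx, iterations, evals


# per-parameter poll scales: positions in mm, angles in rad
_SCALES = np.concatenate([np.full(3, 0.5), [0.2], np.full(8, 0.15), [0.2],
                          np.full(8, 0.15), [0.2]])


def _first_frame_orientation(images, proj, crop_origins, fixed, table, center,
                             length, cost_mode="fast", voxel_pitch=0.03):
    """Brute-force straight-backbone orientation grid for the first frame."""
    best = None
    thetas = np.deg2rad(np.arange(-180, 180, 10))
    phis = np.deg2rad(np.arange(-60, 61, 10))
    gammas = np.deg2rad(np.arange(-45, 46, 15))
    for th in thetas:
        for ph in phis:
            pose = FishPose(x0=center[0], y0=center[1], z0=center[2],
                            theta0=th, phi0=ph, gamma0=0.0, length=length)
            c, _ = cost_function(pose, images, proj, crop_origins, fixed,
                                 mode=cost_mode, table=table,
                                 voxel_pitch=voxel_pitch)
            if best is None or c < best[0]:
                best = (c, th, ph, 0.0)
    _, th, ph, _ = best
    for g in gammas:
        pose = FishPose(x0=center[0], y0=center[1], z0=center[2],
                        theta0=th, phi0=ph, gamma0=g, length=length)
        c, _ = cost_function(pose, images, proj, crop_origins, fixed,
                             mode=cost_mode, table=table, voxel_pitch=voxel_pitch)
        if c < best[0]:
            best = (c, th, ph, g)
    _, th, ph, g = best
    return FishPose(x0=center[0], y0=center[1], z0=center[2],
                    theta0=th, phi0=ph, gamma0=g, length=length)


def coarse_optimize(
    images: np.ndarray,
    proj,
    crop_origins: np.ndarray,
    init: FishPose | None = None,
    fixed: FixedBodyParameters | None = None,
    table: LookupTableP | None = None,
    length: float = 4.5,
    centroid_3d: np.ndarray | None = None,
    max_evals: int = 1200,
    mesh_tol: float = 1e-2,
    cost_ceiling: float | None = None,
) -> FitResult:
    """Coarse pattern-search round using the fast sprite renderer.

    Without an initial guess (first frame of a bout) a brute-force
    straight-backbone orientation grid seeds the search, positioned at the
    triangulated centroid. Succeeding frames pass the previous frame's fit
    as ``init``.
    """
    fixed = fixed or FixedBodyParameters()
    table = table or LookupTableP(fixed)
    if init is None:
        if centroid_3d is None:
            raise ValueError("need init or a triangulated centroid")
        init = _first_frame_orientation(images, proj, crop_origins, fixed,
                                        table, centroid_3d, length)
    L = init.length

    def f(p: np.ndarray) -> float:
        pose = FishPose.from_vector(_clip_pose_vector(p), length=L)
        return cost_function(pose, images, proj, crop_origins, fixed,
                             mode="fast", table=table)[0]

    # staged search: align the position first, then position+orientation,
    # then all 22 parameters — reduces basin-hopping from far starts
    pos_free = np.zeros(22, dtype=bool)
    pos_free[:3] = True
    x, _, it1, ev1 = pattern_search(f, init.to_vector(), _SCALES,
                                    free=pos_free, mesh0=0.5, mesh_tol=0.05,
                                    max_evals=max_evals // 8)
    x, _, it2, ev2 = pattern_search(f, x, _SCALES, free=_ANTERIOR_FREE,
                                    mesh0=0.5, mesh_tol=0.05,
                                    max_evals=max_evals // 4)
    x, fx, it3, ev3 = pattern_search(f, x, _SCALES, mesh0=0.5,
                                     mesh_tol=mesh_tol,
                                     max_evals=max_evals - ev1 - ev2)
    it, ev = it1 + it2 + it3, ev1 + ev2 + ev3
    pose = FishPose.from_vector(_clip_pose_vector(x), length=L)
    total, per_view = cost_function(pose, images, proj, crop_origins, fixed,
                                    mode="fast", table=table)
    flag = ""
    if cost_ceiling is not None and total > cost_ceiling:
        flag = "low-confidence"
    return FitResult(pose, total, per_view, "coarse", it, ev, flag)


def twist_pose(pose: FishPose, angle: float) -> FishPose:
    """Roll the body frame about the first backbone segment, keeping the
    backbone fixed in lab space.

    Shifts gamma0 by ``angle`` while re-expressing the bending angles in
    the rolled frame (exactly, via the coordinate representation). This is
    the near-degenerate direction of the image cost — only the anterior
    appearance distinguishes rolls — so optimizers scan it explicitly.
    """
    from .body import coordinates_to_pose, pose_to_coordinates

    coords = pose_to_coordinates(pose)
    b = coords.backbone
    X = b[1] - b[0]
    X = X / np.linalg.norm(X)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -X[2], X[1]], [X[2], 0, -X[0]], [-X[1], X[0], 0]])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)  # Rodrigues about the heading
    eyes = b[0] + (coords.eyes - b[0]) @ R.T
    new = coordinates_to_pose(
        type(coords)(b, eyes), length=pose.length)
    return new


def _twist_scan(pose: FishPose, cost_fn, max_deg: float = 90.0,
                step_deg: float = 10.0) -> tuple[FishPose, float]:
    """Evaluate the cost along the twist direction; return the best pose."""
    best_pose, best_cost = pose, cost_fn(pose)
    for deg in np.arange(-max_deg, max_deg + 1e-9, step_deg):
        if abs(deg) < 1e-9:
            continue
        try:
            cand = twist_pose(pose, np.deg2rad(deg))
        except ValueError:
            continue
        c = cost_fn(cand)
        if c < best_cost:
            best_pose, best_cost = cand, c
    return best_pose, best_cost


_ANTERIOR_FREE = np.zeros(22, dtype=bool)
_ANTERIOR_FREE[[0, 1, 2, 3, 12, 21]] = True  # position + head Euler angles
_POSTERIOR_FREE = np.zeros(22, dtype=bool)
_POSTERIOR_FREE[_ANGLE_IDX] = True


def fine_optimize(
    images: np.ndarray,
    proj,
    crop_origins: np.ndarray,
    init: FitResult,
    fixed: FixedBodyParameters | None = None,
    voxel_pitch: float = 0.03,
    max_evals_phase: int = 500,
    mesh_tol: float = 1e-3,
) -> FitResult:
    """Fine three-phase optimization with the accurate voxel renderer.

    Phase order: anterior (position + head angles), posterior (bending
    angles, with the anterior image cached), then a joint pass over all 22
    parameters. Returns the coarse result flagged unchanged if no phase
    improves the cost.
    """
    fixed = fixed or FixedBodyParameters()
    L = init.pose.length
    images = np.asarray(images, dtype=float)

    def full_cost(p: np.ndarray) -> float:
        pose = FishPose.from_vector(_clip_pose_vector(p), length=L)
        return cost_function(pose, images, proj, crop_origins, fixed,
                             mode="accurate", voxel_pitch=voxel_pitch)[0]

    def pose_cost(pose: FishPose) -> float:
        return cost_function(pose, images, proj, crop_origins, fixed,
                             mode="accurate", voxel_pitch=voxel_pitch)[0]

    start_pose, _ = _twist_scan(init.pose, pose_cost)
    x = start_pose.to_vector()
    evals = 0
    iters = 0
    # anterior phase (everything moves with the head: full renders)
    x, fa, it, ev = pattern_search(full_cost, x, _SCALES, free=_ANTERIOR_FREE,
                                   mesh0=0.25, mesh_tol=mesh_tol,
                                   max_evals=max_evals_phase)
    evals += ev
    iters += it
    # posterior phase: anterior image is static, cache it
    pose_a = FishPose.from_vector(_clip_pose_vector(x), length=L)
    static = render_component_images(pose_a, fixed, proj, crop_origins,
                                     mode="accurate", voxel_pitch=voxel_pitch,
                                     component="anterior")

    def tail_cost(p: np.ndarray) -> float:
        pose = FishPose.from_vector(_clip_pose_vector(p), length=L)
        return cost_function(pose, images, proj, crop_origins, fixed,
                             mode="accurate", voxel_pitch=voxel_pitch,
                             component="tail", static=static)[0]

    # progressive per-joint pass head -> tail first: each joint is the
    # lever for everything behind it, so fixing joints in order restores
    # overlap for the next one even when the tail starts far off
    for j in range(8):
        free_j = np.zeros(22, dtype=bool)
        free_j[[4 + j, 13 + j]] = True
        x, _, it, ev = pattern_search(tail_cost, x, _SCALES, free=free_j,
                                      mesh0=1.0, mesh_tol=0.02, max_evals=60)
        evals += ev
        iters += it
    x, _, it, ev = pattern_search(tail_cost, x, _SCALES, free=_POSTERIOR_FREE,
                                  mesh0=0.25, mesh_tol=mesh_tol,
                                  max_evals=max_evals_phase)
    evals += ev
    iters += it
    # second twist scan now that the tail matches, then the joint pass
    pose_p, _ = _twist_scan(FishPose.from_vector(_clip_pose_vector(x), length=L),
                            pose_cost)
    x = pose_p.to_vector()
    # joint final pass
    x, fj, it, ev = pattern_search(full_cost, x, _SCALES, mesh0=0.05,
                                   mesh_tol=mesh_tol,
                                   max_evals=max_evals_phase)
    evals += ev
    iters += it
    pose = FishPose.from_vector(_clip_pose_vector(x), length=L)
    total, per_view = cost_function(pose, images, proj, crop_origins, fixed,
                                    mode="accurate", voxel_pitch=voxel_pitch)
    if total > init.cost:
        return replace(init, flag="fine-no-improvement")
    return FitResult(pose, total, per_view, "fine", iters, evals)


# --------------------------------------------------------------------------
# length estimation
# --------------------------------------------------------------------------

def estimate_length(
    frame_sets: list[list[PreprocessedFrame]],
    proj,
    fixed: FixedBodyParameters | None = None,
    init_length: float = 4.5,
    table: LookupTableP | None = None,
) -> tuple[float, np.ndarray]:
    """Estimate larval length from straight-pose frames.

    For each frame (one PreprocessedFrame per camera) the best straight-
    backbone orientation is found by brute force at the initial length
    guess of 4.5 mm, then the length is scaled by the ratio of observed to
    rendered segmented extents (median over cameras). Returns the mean
    over frames and the per-frame estimates; a per-frame spread above 10%
    suggests bent fish and is reported via the spread.
    """
    import warnings

    fixed = fixed or FixedBodyParameters()
    table = table or LookupTableP(fixed)
    if len(frame_sets) < 10:
        warnings.warn("fewer than 10 straight-pose frames; averaging over "
                      f"{len(frame_sets)}")
    estimates = []
    for dets in frame_sets:
        images = np.stack([d.image for d in dets]).astype(float)
        origins = np.stack([d.crop_origin for d in dets])
        pix = [d.centroid for d in dets]
        center, _, _ = triangulate_point(proj, pix)
        pose = _first_frame_orientation(images, proj, origins, fixed, table,
                                        center, init_length)
        ratios = []
        for c in range(len(dets)):
            obs_len = _mask_extent(dets[c].mask)
            model = render_views(pose, fixed, proj, mode="fast", table=table,
                                 crop_centers=origins + (IMAGE_SIZE - 1) // 2)
            mdl_len = _mask_extent(model.images[c] > 25)
            if mdl_len > 0 and obs_len > 0:
                ratios.append(obs_len / mdl_len)
        if ratios:
            estimates.append(init_length * float(np.median(ratios)))
    estimates = np.array(estimates)
    if len(estimates) == 0:
        raise ValueError("no usable frames for length estimation")
    if estimates.std() > 0.1 * estimates.mean():
        warnings.warn("length estimates spread exceeds 10%; fish may be bent")
    return float(estimates.mean()), estimates


def _mask_extent(mask: np.ndarray) -> float:
    """Length of the principal axis of a binary mask (px)."""
    props = measure.regionprops(mask.astype(np.uint8))
    return float(props[0].axis_major_length) if props else 0.0
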