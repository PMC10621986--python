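"""Rendering of larva views from the voxel physical model.

The anterior (eyes, head, belly) is a voxel grid whose intensity is the
maximum of four anisotropic Gaussian densities; camera views are obtained
by projecting every voxel and summing intensities per pixel. The tail is
drawn directly in 2-D as eight trapezium/disk (capsule) segments on the
projected backbone, with a Gaussian transverse profile and a linearly
decreasing longitudinal intensity. Overlapping anterior/tail pixels keep
the higher value, and each finished view is rescaled so its brightest
pixel equals 255 (8-bit).

A sprite cache (Lookup Table P) provides the fast rendering mode used by
coarse template optimization: anterior sprites are orthographic voxel
projections over discretized orientations and scales; tail-segment sprites
are indexed by orientation (5 deg steps), projected length, and subpixel
offset (0.2 px steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body import (FishPose, FixedBodyParameters, PoseCoordinates3D,
                   head_rotation, pose_to_coordinates)

__all__ = [
    "VoxelGrid",
    "ViewTriplet",
    "OrthographicProjection",
    "LookupTableP",
    "render_anterior_voxels",
    "render_views",
    "build_lookup_table_p",
    "project_pose_keypoints",
    "IMAGE_SIZE",
]

IMAGE_SIZE = 141


# --------------------------------------------------------------------------
# projections and containers
# --------------------------------------------------------------------------

@dataclass
class OrthographicProjection:
    """Parallel projection along each camera's principal axis.

    Shares the axis conventions of the default three-camera rig; pixels
    are ``pixel_mm`` on a side with the lab origin at pixel (0, 0).
    """

    pixel_mm: float = 0.065
    axis_maps: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(0, 1, 2), (1, 2, 0), (2, 0, 1)])

    @property
    def n_cameras(self) -> int:
        return len(self.axis_maps)

    def project(self, point: np.ndarray, camera: int,
                check_domain: bool = True) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        ax, ay, _ = self.axis_maps[camera]
        out = np.column_stack([pts[:, ax], pts[:, ay]]) / self.pixel_mm
        return out[0] if np.asarray(point).ndim == 1 else out


@dataclass
class ViewTriplet:
    """Co-registered camera views of one larva.

    ``images`` is (n_cameras, 141, 141) uint8; ``crop_origins`` holds the
    integer sensor pixel of each view's (0, 0) corner so keypoints can be
    mapped between sensor and crop coordinates.
    """

    images: np.ndarray
    camera_ids: tuple[int, ...]
    mode: str  # {"orthographic", "refractive"}
    crop_origins: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.dtype != np.uint8:
            raise ValueError("view images must be 8-bit")
        if self.images.shape[-2:] != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"views must be {IMAGE_SIZE}x{IMAGE_SIZE}")


@dataclass
class VoxelGrid:
    origin: np.ndarray  # lab mm of voxel (0,0,0) center
    pitch: float
    values: np.ndarray  # (nx, ny, nz)

    def centers(self) -> np.ndarray:
        """(N, 3) lab coordinates of all voxel centers."""
        nx, ny, nz = self.values.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        return self.origin + self.pitch * idx


# --------------------------------------------------------------------------
# anterior voxel model
# --------------------------------------------------------------------------

def _anterior_components(pose: FishPose, fixed: FixedBodyParameters):
    """(mu_lab, precision, brightness, max_sigma) for the four Gaussians."""
    R0 = head_rotation(pose.theta0, pose.phi0, pose.gamma0)
    half = fixed.eye_separation / 2.0
    spec = [
        (np.array([fixed.eye_along, -half, fixed.eye_off]), fixed.dims_eye,
         fixed.brightness_eye),
        (np.array([fixed.eye_along, half, fixed.eye_off]), fixed.dims_eye,
         fixed.brightness_eye),
        (np.array([fixed.head_along, 0.0, fixed.head_off]), fixed.dims_head,
         fixed.brightness_head),
        (np.array([fixed.belly_along, 0.0, fixed.belly_off]), fixed.dims_belly,
         fixed.brightness_belly),
    ]
    comps = []
    for pos_fish, dims, bright in spec:
        mu = pose.head + R0 @ pos_fish
        var = np.asarray(dims, dtype=float) ** 2 / fixed.cov_scale
        prec = R0 @ np.diag(1.0 / var) @ R0.T
        comps.append((mu, prec, bright, float(np.sqrt(var.max()))))
    return comps


def render_anterior_voxels(pose: FishPose, fixed: FixedBodyParameters | None = None,
                           pitch: float = 0.015, n_sigma: float = 3.5) -> VoxelGrid:
    """Voxelize the anterior intensity profile V = max of four scaled
    Gaussians (two eyes, head, belly)."""
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    fixed = fixed or FixedBodyParameters()
    comps = _anterior_components(pose, fixed)
    if min(c[3] for c in comps[:2]) < pitch:
        import warnings
        warnings.warn("voxel pitch is coarse relative to the eye size")
    los = np.min([mu - n_sigma * s for mu, _, _, s in comps], axis=0)
    his = np.max([mu + n_sigma * s for mu, _, _, s in comps], axis=0)
    shape = np.maximum(np.ceil((his - los) / pitch).astype(int) + 1, 2)
    grid = VoxelGrid(los, pitch, np.zeros(tuple(shape)))
    P = grid.centers()
    V = np.zeros(len(P))
    for mu, prec, bright, _ in comps:
        d = P - mu
        q = np.einsum("ni,ij,nj->n", d, prec, d)
        np.maximum(V, bright * np.exp(-0.5 * q), out=V)
    grid.values = V.reshape(tuple(shape))
    return grid


# --------------------------------------------------------------------------
# 2-D tail drawing
# --------------------------------------------------------------------------

TAIL_TIP_FRACTION = 0.3  # longitudinal intensity at the tail tip

# fish-frame anterior voxel clouds, keyed by (fixed parameters, pitch);
# rotating a cached cloud is equivalent to re-voxelizing per pose and far
# cheaper inside optimization loops
_TEMPLATE_CACHE: dict = {}


def _anterior_template(fixed: FixedBodyParameters, pitch: float):
    import dataclasses
    key = (dataclasses.astuple(fixed), pitch)
    if key not in _TEMPLATE_CACHE:
        grid = render_anterior_voxels(FishPose(), fixed, pitch=pitch)
        centers = grid.centers()
        vals = grid.values.ravel()
        keep = vals > 1e-4 * vals.max()
        _TEMPLATE_CACHE[key] = (centers[keep], vals[keep])
        if len(_TEMPLATE_CACHE) > 64:
            _TEMPLATE_CACHE.pop(next(iter(_TEMPLATE_CACHE)))
    return _TEMPLATE_CACHE[key]


def _draw_tail(img: np.ndarray, backbone_px: np.ndarray, sigma_px: np.ndarray,
               brightness: float) -> None:
    """Draw the eight posterior capsule segments into ``img`` (max-combine).

    ``backbone_px`` is the (10, 2) projected backbone in crop coordinates;
    segments span points 1..9. ``sigma_px`` gives the per-view transverse
    Gaussian width in pixels (scalar or per-segment array).
    """
    h, w = img.shape
    sig = np.broadcast_to(np.asarray(sigma_px, dtype=float), (8,))
    for s in range(8):
        q0, q1 = backbone_px[1 + s], backbone_px[2 + s]
        amp0 = 1.0 + (TAIL_TIP_FRACTION - 1.0) * s / 8.0
        amp1 = 1.0 + (TAIL_TIP_FRACTION - 1.0) * (s + 1) / 8.0
        pad = 3.5 * sig[s] + 1
        x0 = max(int(np.floor(min(q0[0], q1[0]) - pad)), 0)
        x1 = min(int(np.ceil(max(q0[0], q1[0]) + pad)) + 1, w)
        y0 = max(int(np.floor(min(q0[1], q1[1]) - pad)), 0)
        y1 = min(int(np.ceil(max(q0[1], q1[1]) + pad)) + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        p = np.stack([xs, ys], axis=-1).astype(float)
        v = q1 - q0
        vv = v @ v
        t = ((p - q0) @ v) / vv if vv > 1e-12 else np.zeros(p.shape[:2])
        t = np.clip(t, 0.0, 1.0)
        foot = q0 + t[..., None] * v
        d2 = np.sum((p - foot) ** 2, axis=-1)
        amp = amp0 + (amp1 - amp0) * t
        patch = brightness * amp * np.exp(-d2 / (2.0 * sig[s] ** 2))
        np.maximum(img[y0:y1, x0:x1], patch, out=img[y0:y1, x0:x1])


# --------------------------------------------------------------------------
# full view rendering
# --------------------------------------------------------------------------

def project_pose_keypoints(pose: FishPose, proj, fixed: FixedBodyParameters | None = None,
                           crop_origins: np.ndarray | None = None) -> np.ndarray:
    """Per-view 12 keypoints (10 backbone + 2 eyes) in pixel coordinates.

    Returns (n_cameras, 12, 2); crop origins, when given, shift sensor
    pixels into crop coordinates.
    """
    fixed = fixed or FixedBodyParameters()
    coords = pose_to_coordinates(pose, fixed)
    pts = coords.points
    out = np.stack([proj.project(pts, c, check_domain=False)
                    for c in range(proj.n_cameras)])
    if crop_origins is not None:
        out = out - np.asarray(crop_origins, dtype=float)[:, None, :]
    return out


def _pixel_scale(proj, camera: int, coords: PoseCoordinates3D) -> float:
    """Local transverse magnification (px per mm) at the head position."""
    ax, ay, _ = proj.axis_maps[camera]
    p = coords.backbone[0]
    delta = 0.1  # mm probe
    scales = []
    for axis in (ax, ay):
        q = p.copy()
        q[axis] += delta
        a = proj.project(p, camera, check_domain=False)
        b = proj.project(q, camera, check_domain=False)
        scales.append(np.linalg.norm(b - a) / delta)
    return float(np.mean(scales))


def render_views(
    pose: FishPose,
    fixed: FixedBodyParameters | None = None,
    proj=None,
    mode: str = "accurate",
    table: "LookupTableP | None" = None,
    voxel_pitch: float = 0.02,
    crop_centers: np.ndarray | None = None,
    size: int = IMAGE_SIZE,
    sensor_shape: tuple[int, int] | None = None,
    return_keypoints: bool = False,
):
    """Render the three camera views of a pose.

    ``proj`` is a RefractiveProjection or OrthographicProjection (defaults
    to orthographic). ``mode`` selects the accurate per-voxel anterior
    projection or the sprite-based fast path (a LookupTableP is created on
    demand when not supplied). Views are cropped to ``size`` x ``size``
    around the projected backbone centroid unless explicit sensor-pixel
    ``crop_centers`` are given. Raises when the fish leaves a camera's
    field of view.
    """
    fixed = fixed or FixedBodyParameters()
    proj = proj if proj is not None else OrthographicProjection()
    coords = pose_to_coordinates(pose, fixed)
    n_cam = proj.n_cameras
    origins = np.zeros((n_cam, 2), dtype=int)
    keypoints = np.zeros((n_cam, 12, 2))
    bad_cameras = []
    for c in range(n_cam):
        kp = proj.project(coords.points, c, check_domain=False)
        if sensor_shape is not None:
            ny, nx = sensor_shape
            if (kp[:, 0].min() < 0 or kp[:, 0].max() > nx - 1
                    or kp[:, 1].min() < 0 or kp[:, 1].max() > ny - 1):
                bad_cameras.append(c)
        center = (np.round(np.mean(kp[:10], axis=0)).astype(int)
                  if crop_centers is None else
                  np.round(np.asarray(crop_centers)[c]).astype(int))
        origins[c] = center - (size - 1) // 2
        keypoints[c] = kp - origins[c]
    if bad_cameras:
        raise ValueError(f"fish outside field of view of cameras {bad_cameras}")
    images = render_component_images(pose, fixed, proj, origins, mode=mode,
                                     table=table, voxel_pitch=voxel_pitch,
                                     size=size)
    peak = images.reshape(n_cam, -1).max(axis=1)
    if np.any(peak <= 0):
        raise ValueError("empty rendering: no voxel projected into the crop")
    out = np.clip(images / peak[:, None, None] * 255.0, 0, 255)
    out = np.round(out).astype(np.uint8)
    mode_tag = ("orthographic" if isinstance(proj, OrthographicProjection)
                else "refractive")
    trip = ViewTriplet(out, tuple(range(n_cam)), mode_tag, origins)
    return (trip, keypoints) if return_keypoints else trip


def render_component_images(
    pose: FishPose,
    fixed: FixedBodyParameters,
    proj,
    crop_origins: np.ndarray,
    mode: str = "accurate",
    table: "LookupTableP | None" = None,
    voxel_pitch: float = 0.02,
    size: int = IMAGE_SIZE,
    component: str = "both",
) -> np.ndarray:
    """Unnormalized float view images for the anterior, tail, or both.

    Max-combines the two body parts per the rendering contract; exposing
    the components separately lets optimizers cache whichever part is not
    being varied.
    """
    if mode not in ("accurate", "fast"):
        raise ValueError(f"unknown mode {mode!r}")
    coords = pose_to_coordinates(pose, fixed)
    n_cam = proj.n_cameras
    crop_origins = np.asarray(crop_origins, dtype=int)
    images = np.zeros((n_cam, size, size))
    if mode == "fast" and table is None:
        table = LookupTableP(fixed)
    for c in range(n_cam):
        origin = crop_origins[c]
        img = images[c]
        if component in ("both", "anterior"):
            if mode == "accurate":
                tmpl_centers, tmpl_vals = _anterior_template(fixed, voxel_pitch)
                R0 = head_rotation(pose.theta0, pose.phi0, pose.gamma0)
                centers = pose.head + tmpl_centers @ R0.T
                px = proj.project(centers, c, check_domain=False) - origin
                idx = np.round(px).astype(int)
                ok = ((idx[:, 0] >= 0) & (idx[:, 0] < size)
                      & (idx[:, 1] >= 0) & (idx[:, 1] < size))
                flat = idx[ok, 1] * size + idx[ok, 0]
                ant = np.bincount(flat, weights=tmpl_vals[ok],
                                  minlength=size * size).reshape(size, size)
                # normalize the summed-voxel anterior to the 8-bit scale so
                # its brightness is commensurate with the drawn tail
                if ant.max() > 0:
                    ant *= 255.0 / ant.max()
                np.maximum(img, ant, out=img)
            else:
                table.paste_anterior(img, pose, proj, c, origin)
        if component in ("both", "tail"):
            kp_crop = proj.project(coords.backbone, c, check_domain=False) - origin
            scale = _pixel_scale(proj, c, coords)
            sigma_px = fixed.tail_width_scale * pose.length / 40.0 * scale
            if mode == "fast":
                tail_img = np.zeros_like(img)
                table.paste_tail(tail_img, kp_crop, sigma_px)
                np.maximum(img, tail_img, out=img)
            else:
                _draw_tail(img, kp_crop, sigma_px, fixed.brightness_belly)
    return images


# --------------------------------------------------------------------------
# Lookup Table P: sprite cache for fast rendering
# --------------------------------------------------------------------------

class LookupTableP:
    """Precomputed 2-D sprites of the anterior and of tail segments.

    Entries are generated lazily and cached: the anterior as orthographic
    projections of the voxel model over orientation bins (``angle_step``
    degrees) and projected-scale bins; tail segments over orientation bins,
    projected-length bins and ``offset_step``-pixel subpixel offsets.
    """

    def __init__(self, fixed: FixedBodyParameters | None = None,
                 angle_step_deg: float = 5.0, offset_step_px: float = 0.2,
                 scale_step: float = 0.25, length_step_px: float = 0.5,
                 voxel_pitch: float = 0.025):
        self.fixed = fixed or FixedBodyParameters()
        self.angle_step = np.deg2rad(angle_step_deg)
        self.offset_step = offset_step_px
        self.scale_step = scale_step
        self.length_step = length_step_px
        self.voxel_pitch = voxel_pitch
        self._anterior: dict = {}
        self._tail: dict = {}

    # -- anterior ---------------------------------------------------------

    def _anterior_sprite(self, key) -> np.ndarray:
        if key not in self._anterior:
            qkey, sb = key
            scale = sb * self.scale_step
            q = np.array(qkey, dtype=float)
            q /= np.linalg.norm(q)
            R = _rotation_from_quaternion(q)
            centers, vals = _anterior_template(self.fixed, self.voxel_pitch)
            rotated = centers @ R.T
            # orthographic projection along the depth axis at the binned
            # scale, sprite centered on the head point
            half = 34
            px = rotated[:, :2] * scale + half
            idx = np.round(px).astype(int)
            ok = ((idx[:, 0] >= 0) & (idx[:, 0] <= 2 * half)
                  & (idx[:, 1] >= 0) & (idx[:, 1] <= 2 * half))
            flat = idx[ok, 1] * (2 * half + 1) + idx[ok, 0]
            img = np.bincount(flat, weights=vals[ok],
                              minlength=(2 * half + 1) ** 2)
            img = img.reshape(2 * half + 1, 2 * half + 1)
            if img.max() > 0:
                img *= 255.0 / img.max()  # match the accurate-path scale
            self._anterior[key] = img
        return self._anterior[key]

    def anterior_entry(self, rotation: np.ndarray, scale: float) -> np.ndarray:
        """Sprite for the nearest orientation/scale bin.

        Orientation bins quantize the unit quaternion of ``rotation`` on a
        uniform grid whose spacing matches the configured angular step
        (stable for all orientations, unlike Euler-angle binning).
        """
        q = _quaternion_from_rotation(rotation)
        if q[0] < 0:
            q = -q
        step = self.angle_step / 2.0  # quaternion half-angle
        key = (tuple(np.round(q / step).astype(int)),
               max(int(np.round(scale / self.scale_step)), 1))
        return self._anterior_sprite(key)

    def paste_anterior(self, img: np.ndarray, pose: FishPose, proj,
                       camera: int, origin: np.ndarray) -> None:
        """Paste the binned anterior sprite at the projected head pixel."""
        coords = pose_to_coordinates(pose, self.fixed)
        # head orientation as seen by this camera: express the fish axes in
        # the camera's (pixel-x, pixel-y, depth) axis order
        ax, ay, az = proj.axis_maps[camera]
        perm = np.eye(3)[[ax, ay, az]]
        Rc = perm @ head_rotation(pose.theta0, pose.phi0, pose.gamma0)
        scale = _pixel_scale(proj, camera, coords)
        sprite = self.anterior_entry(Rc, scale)
        head_px = proj.project(coords.backbone[0], camera, check_domain=False) - origin
        _paste_max(img, sprite, np.round(head_px).astype(int))

    # -- tail -------------------------------------------------------------

    def _tail_sprite(self, key) -> np.ndarray:
        if key not in self._tail:
            ab, lb, oxb, oyb, samp0, samp1, sgb = key
            angle = ab * self.angle_step
            length = lb * self.length_step
            off = np.array([oxb, oyb]) * self.offset_step
            sigma = sgb * 0.1
            half = int(np.ceil(length / 2 + 3.5 * sigma)) + 1
            ctr = np.array([half, half], dtype=float) + off
            d = np.array([np.cos(angle), np.sin(angle)])
            q0 = ctr - d * length / 2
            q1 = ctr + d * length / 2
            tmp = np.zeros((2 * half + 1, 2 * half + 1))
            _draw_capsule(tmp, q0, q1, samp0 / 100.0, samp1 / 100.0, sigma)
            self._tail[key] = tmp
        return self._tail[key]

    def tail_entry(self, angle: float, length_px: float, offset: np.ndarray,
                   amp0: float = 1.0, amp1: float = 1.0,
                   sigma_px: float = 1.0) -> np.ndarray:
        key = (int(np.round(angle / self.angle_step)),
               max(int(np.round(length_px / self.length_step)), 1),
               int(np.round(offset[0] / self.offset_step)),
               int(np.round(offset[1] / self.offset_step)),
               int(np.round(amp0 * 100)), int(np.round(amp1 * 100)),
               max(int(np.round(sigma_px / 0.1)), 1))
        return self._tail_sprite(key)

    def paste_tail(self, img: np.ndarray, backbone_px: np.ndarray,
                   sigma_px: float) -> None:
        for s in range(8):
            q0, q1 = backbone_px[1 + s], backbone_px[2 + s]
            v = q1 - q0
            length = float(np.linalg.norm(v))
            angle = float(np.arctan2(v[1], v[0]))
            mid = (q0 + q1) / 2.0
            mid_int = np.floor(mid).astype(int)
            offset = mid - mid_int
            amp0 = 1.0 + (TAIL_TIP_FRACTION - 1.0) * s / 8.0
            amp1 = 1.0 + (TAIL_TIP_FRACTION - 1.0) * (s + 1) / 8.0
            sprite = self.tail_entry(angle, length, offset, amp0, amp1, sigma_px)
            _paste_max(img, sprite * self.fixed.brightness_belly, mid_int)


def _quaternion_from_rotation(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a rotation matrix."""
    t = np.trace(R)
    if t > 0:
        w = 0.5 * np.sqrt(1.0 + t)
        f = 0.25 / w
        return np.array([w, f * (R[2, 1] - R[1, 2]), f * (R[0, 2] - R[2, 0]),
                         f * (R[1, 0] - R[0, 1])])
    i = int(np.argmax(np.diag(R)))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = np.sqrt(max(1.0 + R[i, i] - R[j, j] - R[k, k], 0.0))
    q = np.zeros(4)
    q[1 + i] = 0.5 * s
    f = 0.25 / (0.5 * s)
    q[0] = f * (R[k, j] - R[j, k])
    q[1 + j] = f * (R[j, i] + R[i, j])
    q[1 + k] = f * (R[k, i] + R[i, k])
    return q


def _rotation_from_quaternion(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _draw_capsule(img: np.ndarray, q0: np.ndarray, q1: np.ndarray,
                  amp0: float, amp1: float, sigma: float) -> None:
    """Single trapezium/disk segment with Gaussian transverse profile."""
    h, w = img.shape
    xs, ys = np.meshgrid(np.arange(w), np.arange(h))
    p = np.stack([xs, ys], axis=-1).astype(float)
    v = q1 - q0
    vv = v @ v
    t = ((p - q0) @ v) / vv if vv > 1e-12 else np.zeros(p.shape[:2])
    t = np.clip(t, 0.0, 1.0)
    foot = q0 + t[..., None] * v
    d2 = np.sum((p - foot) ** 2, axis=-1)
    amp = amp0 + (amp1 - amp0) * t
    np.maximum(img, amp * np.exp(-d2 / (2.0 * sigma**2)), out=img)


def _paste_max(img: np.ndarray, sprite: np.ndarray, at: np.ndarray) -> None:
    """Max-paste ``sprite`` with its center at integer pixel ``at``."""
    sh, sw = sprite.shape
    cy, cx = (sh - 1) // 2, (sw - 1) // 2
    y0 = at[1] - cy
    x0 = at[0] - cx
    ys0, xs0 = max(-y0, 0), max(-x0, 0)
    ye = min(img.shape[0] - y0, sh)
    xe = min(img.shape[1] - x0, sw)
    if ys0 >= ye or xs0 >= xe:
        return
    dst = img[y0 + ys0:y0 + ye, x0 + xs0:x0 + xe]
    np.maximum(dst, sprite[ys0:ye, xs0:xe], out=dst)


def build_lookup_table_p(fixed: FixedBodyParameters | None = None,
                         **kwargs) -> LookupTableP:
    """Create the sprite lookup table (entries fill lazily on first use)."""
    return LookupTableP(fixed, **kwargs)
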