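"""Camera models and refraction-corrected 3-D <-> 2-D mapping.

The lab frame has its origin at the tank center with axes along the three
camera principal axes (right-handed, mm units). Pixel coordinates are
0-based with pixel centers at integer coordinates, x right / y down.

Because the three cameras are mutually orthogonal and aligned with the lab
axes, each pixel axis of a camera depends on only two lab coordinates (one
transverse axis plus the depth axis of that camera), so the empirical
refraction-corrected projection separates into two independent bivariate
cubic polynomials per camera.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PinholeCamera",
    "RefractiveProjection",
    "RayTable",
    "project_linear",
    "fit_refractive_projection",
    "reconstruct_dots_air",
    "triangulate_point",
    "build_ray_table",
    "ray_for_pixel",
    "ray_ray_distance",
    "match_larvae_across_views",
    "save_calibration",
    "load_calibration",
]


# --------------------------------------------------------------------------
# linear pinhole model
# --------------------------------------------------------------------------

@dataclass
class PinholeCamera:
    """Linear pinhole camera: lab (mm) -> pixel.

    ``rotation`` maps lab coordinates into camera coordinates (camera z is
    the viewing direction); ``translation`` is the camera-frame offset, so
    X_cam = R @ X_lab + t.  ``axis_map`` records which lab axis each of
    (pixel x, pixel y, depth) follows; it drives the separable cubic fit.
    """

    focal_px: tuple[float, float]
    principal_point: tuple[float, float]
    rotation: np.ndarray
    translation: np.ndarray
    skew: float = 0.0
    axis_map: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        fx, fy = self.focal_px
        if fx <= 0 or fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.axis_map is None:
            # infer from the dominant lab axis of each camera axis
            R = self.rotation
            self.axis_map = tuple(int(np.argmax(np.abs(R[i]))) for i in range(3))

    @property
    def intrinsic(self) -> np.ndarray:
        """3x3 intrinsic matrix K (row-vector convention)."""
        fx, fy = self.focal_px
        u0, v0 = self.principal_point
        return np.array([[fx, 0.0, 0.0], [self.skew, fy, 0.0], [u0, v0, 1.0]])

    @property
    def extrinsic(self) -> np.ndarray:
        """4x3 extrinsic matrix M: [x,y,z,1] M = X_cam."""
        return np.vstack([self.rotation.T, self.translation])

    @property
    def matrix(self) -> np.ndarray:
        """4x3 camera matrix P = M K so that [x_lab,y_lab,z_lab,1] P ~ [u,v,1]."""
        return self.extrinsic @ self.intrinsic

    @property
    def center(self) -> np.ndarray:
        """Optical center in lab coordinates."""
        return -self.rotation.T @ self.translation

    @property
    def principal_axis(self) -> np.ndarray:
        """Viewing direction (camera z) in lab coordinates."""
        return self.rotation[2]


def project_linear(cam: PinholeCamera, point: np.ndarray) -> np.ndarray:
    """Project lab point(s) through the linear pinhole model.

    Accepts a single 3-vector or an (N, 3) array; raises if any point lies
    on or behind the camera plane.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite point")
    hom = np.hstack([pts, np.ones((len(pts), 1))])
    uvw = hom @ cam.matrix
    if np.any(uvw[:, 2] <= 0):
        raise ValueError("point behind camera plane")
    px = uvw[:, :2] / uvw[:, 2:3]
    return px[0] if np.asarray(point).ndim == 1 else px


# --------------------------------------------------------------------------
# separable cubic refraction-corrected projection
# --------------------------------------------------------------------------

def _cubic_design(a: np.ndarray, b: np.ndarray, degree: int = 3) -> np.ndarray:
    """Bivariate polynomial design matrix with all monomials a^i b^j, i+j<=degree."""
    cols = [a**i * b**j for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.column_stack(cols)


N_CUBIC_COEFFS = 10  # monomials a^i b^j with i + j <= 3


@dataclass
class RefractiveProjection:
    """Per-camera separable empirical projection absorbing refraction.

    For camera ``c`` pixel x is a bivariate cubic in lab axes
    ``(axis_map[0], axis_map[2])`` and pixel y a cubic in
    ``(axis_map[1], axis_map[2])``.
    """

    coeffs_x: list[np.ndarray]
    coeffs_y: list[np.ndarray]
    axis_maps: list[tuple[int, int, int]]
    valid_domain: np.ndarray  # (2, 3) [lo; hi] in lab mm
    rms_residual_px: list[float] = field(default_factory=list)
    degree: int = 3

    @property
    def n_cameras(self) -> int:
        return len(self.coeffs_x)

    def _check_domain(self, pts: np.ndarray) -> None:
        lo, hi = self.valid_domain
        tol = 1e-6
        if np.any(pts < lo - tol) or np.any(pts > hi + tol):
            raise ValueError("point outside calibrated valid_domain")

    def project(self, point: np.ndarray, camera: int,
                check_domain: bool = True) -> np.ndarray:
        """Map lab point(s) to pixel coordinates of one camera."""
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        if check_domain:
            self._check_domain(pts)
        ax, ay, az = self.axis_maps[camera]
        u = _cubic_design(pts[:, ax], pts[:, az], self.degree) @ self.coeffs_x[camera]
        v = _cubic_design(pts[:, ay], pts[:, az], self.degree) @ self.coeffs_y[camera]
        out = np.column_stack([u, v])
        return out[0] if np.asarray(point).ndim == 1 else out

    def project_all(self, point: np.ndarray, check_domain: bool = True) -> list[np.ndarray]:
        return [self.project(point, c, check_domain) for c in range(self.n_cameras)]


def fit_refractive_projection(
    dots3d: np.ndarray,
    pixels: list[np.ndarray],
    axis_maps: list[tuple[int, int, int]] | None = None,
    cams: list[PinholeCamera] | None = None,
    degree: int = 3,
    domain_pad: float = 0.0,
) -> RefractiveProjection:
    """Least-squares fit of the separable per-camera cubic projection.

    Parameters
    ----------
    dots3d : (N, 3) lab positions of calibration dots (mm).
    pixels : per camera, (N, 2) observed pixel coordinates of the dots.
    axis_maps : per camera (pixel-x axis, pixel-y axis, depth axis); taken
        from ``cams`` when omitted.
    """
    dots3d = np.asarray(dots3d, dtype=float)
    n_terms = (degree + 1) * (degree + 2) // 2
    if len(dots3d) < n_terms:
        raise ValueError(f"need at least {n_terms} dots for a degree-{degree} fit")
    if axis_maps is None:
        if cams is None:
            raise ValueError("provide axis_maps or cams")
        axis_maps = [cam.axis_map for cam in cams]

    coeffs_x, coeffs_y, rms = [], [], []
    for c, px in enumerate(pixels):
        px = np.asarray(px, dtype=float)
        ax, ay, az = axis_maps[c]
        for axis_name, (a_idx, obs_col) in {"x": (ax, 0), "y": (ay, 1)}.items():
            A = _cubic_design(dots3d[:, a_idx], dots3d[:, az], degree)
            if np.linalg.matrix_rank(A) < A.shape[1]:
                raise ValueError(
                    f"rank-deficient dot configuration for camera {c} axis {axis_name}")
            # QR for conditioning
            q, r = np.linalg.qr(A)
            coef = np.linalg.solve(r, q.T @ px[:, obs_col])
            res = A @ coef - px[:, obs_col]
            if axis_name == "x":
                coeffs_x.append(coef)
                res_x = res
            else:
                coeffs_y.append(coef)
                rms.append(float(np.sqrt(np.mean(res_x**2 + res**2))))
    lo = dots3d.min(axis=0) - domain_pad
    hi = dots3d.max(axis=0) + domain_pad
    return RefractiveProjection(coeffs_x, coeffs_y, list(axis_maps),
                                np.vstack([lo, hi]), rms, degree)


# --------------------------------------------------------------------------
# triangulation
# --------------------------------------------------------------------------

def reconstruct_dots_air(
    pixels: list[np.ndarray],
    cams: list[PinholeCamera],
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Reconstruct 3-D dot positions from refraction-free (air) images.

    Minimizes the summed squared pixel reprojection residual over the
    cameras that see each dot. Dots seen by fewer than two cameras are
    skipped (returned in the skipped-index list).
    """
    from scipy.optimize import least_squares

    n_dots = len(pixels[0])
    n_cams = len(cams)
    if valid is None:
        valid = np.ones((n_dots, n_cams), dtype=bool)
    out = np.full((n_dots, 3), np.nan)
    skipped: list[int] = []
    for n in range(n_dots):
        views = [c for c in range(n_cams) if valid[n, c]]
        if len(views) < 2:
            skipped.append(n)
            continue

        def resid(X: np.ndarray, n=n, views=views) -> np.ndarray:
            return np.concatenate(
                [project_linear(cams[c], X) - pixels[c][n] for c in views])

        sol = least_squares(resid, x0=np.zeros(3), method="lm")
        out[n] = sol.x
    return out, skipped


def triangulate_point(
    proj: RefractiveProjection,
    pixels: list[np.ndarray | None],
    x0: np.ndarray | None = None,
    max_nfev: int = 200,
) -> tuple[np.ndarray, float, bool]:
    """Triangulate one lab point from per-camera pixel observations.

    Nonlinear least squares on the pixel reprojection error of the
    empirical cubic projection, started from the tank center. ``pixels``
    entries may be None for unobserved views. Returns (point, RMS residual
    in px, converged flag).
    """
    from scipy.optimize import least_squares

    views = [c for c, p in enumerate(pixels) if p is not None]
    if len(views) < 2:
        raise ValueError("need observations from at least 2 cameras")
    obs = np.concatenate([np.asarray(pixels[c], float) for c in views])
    lo, hi = proj.valid_domain

    def resid(X: np.ndarray) -> np.ndarray:
        Xc = np.clip(X, lo, hi)
        pred = np.concatenate([proj.project(Xc, c, check_domain=False)
                               for c in views])
        return pred - obs

    start = np.zeros(3) if x0 is None else np.asarray(x0, float)
    sol = least_squares(resid, x0=start, method="trf",
                        bounds=(lo, hi), max_nfev=max_nfev)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return sol.x, rms, bool(sol.status > 0)


# --------------------------------------------------------------------------
# per-pixel ray lookup (Lookup Table R)
# --------------------------------------------------------------------------

@dataclass
class RayTable:
    """Per-pixel rays a + L*r for one camera's sensor grid.

    ``origins``/``directions`` have shape (ny, nx, 3) over the sampled
    pixel grid; ``valid`` marks pixels whose ray could be determined.
    The origin lies on the plane through the tank center perpendicular to
    the camera's principal axis.
    """

    camera: int
    pixel_x: np.ndarray
    pixel_y: np.ndarray
    origins: np.ndarray
    directions: np.ndarray
    valid: np.ndarray

    def ray_at(self, pixel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ray of the nearest sampled pixel."""
        ix = int(np.argmin(np.abs(self.pixel_x - pixel[0])))
        iy = int(np.argmin(np.abs(self.pixel_y - pixel[1])))
        if not self.valid[iy, ix]:
            raise ValueError("pixel ray marked invalid")
        return self.origins[iy, ix], self.directions[iy, ix]


def _solve_transverse(proj: RefractiveProjection, camera: int,
                      pixel: np.ndarray, depth: float) -> np.ndarray | None:
    """Lab point at a given depth (coordinate along the principal axis)
    projecting onto ``pixel``; None if outside the calibrated volume."""
    from scipy.optimize import least_squares

    ax, ay, az = proj.axis_maps[camera]
    lo, hi = proj.valid_domain

    def resid(t: np.ndarray) -> np.ndarray:
        X = np.zeros(3)
        X[ax], X[ay], X[az] = t[0], t[1], depth
        return proj.project(X, camera, check_domain=False) - pixel

    sol = least_squares(resid, x0=np.zeros(2), method="lm")
    if np.sqrt(np.mean(sol.fun**2)) > 1e-6:
        return None
    X = np.zeros(3)
    X[ax], X[ay], X[az] = sol.x[0], sol.x[1], depth
    if np.any(X < lo - 1e-9) or np.any(X > hi + 1e-9):
        return None
    return X


def ray_for_pixel(
    proj: RefractiveProjection,
    camera: int,
    pixel: np.ndarray,
    depths: tuple[float, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Fit the lab-frame ray projecting onto one pixel.

    Three probe points at fixed depths along the viewing direction
    (-30, 0, +30 mm, clipped to the calibrated volume) are inverted through
    the projection and a line fitted through them; pass ``rng`` to draw the
    probe depths at random instead. The returned origin lies on the central
    plane (depth 0).
    """
    pixel = np.asarray(pixel, dtype=float)
    az = proj.axis_maps[camera][2]
    lo, hi = proj.valid_domain
    if rng is not None:
        depths = tuple(rng.uniform(lo[az], hi[az], size=3))
    elif depths is None:
        span = min(30.0, 0.45 * (hi[az] - lo[az]))
        depths = (-span, 0.0, span)
    pts = []
    for d in depths:
        X = _solve_transverse(proj, camera, pixel, d)
        if X is None:
            return None
        pts.append(X)
    pts = np.array(pts)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    r = vt[0]
    if r[az] < 0:
        r = -r
    # shift origin onto the depth-0 plane
    a = centroid - (centroid[az] / r[az]) * r
    return a, r / np.linalg.norm(r)


def build_ray_table(
    proj: RefractiveProjection,
    sensor_shape: tuple[int, int],
    camera: int = 0,
    pixel_step: int = 16,
    seed: int | None = None,
) -> RayTable:
    """Tabulate per-pixel rays over a (possibly subsampled) sensor grid.

    ``sensor_shape`` is (height, width) in pixels; ``pixel_step`` controls
    the sampling stride. Pixels whose ray misses the calibrated tank
    volume are marked invalid.
    """
    ny, nx = sensor_shape
    xs = np.arange(0, nx, pixel_step, dtype=float)
    ys = np.arange(0, ny, pixel_step, dtype=float)
    rng = np.random.default_rng(seed) if seed is not None else None
    origins = np.zeros((len(ys), len(xs), 3))
    dirs = np.zeros_like(origins)
    valid = np.zeros((len(ys), len(xs)), dtype=bool)
    for iy, y in enumerate(ys):
        for ix, x in enumerate(xs):
            res = ray_for_pixel(proj, camera, np.array([x, y]), rng=rng)
            if res is None:
                continue
            origins[iy, ix], dirs[iy, ix] = res
            valid[iy, ix] = True
    return RayTable(camera, xs, ys, origins, dirs, valid)


# --------------------------------------------------------------------------
# cross-view larva matching
# --------------------------------------------------------------------------

def ray_ray_distance(a1: np.ndarray, r1: np.ndarray,
                     a2: np.ndarray, r2: np.ndarray) -> float:
    """Minimum distance between two lines (closed-form skew-line formula;
    parallel rays fall back to point-to-line distance)."""
    n = np.cross(r1, r2)
    nn = np.linalg.norm(n)
    d = a2 - a1
    if nn < 1e-12:
        return float(np.linalg.norm(np.cross(d, r1)) / np.linalg.norm(r1))
    return float(abs(d @ n) / nn)


def match_larvae_across_views(
    centroids: list[list[np.ndarray]],
    rays: list[list[tuple[np.ndarray, np.ndarray]]] | None = None,
    proj: RefractiveProjection | None = None,
    eps: float = 1.0,
) -> list[tuple[int, int, int]]:
    """Match larva centroids across three camera views by ray proximity.

    For every index triple (i, j, k) the score is
    ``delta = max`` of the three pairwise minimum ray-ray distances; triples
    with delta < eps are accepted greedily by ascending delta, each
    centroid used at most once. Pass precomputed ``rays`` (origin,
    direction per centroid per camera) or a projection to derive them.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if any(len(c) == 0 for c in centroids):
        return []
    if rays is None:
        if proj is None:
            raise ValueError("provide rays or proj")
        rays = [[ray_for_pixel(proj, cam, np.asarray(px, float))
                 for px in centroids[cam]] for cam in range(3)]
    scored = []
    for i, j, k in itertools.product(*[range(len(c)) for c in centroids]):
        trip = (rays[0][i], rays[1][j], rays[2][k])
        if any(t is None for t in trip):
            continue
        d12 = ray_ray_distance(*trip[0], *trip[1])
        d23 = ray_ray_distance(*trip[1], *trip[2])
        d13 = ray_ray_distance(*trip[0], *trip[2])
        delta = max(d12, d23, d13)
        if delta < eps:
            scored.append((delta, (i, j, k)))
    scored.sort(key=lambda t: (t[0], t[1]))
    used: list[set[int]] = [set(), set(), set()]
    matches = []
    for _, trip in scored:
        if any(trip[c] in used[c] for c in range(3)):
            continue
        matches.append(trip)
        for c in range(3):
            used[c].add(trip[c])
    return matches


# --------------------------------------------------------------------------
# calibration file I/O
# --------------------------------------------------------------------------

def save_calibration(path: str, proj: RefractiveProjection,
                     cams: list[PinholeCamera] | None = None) -> None:
    """Write calibration as JSON (per-camera K, M, cubic coefficients,
    valid domain; pixel convention tag)."""
    doc = {
        "pixel_convention": "0-based, pixel centers at integers, x right / y down",
        "valid_domain": proj.valid_domain.tolist(),
        "degree": proj.degree,
        "cameras": [],
    }
    for c in range(proj.n_cameras):
        entry = {
            "coeffs_x": proj.coeffs_x[c].tolist(),
            "coeffs_y": proj.coeffs_y[c].tolist(),
            "axis_map": list(proj.axis_maps[c]),
            "rms_residual_px": proj.rms_residual_px[c] if proj.rms_residual_px else None,
        }
        if cams is not None:
            entry["K"] = cams[c].intrinsic.tolist()
            entry["M"] = cams[c].extrinsic.tolist()
        doc["cameras"].append(entry)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_calibration(path: str) -> RefractiveProjection:
    with open(path) as fh:
        doc = json.load(fh)
    cams = doc["cameras"]
    return RefractiveProjection(
        coeffs_x=[np.array(c["coeffs_x"]) for c in cams],
        coeffs_y=[np.array(c["coeffs_y"]) for c in cams],
        axis_maps=[tuple(c["axis_map"]) for c in cams],
        valid_domain=np.array(doc["valid_domain"]),
        rms_residual_px=[c.get("rms_residual_px") for c in cams],
        degree=doc.get("degree", 3),
    )
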