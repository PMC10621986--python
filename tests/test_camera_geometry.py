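"""Camera models, refraction simulation, cubic calibration, rays, matching."""

import numpy as np
import pytest
from scipy.optimize import bisect

from zebra3d.camera import (PinholeCamera, build_ray_table,
                            fit_refractive_projection,
                            match_larvae_across_views, project_linear,
                            ray_for_pixel, ray_ray_distance,
                            reconstruct_dots_air, triangulate_point)
from zebra3d.optics import TankOptics, simulate_refraction


@pytest.fixture
def simple_cam():
    return PinholeCamera((1000.0, 1000.0), (320.0, 240.0), np.eye(3),
                         np.array([0.0, 0.0, 100.0]))


class TestProjectLinear:
    def test_principal_axis_maps_to_principal_point(self, simple_cam):
        px = project_linear(simple_cam, np.array([0.0, 0.0, 50.0]))
        assert np.allclose(px, (320.0, 240.0))

    def test_hand_evaluated_offset(self, simple_cam):
        # fx=1000, depth 100 -> 1 mm lateral = 10 px
        px = project_linear(simple_cam, np.array([1.0, 0.0, 0.0]))
        assert np.allclose(px, (330.0, 240.0))

    def test_camera_matrix_factors_as_extrinsic_times_intrinsic(self, rig):
        cam = rig[1]
        P = cam.extrinsic @ cam.intrinsic
        assert np.allclose(P, cam.matrix)
        X = np.array([3.0, -4.0, 5.0, 1.0])
        uvw = X @ P
        assert np.allclose(uvw[:2] / uvw[2], project_linear(cam, X[:3]))

    def test_point_behind_camera_raises(self, simple_cam):
        with pytest.raises(ValueError, match="behind"):
            project_linear(simple_cam, np.array([0.0, 0.0, -200.0]))

    def test_rotation_must_be_orthonormal(self):
        with pytest.raises(ValueError, match="orthonormal"):
            PinholeCamera((1000, 1000), (0, 0), np.eye(3) * 1.1, np.zeros(3))


class TestSimulateRefraction:
    def test_no_refraction_limit_equals_linear(self, rig):
        near_one = TankOptics(n_glass=1.0 + 1e-12, n_water=1.0 + 1e-12)
        P = np.array([5.0, -7.0, 3.0])
        for cam in rig:
            assert np.allclose(simulate_refraction(near_one, cam, P),
                               project_linear(cam, P), atol=1e-6)

    def test_normal_incidence_undeviated(self, optics, rig):
        # a point on the bottom camera's principal axis
        P = np.array([0.0, 0.0, 10.0])
        assert np.allclose(simulate_refraction(optics, rig[0], P),
                           project_linear(rig[0], P), atol=1e-9)

    def test_off_axis_matches_independent_bisection_solve(self, optics, rig):
        """Displacement agrees with a scalar Snell solve done by bisection
        on the water-side angle (independent of the shooting solver)."""
        cam = rig[0]
        P = np.array([8.0, 0.0, -5.0])
        half = optics.tank_side / 2
        d_w = P[2] + half
        d_g = optics.glass_thickness
        d_a = -half - d_g - cam.center[2]
        rho = P[0] - cam.center[0]

        def offset_mismatch(theta_w):
            s_w = np.sin(theta_w)
            s_g = optics.n_water * s_w / optics.n_glass
            s_a = optics.n_water * s_w / optics.n_air
            return (d_w * np.tan(theta_w)
                    + d_g * s_g / np.sqrt(1 - s_g**2)
                    + d_a * s_a / np.sqrt(1 - s_a**2)) - rho

        theta_w = bisect(offset_mismatch, 0.0, np.arcsin(1 / optics.n_water) - 1e-9,
                         xtol=1e-14)
        # exit point on the outer glass face, then the pinhole projection
        s_g = optics.n_water * np.sin(theta_w) / optics.n_glass
        t_wg = d_w * np.tan(theta_w) + d_g * s_g / np.sqrt(1 - s_g**2)
        exit_pt = np.array([P[0] - t_wg, 0.0, -half - d_g])
        expected = project_linear(cam, exit_pt)
        assert np.allclose(simulate_refraction(optics, cam, P), expected,
                           atol=1e-8)

    def test_point_outside_water_rejected(self, optics, rig):
        with pytest.raises(ValueError, match="outside"):
            simulate_refraction(optics, rig[0], np.array([0.0, 0.0, 60.0]))


class TestFitRefractiveProjection:
    def test_cubic_contains_affine_maps_exactly(self, rig, dot_obs):
        """A projection affine in the lab coordinates (telecentric limit)
        is inside the cubic model class: zero fit residual."""
        dots = dot_obs.dots3d
        pixels = []
        for cam in rig:
            ax, ay, az = cam.axis_map
            pixels.append(np.column_stack(
                [2.0 * dots[:, ax] + 0.1 * dots[:, az] + 5.0,
                 -1.5 * dots[:, ay] + 0.2 * dots[:, az]]))
        proj = fit_refractive_projection(dots, pixels, cams=rig)
        assert max(proj.rms_residual_px) < 1e-6

    def test_cubic_fits_unrefracted_pinhole_to_small_fraction_of_a_pixel(
            self, rig, dot_obs):
        # perspective division is rational in depth, so the cubic is an
        # approximation here; over the calibrated volume it is tight
        proj = fit_refractive_projection(dot_obs.dots3d, dot_obs.pixels_air,
                                         cams=rig)
        assert max(proj.rms_residual_px) < 0.05

    def test_separable_form_ignores_the_other_transverse_axis(self, proj):
        # camera 0 (view along z): pixel x depends on (x, z) only
        a = proj.project(np.array([3.0, -5.0, 2.0]), 0)
        b = proj.project(np.array([3.0, 9.0, 2.0]), 0)
        assert np.isclose(a[0], b[0])
        # and pixel y depends on (y, z) only
        c = proj.project(np.array([-8.0, -5.0, 2.0]), 0)
        assert np.isclose(a[1], c[1])

    def test_residual_decreases_with_degree(self, rig, dot_obs):
        rms = []
        for degree in (1, 2, 3):
            p = fit_refractive_projection(dot_obs.dots3d, dot_obs.pixels_water,
                                          cams=rig, degree=degree)
            rms.append(max(p.rms_residual_px))
        assert rms[0] > rms[1] > rms[2]

    def test_refraction_fit_beats_dense_grid_only_slightly(self, rig, optics,
                                                           proj):
        """Residual of the working fit stays within 2x of a denser-grid
        refit (the fit is not limited by the dot count)."""
        from zebra3d.optics import simulate_dot_grid

        dense = simulate_dot_grid(optics, rig, n_dots=13, pitch=2.5)
        refit = fit_refractive_projection(dense.dots3d, dense.pixels_water,
                                          cams=rig)
        assert max(proj.rms_residual_px) < 2 * max(refit.rms_residual_px) + 1e-3

    def test_degenerate_dots_raise_with_camera_named(self, rig):
        dots = np.column_stack([np.linspace(-5, 5, 12), np.zeros(12),
                                np.zeros(12)])
        pixels = [project_linear(cam, dots) for cam in rig]
        with pytest.raises(ValueError, match="camera 0"):
            fit_refractive_projection(dots, pixels, cams=rig)


class TestReconstructDotsAir:
    def test_noiseless_round_trip(self, rig):
        rng = np.random.default_rng(3)
        dots = rng.uniform(-10, 10, size=(12, 3))
        pixels = [project_linear(cam, dots) for cam in rig]
        rec, skipped = reconstruct_dots_air(pixels, rig)
        assert not skipped
        assert np.abs(rec - dots).max() < 1e-6

    def test_noisy_matches_grid_search_minimizer(self, rig):
        """With 0.5 px noise the least-squares solution agrees with a
        brute-force grid search of the same objective within 10%."""
        rng = np.random.default_rng(4)
        dots = np.array([[2.0, -3.0, 4.0], [-6.0, 5.0, -2.0]])
        pixels = [project_linear(cam, dots) + rng.normal(0, 0.5, (2, 2))
                  for cam in rig]
        rec, _ = reconstruct_dots_air(pixels, rig)

        def objective(X, n):
            return sum(np.sum((project_linear(cam, X) - pixels[c][n]) ** 2)
                       for c, cam in enumerate(rig))

        errors_ls, errors_grid = [], []
        for n, dot in enumerate(dots):
            # coarse-to-fine grid search around the true dot
            best, best_val = None, np.inf
            for span, steps in ((1.0, 21), (0.1, 21)):
                center = best if best is not None else dot
                axes = [np.linspace(c - span, c + span, steps) for c in center]
                for x in axes[0]:
                    for y in axes[1]:
                        for z in axes[2]:
                            v = objective(np.array([x, y, z]), n)
                            if v < best_val:
                                best, best_val = np.array([x, y, z]), v
            errors_ls.append(np.linalg.norm(rec[n] - dot))
            errors_grid.append(np.linalg.norm(best - dot))
        assert np.mean(errors_ls) <= np.mean(errors_grid) * 1.1

    def test_dots_seen_in_one_camera_are_skipped(self, rig):
        dots = np.array([[1.0, 2.0, 3.0]])
        pixels = [project_linear(cam, dots) for cam in rig]
        valid = np.array([[True, False, False]])
        rec, skipped = reconstruct_dots_air(pixels, rig, valid=valid)
        assert skipped == [0]
        assert np.all(np.isnan(rec[0]))


class TestTriangulatePoint:
    def test_round_trip(self, proj):
        X = np.array([4.0, -6.0, 8.0])
        pixels = proj.project_all(X)
        rec, rms, ok = triangulate_point(proj, pixels)
        assert ok and rms < 1e-6
        assert np.abs(rec - X).max() < 1e-6

    def test_two_views_suffice(self, proj):
        X = np.array([-3.0, 5.0, -7.0])
        pixels = proj.project_all(X)
        pixels[1] = None
        rec, _, _ = triangulate_point(proj, pixels)
        assert np.abs(rec - X).max() < 1e-5

    def test_single_view_rejected(self, proj):
        with pytest.raises(ValueError, match="2 cameras"):
            triangulate_point(proj, [np.zeros(2), None, None])

    def test_pixel_noise_error_matches_jacobian_sensitivity(self, proj):
        """+-0.5 px perturbations move the solution by an amount bounded
        by the sensitivity of the finite-difference projection Jacobian."""
        X = np.array([2.0, 3.0, -4.0])
        pixels = proj.project_all(X)
        # numerical Jacobian of the stacked projection (6 x 3)
        J = np.zeros((6, 3))
        eps = 1e-4
        for j in range(3):
            dX = np.zeros(3)
            dX[j] = eps
            up = np.concatenate(proj.project_all(X + dX))
            dn = np.concatenate(proj.project_all(X - dX))
            J[:, j] = (up - dn) / (2 * eps)
        # worst-case linearized displacement for a 0.5 px perturbation
        sigma_min = np.linalg.svd(J, compute_uv=False)[-1]
        bound = 0.5 * np.sqrt(6) / sigma_min
        rng = np.random.default_rng(5)
        for _ in range(10):
            noisy = [p + rng.uniform(-0.5, 0.5, 2) for p in pixels]
            rec, _, _ = triangulate_point(proj, noisy)
            assert np.linalg.norm(rec - X) <= bound * 1.2


class TestRayTable:
    def test_linear_camera_rays_pass_through_optical_center(self, rig, dot_obs):
        proj_air = fit_refractive_projection(dot_obs.dots3d, dot_obs.pixels_air,
                                             cams=rig)
        cam = rig[0]
        table = build_ray_table(proj_air, (488, 648), camera=0, pixel_step=200)
        C = cam.center
        assert table.valid.any()
        for iy in range(table.valid.shape[0]):
            for ix in range(table.valid.shape[1]):
                if not table.valid[iy, ix]:
                    continue
                a, r = table.origins[iy, ix], table.directions[iy, ix]
                d = np.linalg.norm(np.cross(C - a, r))
                # limited by the cubic approximation of the perspective
                # division (~0.02 px), not by the line fit itself
                assert d < 0.02

    def test_refracted_ray_close_to_ray_trace_oracle(self, proj, optics, rig):
        """Points ray-traced to the tabulated pixel lie within 10 um of the
        stored line, throughout the calibrated volume."""
        res = ray_for_pixel(proj, 0, np.array([250.0, 250.0]))
        assert res is not None
        a, r = res
        from scipy.optimize import least_squares

        cam = rig[0]
        for depth in (-12.0, -3.0, 6.0, 12.0):
            def resid(t, depth=depth):
                X = np.array([t[0], t[1], depth])
                return simulate_refraction(optics, cam, X) - np.array([250.0, 250.0])

            sol = least_squares(resid, x0=np.zeros(2), method="lm")
            X = np.array([sol.x[0], sol.x[1], depth])
            dist = np.linalg.norm(np.cross(X - a, r))
            assert dist < 0.010  # 10 um

    def test_three_collinear_probes_define_the_line(self, proj):
        pixel = np.array([300.0, 220.0])
        a, r = ray_for_pixel(proj, 1, pixel)
        # probe points at several depths project back onto the pixel
        for lam in (-10.0, 0.0, 10.0):
            X = a + lam * r
            assert np.abs(proj.project(X, 1, check_domain=False) - pixel).max() < 5e-3

    def test_rays_missing_the_tank_marked_invalid(self, proj):
        table = build_ray_table(proj, (488, 648), camera=0, pixel_step=640)
        # the corner pixel (0,0) looks outside the calibrated volume
        assert not table.valid[0, 0]


class TestMatchLarvae:
    def _rays(self, proj, points):
        out = []
        for cam in range(3):
            cam_list = []
            for X in points:
                px = proj.project(np.asarray(X), cam)
                cam_list.append(px)
            out.append(cam_list)
        return out

    def test_single_larva_noiseless(self, proj):
        cents = self._rays(proj, [np.array([2.0, -1.0, 3.0])])
        matches = match_larvae_across_views(cents, proj=proj, eps=1.0)
        assert matches == [(0, 0, 0)]

    def test_two_larvae_cross_pairings_rejected(self, proj):
        pts = [np.array([5.0, 5.0, 5.0]), np.array([-5.0, -5.0, -5.0])]
        cents = self._rays(proj, pts)
        matches = match_larvae_across_views(cents, proj=proj, eps=1.0)
        assert sorted(matches) == [(0, 0, 0), (1, 1, 1)]
        # verify delta for all 8 index triples with the closed-form
        # skew-line oracle: only the diagonal triples fall under eps
        rays = [[ray_for_pixel(proj, c, px) for px in cents[c]]
                for c in range(3)]
        import itertools

        for i, j, k in itertools.product(range(2), repeat=3):
            trip = (rays[0][i], rays[1][j], rays[2][k])
            delta = max(ray_ray_distance(*trip[0], *trip[1]),
                        ray_ray_distance(*trip[1], *trip[2]),
                        ray_ray_distance(*trip[0], *trip[2]))
            if i == j == k:
                assert delta < 1e-3
            else:
                assert delta > 1.0

    def test_permutation_invariance(self, proj):
        pts = [np.array([5.0, 5.0, 5.0]), np.array([-5.0, -5.0, -5.0])]
        cents = self._rays(proj, pts)
        flipped = [list(reversed(c)) for c in cents]
        m1 = match_larvae_across_views(cents, proj=proj, eps=1.0)
        m2 = match_larvae_across_views(flipped, proj=proj, eps=1.0)
        # same physical pairs after undoing the permutation
        undo = {0: 1, 1: 0}
        m2_undone = sorted(tuple(undo[i] for i in t) for t in m2)
        assert sorted(m1) == m2_undone

    def test_empty_camera_gives_empty_result(self, proj):
        assert match_larvae_across_views([[], [np.zeros(2)], [np.zeros(2)]],
                                         proj=proj) == []

    def test_parallel_rays_fall_back_to_point_distance(self):
        d = ray_ray_distance(np.zeros(3), np.array([1.0, 0, 0]),
                             np.array([0.0, 2.0, 0.0]), np.array([1.0, 0, 0]))
        assert np.isclose(d, 2.0)


class TestRoundTripInvariant:
    def test_triangulate_inverts_projection_across_the_volume(self, proj):
        rng = np.random.default_rng(11)
        for _ in range(5):
            X = rng.uniform(-12, 12, 3)
            rec, _, _ = triangulate_point(proj, proj.project_all(X))
            assert np.abs(rec - X).max() < 1e-6
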