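"""Preprocessing, tracking, and the two-round template optimization."""

import numpy as np
import pytest

from conftest import random_pose
from zebra3d.body import FishPose, pose_to_coordinates
from zebra3d.render import render_views
from zebra3d.synthesis import NoiseModel
from zebra3d.templatefit import (FitResult, coarse_optimize,
                                 compute_background, cost_function,
                                 estimate_length, fine_optimize,
                                 pattern_search, preprocess_frame,
                                 track_larva)


class TestComputeBackground:
    def test_constant_video_returns_constant(self):
        frames = np.full((12, 8, 8), 37.0)
        assert np.allclose(compute_background(frames), 37.0)

    def test_linear_interpolation_percentile(self):
        # pixel time series 0..99 -> 89.1 at the 90th percentile
        frames = np.arange(100.0)[:, None, None] * np.ones((1, 2, 2))
        assert np.allclose(compute_background(frames), 89.1)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="10 frames"):
            compute_background(np.zeros((5, 4, 4)))


class TestPreprocessFrame:
    def _scene(self, rng, with_fish=True):
        """Bright background with a dark larva-like blob (transmitted
        illumination: the fish absorbs light)."""
        bg = np.full((200, 220), 180.0) + rng.normal(0, 3, (200, 220))
        frame = bg.copy()
        if with_fish:
            yy, xx = np.mgrid[:200, :220]
            blob = 120 * np.exp(-(((yy - 90) / 6.0) ** 2
                                  + ((xx - 120) / 18.0) ** 2))
            frame -= blob
        return np.clip(bg, 0, 255), np.clip(frame, 0, 255)

    def test_blank_frame_has_no_detections(self):
        rng = np.random.default_rng(0)
        bg, _ = self._scene(rng, with_fish=False)
        dets = preprocess_frame(bg, bg)
        assert dets == []

    def test_detection_contains_the_blob(self):
        rng = np.random.default_rng(1)
        bg, frame = self._scene(rng)
        dets = preprocess_frame(frame, bg)
        assert len(dets) >= 1
        r0, c0, r1, c1 = dets[0].bbox
        assert r0 <= 90 <= r1 and c0 <= 120 <= c1
        assert np.allclose(dets[0].centroid, (120, 90), atol=3)
        assert dets[0].image.shape == (141, 141)

    def test_rendered_larva_keypoints_inside_crop(self, proj, fixed):
        pose = FishPose(theta0=0.5, dtheta=np.full(8, 0.15))
        trip, kp = render_views(pose, fixed, proj, return_keypoints=True)
        # embed view 0 into a dark-fish scene
        bg = np.full((300, 300), 200.0)
        frame = bg.copy()
        frame[60:201, 60:201] -= trip.images[0] * 0.6
        dets = preprocess_frame(np.clip(frame, 0, 255), bg)
        assert len(dets) == 1
        kp_frame = kp[0] + np.array([60, 60])  # keypoints in scene coords
        kp_crop = kp_frame - dets[0].crop_origin
        assert kp_crop.min() >= 0 and kp_crop.max() <= 141

    def test_mismatched_background_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            preprocess_frame(np.zeros((4, 4)), np.zeros((5, 5)))


class TestTrackLarva:
    def test_single_larva_continuous_track(self, proj):
        path = [np.array([i * 0.5 - 2.0, 1.0, -1.0]) for i in range(8)]
        frames = [[[proj.project(X, c)] for c in range(3)] for X in path]
        track = track_larva(frames, proj)
        assert all(t["status"] == "ok" for t in track)
        for t, X in zip(track, path):
            assert np.linalg.norm(t["position"] - X) < 1e-4

    def test_two_crossing_larvae_keep_identity(self, proj):
        # larva A moves +x at z=+3, larva B moves -x at z=-3; their bottom
        # camera projections cross mid-way
        pa = [np.array([-4.0 + i, 0.0, 3.0]) for i in range(9)]
        pb = [np.array([4.0 - i, 0.0, -3.0]) for i in range(9)]
        frames = []
        for A, B in zip(pa, pb):
            frames.append([[proj.project(A, c), proj.project(B, c)]
                           for c in range(3)])
        track = track_larva(frames, proj)
        for t, A in zip(track, pa):
            assert t["status"] == "ok"
            assert np.linalg.norm(t["position"] - A) < 0.2

    def test_track_terminates_after_gap(self, proj):
        X = np.array([1.0, 1.0, 1.0])
        good = [[proj.project(X, c)] for c in range(3)]
        empty = [[], [], []]
        frames = [good] + [empty] * 7 + [good]
        track = track_larva(frames, proj, max_gap=3)
        assert track[0]["status"] == "ok"
        assert track[4]["status"] == "lost"
        assert track[-1]["status"] == "terminated"


class TestCostFunction:
    def test_identity_is_zero(self, proj, fixed, bent_pose):
        trip = render_views(bent_pose, fixed, proj, mode="accurate",
                            voxel_pitch=0.03)
        c, per = cost_function(bent_pose, trip.images.astype(float), proj,
                               trip.crop_origins, fixed, voxel_pitch=0.03)
        assert c == 0.0 and np.all(per == 0.0)

    def test_single_pixel_difference_costs_squared_value(self, proj, fixed,
                                                         bent_pose):
        trip = render_views(bent_pose, fixed, proj, mode="accurate",
                            voxel_pitch=0.03)
        images = trip.images.astype(float)
        images[1, 70, 70] += 10.0
        c, per = cost_function(bent_pose, images, proj, trip.crop_origins,
                               fixed, voxel_pitch=0.03)
        assert np.isclose(c, 100.0)
        assert np.isclose(per[1], 100.0) and per[0] == 0.0 and per[2] == 0.0

    def test_three_views_summed(self, proj, fixed, bent_pose):
        trip = render_views(bent_pose, fixed, proj, mode="accurate",
                            voxel_pitch=0.03)
        images = trip.images.astype(float)
        images[:, 60, 60] += 2.0
        c, per = cost_function(bent_pose, images, proj, trip.crop_origins,
                               fixed, voxel_pitch=0.03)
        assert np.isclose(c, per.sum()) and len(per) == 3

    def test_shape_mismatch_raises(self, proj, fixed, bent_pose):
        with pytest.raises(ValueError, match="mismatch"):
            cost_function(bent_pose, np.zeros((3, 100, 100)), proj,
                          np.zeros((3, 2), dtype=int), fixed)


class TestPatternSearch:
    def test_quadratic_bowl_recovery(self):
        target = np.array([0.3, -1.2, 2.0])

        def f(x):
            return float(np.sum((x - target) ** 2))

        x, fx, _, _ = pattern_search(f, np.zeros(3), np.ones(3), mesh0=1.0,
                                     mesh_tol=1e-6, max_evals=5000)
        assert np.abs(x - target).max() < 1e-4

    def test_accepted_cost_sequence_non_increasing(self):
        history = []

        def f(x):
            v = float(np.sum((x - 1.0) ** 2))
            return v

        accepted = []
        # wrap to record accepted values: pattern_search guarantees the
        # running best is monotone; verify via repeated snapshots
        x0 = np.full(4, 5.0)
        prev = f(x0)
        for evals in (10, 50, 200, 1000):
            _, fx, _, _ = pattern_search(f, x0, np.ones(4), mesh0=1.0,
                                         max_evals=evals)
            accepted.append(fx)
        assert all(b <= a + 1e-12 for a, b in zip(accepted, accepted[1:]))

    def test_free_mask_restricts_motion(self):
        def f(x):
            return float(np.sum(x**2))

        free = np.array([True, False, True])
        x, _, _, _ = pattern_search(f, np.array([1.0, 1.0, 1.0]), np.ones(3),
                                    free=free, mesh0=1.0, max_evals=500)
        assert np.isclose(x[1], 1.0)
        assert abs(x[0]) < 1e-3 and abs(x[2]) < 1e-3


@pytest.fixture(scope="module")
def fit_scene(proj, lookup_table):
    """One rendered noisy frame with known pose and a perturbed init."""
    from zebra3d.body import FixedBodyParameters

    fixed = FixedBodyParameters()
    rng = np.random.default_rng(7)
    pose = random_pose(rng)
    trip = render_views(pose, fixed, proj, mode="accurate", voxel_pitch=0.03)
    noise = NoiseModel()
    unit = trip.images.astype(float) / 255.0
    noisy = np.stack([noise.apply(unit[c], c, rng) for c in range(3)])
    images = np.round(noisy / noisy.reshape(3, -1).max(axis=1)[:, None, None]
                      * 255.0)
    v = pose.to_vector()
    v[:3] += rng.uniform(-0.5, 0.5, 3)
    pert = np.deg2rad(5) * rng.choice([-1.0, 1.0], 18)
    v[3] += pert[0]
    v[4:12] += pert[1:9]
    v[12] += pert[9]
    v[13:21] += pert[10:18]
    v[21] += pert[17]
    init = FishPose.from_vector(v, length=pose.length)
    return pose, trip, images, init, fixed


class TestCoarseOptimize:
    def test_ground_truth_init_is_a_fixed_point(self, proj, fixed,
                                                lookup_table, bent_pose):
        trip = render_views(bent_pose, fixed, proj, mode="fast",
                            table=lookup_table)
        res = coarse_optimize(trip.images.astype(float), proj,
                              trip.crop_origins, init=bent_pose,
                              fixed=fixed, table=lookup_table, max_evals=300)
        assert res.cost <= 1e-9
        assert np.abs(res.pose.to_vector() - bent_pose.to_vector()).max() < 1e-9

    def test_perturbed_init_recovers_backbone_within_2px(self, fit_scene,
                                                         proj, lookup_table):
        pose, trip, images, init, fixed = fit_scene
        res = coarse_optimize(images, proj, trip.crop_origins, init=init,
                              fixed=fixed, table=lookup_table, max_evals=1200)
        kp_true = np.stack([proj.project(
            pose_to_coordinates(pose, fixed).backbone, c) for c in range(3)])
        kp_fit = np.stack([proj.project(
            pose_to_coordinates(res.pose, fixed).backbone, c)
            for c in range(3)])
        rmse = np.sqrt(np.mean((kp_true - kp_fit) ** 2))
        assert rmse < 2.0

    def test_first_frame_needs_centroid(self, proj, fixed):
        with pytest.raises(ValueError, match="centroid"):
            coarse_optimize(np.zeros((3, 141, 141)), proj,
                            np.zeros((3, 2), dtype=int), init=None,
                            fixed=fixed)


class TestFineOptimize:
    def test_fine_reduces_cost_from_coarse(self, fit_scene, proj,
                                           lookup_table):
        pose, trip, images, init, fixed = fit_scene
        coarse = coarse_optimize(images, proj, trip.crop_origins, init=init,
                                 fixed=fixed, table=lookup_table,
                                 max_evals=900)
        fine = fine_optimize(images, proj, trip.crop_origins, coarse,
                             fixed=fixed, voxel_pitch=0.05,
                             max_evals_phase=350)
        assert fine.round == "fine"
        # the fine cost is measured with the accurate renderer; recompute
        # the coarse pose's accurate cost for a like-for-like comparison
        coarse_acc, _ = cost_function(coarse.pose, images, proj,
                                      trip.crop_origins, fixed,
                                      voxel_pitch=0.05)
        assert fine.cost <= coarse_acc
        b_true = pose_to_coordinates(pose, fixed).backbone
        b_fit = pose_to_coordinates(fine.pose, fixed).backbone
        assert np.linalg.norm(b_fit - b_true, axis=1).mean() < 0.05

    def test_init_at_truth_keeps_cost(self, proj, fixed, bent_pose):
        trip = render_views(bent_pose, fixed, proj, mode="accurate",
                            voxel_pitch=0.05)
        images = trip.images.astype(float)
        start = FitResult(bent_pose, 0.0, np.zeros(3), "coarse", 0)
        fine = fine_optimize(images, proj, trip.crop_origins, start,
                             fixed=fixed, voxel_pitch=0.05,
                             max_evals_phase=100)
        # zero cost cannot be improved; the coarse result is returned
        assert fine.cost == 0.0 or fine.flag == "fine-no-improvement"


class TestEstimateLength:
    def test_straight_larva_length_recovered_within_5_percent(self, proj,
                                                              lookup_table,
                                                              fixed):
        true_L = 4.2
        pose = FishPose(theta0=0.8, phi0=0.1, length=true_L)
        trip = render_views(pose, fixed, proj, mode="accurate",
                            voxel_pitch=0.03)
        dets = []
        from zebra3d.templatefit import PreprocessedFrame

        for c in range(3):
            img = trip.images[c]
            mask = img > 20
            ys, xs = np.nonzero(mask)
            cx, cy = xs.mean(), ys.mean()
            origin = trip.crop_origins[c]
            dets.append(PreprocessedFrame(
                image=img, bbox=(0, 0, 141, 141), mask=mask,
                centroid=np.array([cx, cy]) + origin,
                crop_origin=np.asarray(origin)))
        frame_sets = [dets] * 3
        with pytest.warns(UserWarning, match="fewer than 10"):
            L, per_frame = estimate_length(frame_sets, proj, fixed,
                                           table=lookup_table)
        assert abs(L - true_L) / true_L < 0.05
        # identical frames give identical per-frame estimates
        assert np.allclose(per_frame, per_frame[0])
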