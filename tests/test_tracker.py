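"""Kalman prediction, gated Hungarian association, and track lifecycle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import brute_force_assignment
from pearcount.errors import SequencingError, ValidationError
from pearcount.io import BBox, Detection, group_by_frame
from pearcount.tracker import (
    INFEASIBLE,
    KalmanFilter,
    TrackerConfig,
    TrackStatus,
    associate,
    hungarian_assign,
    init_track,
    predict,
    run_tracker,
    step,
    write_tracks,
)


def _det(x, y, w, h, conf=1.0, frame=0, emb=None):
    return Detection(frame, BBox(x, y, w, h), conf, emb)


class TestInitTrack:
    def test_mean_from_centroid_aspect_height(self):
        t = init_track(_det(10, 10, 4, 8), frame=0, next_id=1)
        assert np.allclose(t.mean, [12, 14, 0.5, 8, 0, 0, 0, 0])
        assert t.status is TrackStatus.TENTATIVE and t.hits == 1

    def test_two_inits_get_distinct_consecutive_ids(self):
        tracks = []
        step(tracks, [_det(0, 0, 5, 5), _det(50, 50, 5, 5)], 0)
        assert sorted(t.id for t in tracks) == [1, 2]

    def test_init_with_embedding_seeds_gallery(self):
        emb = np.zeros(8)
        emb[0] = 1.0
        t = init_track(_det(0, 0, 5, 5, emb=emb), 0, 1)
        assert len(t.gallery) == 1


class TestKalman:
    def test_zero_velocity_keeps_position(self):
        t = init_track(_det(10, 10, 4, 8), 0, 1)
        predict(t)
        assert t.mean[0] == pytest.approx(12)

    def test_constant_velocity_advances_position(self):
        t = init_track(_det(8, 10, 4, 8), 0, 1)
        t.mean[4] = 2.0  # vx
        predict(t)
        assert t.mean[0] == pytest.approx(12)

    def test_covariance_inflates_under_predict(self):
        t = init_track(_det(10, 10, 4, 8), 0, 1)
        before = np.diag(t.cov).copy()
        predict(t)
        after = np.diag(t.cov)
        assert np.all(after > before)

    def test_matches_textbook_recursion(self):
        # independent recursion: explicit F/H/Q/R matrices and the standard
        # K = P Hᵀ (H P Hᵀ + R)⁻¹ update, no Cholesky shortcuts
        kf = KalmanFilter()
        z0 = np.array([50.0, 60.0, 0.9, 20.0])
        mean, cov = kf.initiate(z0)
        F = np.eye(8)
        F[:4, 4:] = np.eye(4)
        H = np.eye(4, 8)

        ref_mean, ref_cov = mean.copy(), cov.copy()
        z1 = np.array([52.0, 63.0, 0.9, 20.5])

        mean, cov = kf.predict(mean, cov)
        h = ref_mean[3]
        q = np.diag(
            np.array([h / 20, h / 20, 1e-2, h / 20, h / 160, h / 160, 1e-5, h / 160]) ** 2
        )
        ref_mean = F @ ref_mean
        ref_cov = F @ ref_cov @ F.T + q
        assert np.allclose(mean, ref_mean)
        assert np.allclose(cov, ref_cov)

        mean, cov = kf.update(mean, cov, z1)
        r = np.diag(np.array([ref_mean[3] / 20, ref_mean[3] / 20, 1e-1, ref_mean[3] / 20]) ** 2)
        S = H @ ref_cov @ H.T + r
        K = ref_cov @ H.T @ np.linalg.inv(S)
        ref_mean = ref_mean + K @ (z1 - H @ ref_mean)
        ref_cov = ref_cov - K @ S @ K.T
        assert np.allclose(mean, ref_mean)
        assert np.allclose(cov, ref_cov, atol=1e-8)

    def test_exact_linear_motion_recovered_after_two_updates(self):
        # with (near) zero process and measurement noise the filter locks on
        # to a constant-velocity target after two corrections; the initial
        # velocity uncertainty comes from the default prior (a zero prior
        # variance would pin the velocity at zero forever)
        kf = KalmanFilter(1e-9, 1e-9)
        mean, cov = KalmanFilter().initiate(np.array([100.0, 50.0, 1.0, 10.0]))
        for k in range(1, 4):
            mean, cov = kf.predict(mean, cov)
            mean, cov = kf.update(mean, cov, np.array([100.0 + 3 * k, 50.0 + 2 * k, 1.0, 10.0]))
        mean, cov = kf.predict(mean, cov)
        assert mean[0] == pytest.approx(112.0, abs=1e-6)
        assert mean[1] == pytest.approx(58.0, abs=1e-6)


class TestHungarian:
    def test_single_entry(self):
        matches, ur, uc = hungarian_assign(np.array([[0.1]]))
        assert matches == [(0, 0)] and ur == [] and uc == []

    def test_diagonal_preferred(self):
        matches, _, _ = hungarian_assign(np.array([[0.1, 0.9], [0.9, 0.1]]))
        assert matches == [(0, 0), (1, 1)]

    def test_forbidden_pairs_never_returned(self):
        cost = np.array([[0.1, INFEASIBLE], [INFEASIBLE, INFEASIBLE]])
        matches, ur, uc = hungarian_assign(cost)
        assert matches == [(0, 0)] and ur == [1] and uc == [1]

    def test_rectangular_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m, n = rng.integers(1, 5, size=2)
            cost = rng.uniform(0, 1, size=(m, n))
            cost[rng.uniform(size=(m, n)) < 0.25] = INFEASIBLE
            matches, _, _ = hungarian_assign(cost)
            k_ref, c_ref = brute_force_assignment(cost, INFEASIBLE)
            assert len(matches) == k_ref
            assert sum(cost[r, c] for r, c in matches) == pytest.approx(c_ref)

    @given(
        hnp.arrays(
            np.float64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=4),
            elements=st.floats(0, 10, allow_nan=False),
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_total_cost_is_global_minimum(self, cost):
        matches, _, _ = hungarian_assign(cost, infeasible_cost=11.0)
        k_ref, c_ref = brute_force_assignment(cost, 11.0)
        assert len(matches) == k_ref
        assert sum(cost[r, c] for r, c in matches) == pytest.approx(c_ref)


class TestAssociate:
    def test_perfect_overlap_zero_cost_match(self):
        cfg = TrackerConfig(cost_mode="iou")
        t = init_track(_det(10, 10, 10, 20), 0, 1)
        predict(t, cfg)
        matches, ut, ud = associate([t], [_det(10, 10, 10, 20)], cfg)
        assert matches == [(0, 0)] and not ut and not ud

    def test_detection_beyond_gate_unmatched(self):
        cfg = TrackerConfig(cost_mode="iou")
        t = init_track(_det(10, 10, 10, 20), 0, 1)
        predict(t, cfg)
        matches, ut, ud = associate([t], [_det(500, 500, 10, 20)], cfg)
        assert not matches and ut == [0] and ud == [0]

    def test_crossed_structure_matches_brute_force_minimum(self):
        cfg = TrackerConfig(cost_mode="iou")
        tracks = [init_track(_det(0, 0, 10, 10), 0, 1), init_track(_det(8, 0, 10, 10), 0, 2)]
        for t in tracks:
            predict(t, cfg)
        dets = [_det(7, 0, 10, 10), _det(1, 0, 10, 10)]
        matches, _, _ = associate(tracks, dets, cfg)
        from pearcount.det_metrics import iou

        cost = np.array(
            [[1 - iou(t.predicted_box(), d.box) for d in dets] for t in tracks]
        )
        _, c_ref = brute_force_assignment(np.where(cost > cfg.max_iou_cost, INFEASIBLE, cost), INFEASIBLE)
        assert sum(cost[r, c] for r, c in matches) == pytest.approx(c_ref)


class TestLifecycle:
    def test_clean_stream_confirms_single_track(self):
        stream = group_by_frame([_det(10, 10 + 2 * f, 10, 20, frame=f) for f in range(5)])
        tracks = run_tracker(stream, TrackerConfig(cost_mode="iou"))
        confirmed = [t for t in tracks if t.was_confirmed]
        assert len(tracks) == 1 and len(confirmed) == 1
        assert sorted(confirmed[0].history) == list(range(5))

    def test_long_gap_deletes_and_respawns_new_id(self):
        cfg = TrackerConfig(cost_mode="iou", max_age=3)
        dets = [_det(10, 10, 10, 20, frame=f) for f in range(5)]
        dets += [_det(10, 10, 10, 20, frame=f) for f in range(10, 15)]
        tracks = run_tracker(group_by_frame(dets), cfg)
        confirmed = [t for t in tracks if t.was_confirmed]
        assert len(confirmed) == 2
        assert confirmed[0].id != confirmed[1].id
        assert confirmed[0].status is TrackStatus.DELETED

    def test_tentative_missed_once_is_deleted(self):
        cfg = TrackerConfig(cost_mode="iou")
        tracks = []
        step(tracks, [_det(10, 10, 10, 20)], 0, cfg)
        step(tracks, [], 1, cfg)
        assert tracks[0].status is TrackStatus.DELETED
        assert not tracks[0].was_confirmed

    def test_out_of_order_frame_rejected(self):
        tracks = []
        step(tracks, [_det(10, 10, 10, 20)], 5)
        with pytest.raises(SequencingError):
            step(tracks, [], 5)

    def test_parallel_objects_keep_identities(self):
        # two well-separated constant-velocity objects, 50 noise-free frames:
        # exactly two tracks and no identity swaps
        cfg = TrackerConfig(cost_mode="iou")
        dets = []
        for f in range(50):
            dets.append(_det(10, 5 + 4 * f, 12, 16, frame=f))
            dets.append(_det(150, 5 + 4 * f, 12, 16, frame=f))
        tracks = run_tracker(group_by_frame(dets), cfg)
        assert len(tracks) == 2
        for t in tracks:
            xs = {round(box.x) for box, _ in t.history.values()}
            assert len(xs) == 1  # each track stays on one object's column

    def test_predict_deleted_track_rejected(self):
        t = init_track(_det(0, 0, 5, 5), 0, 1)
        t.status = TrackStatus.DELETED
        with pytest.raises(ValidationError):
            predict(t)


class TestRunTracker:
    def test_empty_stream(self):
        assert run_tracker({}) == []

    def test_deterministic_output(self, tmp_path, small_scene_cfg):
        from pearcount.simulator import CorruptionConfig, corrupt_detections, generate_scene

        scene, ideal = generate_scene(small_scene_cfg)
        stream = corrupt_detections(ideal, scene, CorruptionConfig(seed=4), small_scene_cfg)
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_tracks(run_tracker(stream), p1)
        write_tracks(run_tracker(stream), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_online_prefix_property(self, small_scene_cfg):
        # the state after frame t never depends on later frames: truncating
        # the stream reproduces every track history up to t byte-identically
        from pearcount.simulator import CorruptionConfig, corrupt_detections, generate_scene

        scene, ideal = generate_scene(small_scene_cfg)
        stream = corrupt_detections(ideal, scene, CorruptionConfig(seed=4), small_scene_cfg)
        full = run_tracker(stream)
        t_cut = max(stream) // 2
        truncated = run_tracker({f: d for f, d in stream.items() if f <= t_cut})
        trunc_by_id = {t.id: t for t in truncated}
        for t in full:
            if t.first_frame > t_cut:
                continue
            prefix = {f: v for f, v in t.history.items() if f <= t_cut}
            assert repr(prefix) == repr(trunc_by_id[t.id].history)

    def test_ids_never_reused(self, small_scene_cfg):
        from pearcount.simulator import CorruptionConfig, corrupt_detections, generate_scene

        scene, ideal = generate_scene(small_scene_cfg)
        stream = corrupt_detections(ideal, scene, CorruptionConfig(p_miss=0.4, seed=9), small_scene_cfg)
        tracks = run_tracker(stream)
        ids = [t.id for t in tracks]
        assert len(ids) == len(set(ids))
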