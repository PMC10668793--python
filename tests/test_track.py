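"""Kalman filter, Hungarian association and track lifecycle."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from shssd.head import BoxSet
from shssd.track import (GATE_CHI2_99_DF4, KalmanFilter, KalmanState, Tracker,
                         TrackStatus, associate, histogram_embedding)


def textbook_kalman_step(mean, cov, F, Q, H, R, z=None):
    """Plain matrix-formula predict(/update) reference."""
    mean = F @ mean
    cov = F @ cov @ F.T + Q
    if z is not None:
        S = H @ cov @ H.T + R
        K = cov @ H.T @ np.linalg.inv(S)
        mean = mean + K @ (z - H @ mean)
        cov = (np.eye(len(mean)) - K @ H) @ cov
    return mean, cov


class TestKalman:
    def test_linear_motion_prediction(self):
        kf = KalmanFilter()
        s = kf.initiate([10.0, 20.0, 1.0, 30.0])
        s.mean[4] = 2.0                       # vx
        s2 = kf.predict(s)
        assert s2.mean[0] == 12.0

    def test_process_noise_grows_covariance(self):
        kf = KalmanFilter()
        s = kf.initiate([10.0, 20.0, 1.0, 30.0])
        s2 = kf.predict(s)
        assert s2.mean[0] == 10.0             # zero velocity: position fixed
        assert np.trace(s2.cov) > np.trace(s.cov)

    def test_constant_velocity_tracked_exactly(self):
        """After a burn-in update, pure predicts follow the closed-form
        linear recursion."""
        kf = KalmanFilter()
        s = kf.initiate([0.0, 0.0, 1.0, 30.0])
        s.mean[4:6] = [3.0, 4.0]
        for i in range(1, 6):
            s = kf.predict(s)
            assert np.allclose(s.mean[:2], [3.0 * i, 4.0 * i])

    def test_update_with_predicted_mean_is_noop(self):
        kf = KalmanFilter()
        s = kf.initiate([5.0, 5.0, 1.0, 20.0])
        s = kf.predict(s)
        s2 = kf.update(s, s.mean[:4].copy())
        assert np.allclose(s2.mean, s.mean, atol=1e-9)

    def test_repeated_measurements_converge_and_trace_shrinks(self):
        kf = KalmanFilter()
        s = kf.initiate([0.0, 0.0, 1.0, 20.0])
        z = np.array([10.0, -4.0, 1.1, 22.0])
        for _ in range(20):
            s_pred = kf.predict(s)
            projected_trace = np.trace(kf.project(s_pred)[1])
            s = kf.update(s_pred, z)
            # every update strictly reduces the projected uncertainty
            assert np.trace(kf.project(s)[1]) < projected_trace
        assert np.linalg.norm(s.mean[:4] - z) < 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_implementation(self, seed):
        """Predict/update equals the inverse-based textbook formulas."""
        rng = np.random.default_rng(seed)
        kf = KalmanFilter()
        z0 = np.array([rng.uniform(0, 500), rng.uniform(0, 500),
                       rng.uniform(0.5, 2), rng.uniform(10, 80)])
        s = kf.initiate(z0)
        mean, cov = s.mean.copy(), s.cov.copy()
        for _ in range(20):
            z = z0 + rng.normal(0, 1, 4) * [1, 1, 0.01, 1]
            # noise schedule: Q from pre-predict height, R from predicted one
            Q = kf._process_noise(max(mean[3], 1e-3))
            mean_pred = kf.F @ mean
            R = kf._measurement_noise(max(mean_pred[3], 1e-3))
            s = kf.update(kf.predict(s), z)
            mean, cov = textbook_kalman_step(mean, cov, kf.F, Q, kf.H, R, z)
            assert np.allclose(s.mean, mean, atol=1e-8)
            assert np.allclose(s.cov, cov, atol=1e-8)


class TestAssociation:
    def test_no_tracks_all_dets_unmatched(self):
        dets = BoxSet([[0, 0, 10, 10]], [0.9], [0])
        m, ut, ud = associate([], dets, KalmanFilter())
        assert m == [] and ud == [0]

    def test_two_by_two_cost_resolved_optimally(self):
        """Cost [[1,2],[2,1]] pairs the diagonal (total 2, not 4)."""
        cost = np.array([[1.0, 2.0], [2.0, 1.0]])
        rows, cols = linear_sum_assignment(cost)
        assert cost[rows, cols].sum() == 2.0
        assert list(cols) == [0, 1]

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_hungarian_equals_permutation_minimum(self, n, rng):
        for _ in range(20):
            cost = rng.uniform(0, 10, (n, n))
            rows, cols = linear_sum_assignment(cost)
            best = min(sum(cost[i, p[i]] for i in range(n))
                       for p in itertools.permutations(range(n)))
            assert abs(cost[rows, cols].sum() - best) < 1e-9

    def test_detection_outside_gate_never_matches(self):
        kf = KalmanFilter()
        from shssd.track import Track

        s = kf.predict(kf.initiate([50.0, 50.0, 1.0, 20.0]))
        t = Track(1, s, status=TrackStatus.CONFIRMED, time_since_update=1)
        far = BoxSet([[500, 500, 520, 520]], [0.99], [0])
        maha = kf.gating_distance(s, np.array([[510, 510, 1.0, 20.0]]))
        assert maha[0] > GATE_CHI2_99_DF4
        m, ut, ud = associate([t], far, kf)
        assert m == [] and ud == [0]


def synthetic_streams(n_tracks, n_frames, speed=5.0, x_gap=150.0):
    """Clean detections of parallel non-crossing constant-velocity targets."""
    streams = []
    for f in range(n_frames):
        boxes = [[i * x_gap + 10, f * speed, i * x_gap + 50, f * speed + 40]
                 for i in range(n_tracks)]
        streams.append(BoxSet(boxes, np.ones(n_tracks),
                              np.zeros(n_tracks, dtype=np.int64)))
    return streams


class TestTracker:
    def test_three_clean_targets_three_ids(self):
        tracker = Tracker()
        seen = set()
        for f, dets in enumerate(synthetic_streams(3, 50)):
            for t in tracker.step(dets, f):
                seen.add(t.id)
        assert len(seen) == 3

    def test_id_preserved_across_one_frame_dropout(self):
        tracker = Tracker(max_age=30)
        streams = synthetic_streams(1, 30)
        ids = []
        for f, dets in enumerate(streams):
            if f == 15:
                dets = BoxSet.empty()
            ids += [t.id for t in tracker.step(dets, f)]
        assert set(ids) == {1}

    def test_empty_video_zero_tracks(self):
        tracker = Tracker()
        for f in range(10):
            assert tracker.step(BoxSet.empty(), f) == []
        assert tracker.tracks == []

    def test_ids_never_reused(self):
        """Tracks that die free their id permanently."""
        tracker = Tracker(max_age=2, n_init=1)
        issued = set()
        rng = np.random.default_rng(0)
        for f in range(60):
            if (f // 10) % 2 == 0:
                x = rng.uniform(0, 400)
                dets = BoxSet([[x, 100, x + 40, 140]], [0.9], [0])
            else:
                dets = BoxSet.empty()
            for t in tracker.step(dets, f):
                issued.add((t.id, f // 20))
        ids = [i for i, _ in issued]
        assert len(set(ids)) >= 2               # several tracks were born
        # a given id is only ever one physical track: ids strictly increase
        assert max(ids) == tracker._next_id - 1

    def test_confirmation_requires_n_init_hits(self):
        tracker = Tracker(n_init=3)
        streams = synthetic_streams(1, 5)
        confirmed_at = None
        for f, dets in enumerate(streams):
            if tracker.step(dets, f) and confirmed_at is None:
                confirmed_at = f
        assert confirmed_at == 2                # third consecutive hit


def test_histogram_embedding_discriminates_colors(rng):
    frame = np.zeros((100, 200, 3), dtype=np.uint8)
    frame[:, :100] = [200, 40, 40]
    frame[:, 100:] = [40, 40, 200]
    red = histogram_embedding(frame, np.array([10, 10, 80, 80]))
    red2 = histogram_embedding(frame, np.array([20, 20, 90, 90]))
    blue = histogram_embedding(frame, np.array([110, 10, 190, 80]))
    assert red @ red2 > 0.99
    assert red @ blue < 0.1
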