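"""Exclusion criteria, fixation detection, and view-angle geometry."""

import numpy as np
import pytest

from vantage.preprocess import (
    ExclusionConfig, UndefinedAngleError, UndefinedRateError,
    apply_exclusions, detect_fixations, mean_record_rate, view_angle,
    view_angles, wrap_angle,
)
from vantage.sessions import Cohort
from vantage.simulate import make_exclusion_cohort

from conftest import make_session


class TestMeanRecordRate:
    @pytest.mark.parametrize("n_frames, span_ms, expected", [
        (900, 100_000, 9.0),     # below the 10 records/s criterion
        (6000, 100_000, 60.0),   # the logging-rate cap
        (2, 1000, 2.0),
    ])
    def test_rate_arithmetic(self, n_frames, span_ms, expected):
        t = np.linspace(0, span_ms, n_frames).astype(np.int64)
        s = make_session(t, np.tile([0, 1, 5.0], (n_frames, 1)))
        assert mean_record_rate(s) == pytest.approx(expected)

    def test_single_frame_rate_undefined(self):
        s = make_session([0], [[0, 1, 5]])
        with pytest.raises(UndefinedRateError):
            mean_record_rate(s)


class TestViewAngle:
    def test_front_is_zero(self):
        assert view_angle([0, 0, 5], [0, 0, 0]) == pytest.approx(0.0)

    def test_rear_is_pi_and_elevation_ignored(self):
        assert view_angle([0, 1, -5], [0, 0, 0]) == pytest.approx(np.pi)

    def test_matches_atan2_oracle(self, rng):
        tgt = rng.normal(size=3)
        for _ in range(200):
            cam = tgt + rng.normal(size=3)
            d = cam - tgt
            if d[0] == 0 and d[2] == 0:
                continue
            expected = np.arctan2(d[0], d[2])
            if expected == -np.pi:
                expected = np.pi
            assert view_angle(cam, tgt) == pytest.approx(expected, abs=1e-12)

    def test_rotation_equivariance(self, rng):
        # rotating the camera about the target's vertical axis adds the
        # rotation angle to theta (mod 2 pi)
        tgt = np.array([1.0, 2.0, 3.0])
        for _ in range(50):
            v = rng.normal(size=3)
            phi = rng.uniform(-np.pi, np.pi)
            c, s = np.cos(phi), np.sin(phi)
            R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
            base = view_angle(tgt + v, tgt)
            rotated = view_angle(tgt + R @ v, tgt)
            assert wrap_angle(rotated - base - phi) == pytest.approx(0.0, abs=1e-10)

    def test_vertical_camera_undefined(self):
        with pytest.raises(UndefinedAngleError):
            view_angle([0, 3, 0], [0, 0, 0])
        with pytest.raises(UndefinedAngleError):
            view_angles(np.array([[0, 3, 0.0]]), np.zeros((1, 3)))

    def test_wrap_interval_half_open(self):
        assert wrap_angle(np.pi) == pytest.approx(np.pi)
        assert wrap_angle(-np.pi) == pytest.approx(np.pi)
        assert wrap_angle(3 * np.pi) == pytest.approx(np.pi)


def _hold_session(segments, dt=50):
    """Frames from (position, duration_ms) hold segments at dt spacing."""
    t, cam = [], []
    now = 0
    for pos, dur in segments:
        for ti in range(now, now + dur, dt):
            t.append(ti)
            cam.append(pos)
        now += dur
    return make_session(np.array(t), np.array(cam, dtype=float),
                        tgt=np.tile([0, 0, -1.0], (len(t), 1)))


def _brute_force_fixations(t, cam, min_dwell, eps):
    """O(n^2) reference scan for maximal stationary runs."""
    n = len(t)
    runs = []
    i = 0
    while i < n:
        j = i
        while (j + 1 < n
               and np.linalg.norm(cam[j + 1] - cam[j]) <= eps):
            j += 1
        if t[j] - t[i] >= min_dwell:
            runs.append((i, j))
        i = j + 1
    return runs


class TestDetectFixations:
    def test_constant_trial_single_event(self):
        n = 2001
        t = np.linspace(0, 100_000, n).astype(np.int64)
        s = make_session(t, np.tile([0, 1, 5.0], (n, 1)))
        fx = detect_fixations(s)
        assert fx.n_events == 1
        assert fx.dwell[0] == pytest.approx(100_000)

    def test_run_length_rule(self):
        # hold A 600 ms, move 200 ms, hold B 400 ms (too short), hold C 900 ms
        a, b, c = [0, 0, 5.0], [1, 0, 5.0], [2, 0, 5.0]
        moving = [([0.2 * k, 0, 5.0], 50) for k in range(1, 5)]
        s = _hold_session([(a, 600), *moving, (b, 400), (c, 900)])
        fx = detect_fixations(s, min_dwell_ms=500)
        # B merges nothing: its 400 ms run and each 50 ms moving step fail
        assert fx.n_events == 2
        np.testing.assert_allclose(fx.cam[0], a)
        np.testing.assert_allclose(fx.cam[1], c)

    def test_alternating_positions_no_events(self):
        t = np.arange(0, 10_000, 100)
        cam = np.tile([[0, 0, 5.0], [1, 0, 5.0]], (len(t) // 2, 1))
        s = make_session(t, cam)
        assert detect_fixations(s).n_events == 0

    def test_moving_prefix_suffix_invariance(self, rng):
        hold = ([0, 0, 5.0], 1500)
        s_plain = _hold_session([hold])
        wander = [([0.3 * k, 0.1, 5.0], 100) for k in range(1, 8)]
        s_decorated = _hold_session([*wander, hold, *reversed(wander)])
        f1 = detect_fixations(s_plain)
        f2 = detect_fixations(s_decorated)
        assert f2.n_events == f1.n_events == 1
        np.testing.assert_allclose(f1.cam, f2.cam)

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(50, 600))
            t = np.sort(rng.choice(np.arange(0, 60_000), n, replace=False))
            # random walk with frequent exact holds
            steps = rng.normal(0, 0.2, (n, 3))
            steps[rng.random(n) < 0.7] = 0.0
            cam = np.cumsum(steps, axis=0) + [0, 1, 5]
            s = make_session(t, cam)
            fx = detect_fixations(s, min_dwell_ms=500)
            runs = _brute_force_fixations(s.t, s.cam, 500, 0.0)
            assert fx.n_events == len(runs)
            for k, (i, j) in enumerate(runs):
                assert fx.dwell[k] == pytest.approx(s.t[j] - s.t[i])

    def test_dwell_total_bounded_by_phase(self, random_session):
        s = random_session(n=300, seed=3)
        fx = detect_fixations(s)
        span = s.phase_arrays("main")[0]
        if len(span) and fx.n_events:
            assert fx.dwell.sum() <= span[-1] - span[0]

    def test_empty_phase_empty_sequence(self):
        s = make_session([0, 100], np.zeros((2, 3)) + [0, 1, 5],
                         phase="practice")
        assert detect_fixations(s).n_events == 0


class TestExclusions:
    def test_engineered_cohort_counts(self):
        cohort = make_exclusion_cohort(n_total=60, n_flagged=(2, 5, 7),
                                       n_overlap=1, seed=3)
        retained, report = apply_exclusions(cohort)
        assert report.counts == {"too_far": 2, "too_short_travel": 5,
                                 "low_rate": 7}
        assert report.n_excluded == 13   # union, one id double-flagged
        assert report.n_retained == 47
        assert len(retained) == 47

    def test_clean_cohort_identity(self):
        cohort = make_exclusion_cohort(n_total=20, n_flagged=(0, 0, 0),
                                       n_overlap=0, seed=4)
        retained, report = apply_exclusions(cohort)
        assert report.n_excluded == 0
        assert retained.participant_ids == cohort.participant_ids

    def test_triple_flag_counts_once(self):
        n = 1200
        t = np.linspace(0, 100_000, n).astype(np.int64)  # ~12 rec/s, fine
        good = make_session(t, np.cumsum(np.full((n, 3), 0.01), axis=0)
                            + [0, 1, 5], participant_id="good")
        nbad = 500                                       # 5 rec/s
        tb = np.linspace(0, 100_000, nbad).astype(np.int64)
        cam = np.tile([0, 1, 500.0], (nbad, 1))          # far and motionless
        bad = make_session(tb, cam, participant_id="bad")
        cfg = ExclusionConfig(d_max=50.0, min_travel=0.05)
        _, report = apply_exclusions(Cohort(sessions=[good, bad]), cfg)
        assert report.excluded_ids == ["bad"]
        assert sum(report.counts.values()) == 3

    def test_report_partition(self):
        cohort = make_exclusion_cohort(n_total=40, n_flagged=(1, 2, 3),
                                       n_overlap=0, seed=5)
        _, report = apply_exclusions(cohort)
        assert report.n_excluded + report.n_retained == 40
        assert set(report.excluded_ids).isdisjoint(report.retained_ids)
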