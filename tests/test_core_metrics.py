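"""Startle-window, freeze-run and threshold-calibration behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcvision.core_metrics import (AnalysisConfig, MotionSeries,
                                   calibrate_threshold, detect_freezes,
                                   diff_kinematics, startle_magnitude,
                                   window_frames)
from conftest import series


# ---------------------------------------------------------------------------
# kinematic differencing

class TestDiffKinematics:
    def test_stationary_point_has_zero_speed_and_accel(self):
        sp, ac = diff_kinematics([5, 5, 5, 5], rate_hz=30.0)
        assert np.all(sp.values[sp.valid] == 0)
        assert np.all(ac.values[ac.valid] == 0)

    def test_uniform_motion_has_unit_speed_zero_accel(self):
        sp, ac = diff_kinematics([0, 1, 2, 3], rate_hz=30.0)
        assert np.all(sp.values[1:] == 1) and sp.valid[1:].all()
        assert np.all(ac.values[2:] == 0) and ac.valid[2:].all()

    def test_second_difference_arithmetic(self):
        sp, ac = diff_kinematics([0, 1, 3], rate_hz=30.0)
        assert sp.values[2] == 2
        assert ac.values[2] == abs(3 - 2 * 1 + 0) == 1

    def test_2d_positions_use_euclidean_norm(self):
        p = np.array([[0, 0], [3, 4], [6, 8]])
        sp, _ = diff_kinematics(p, rate_hz=30.0)
        assert sp.values[1] == pytest.approx(5.0)

    def test_occlusion_invalidates_dependent_frames(self):
        valid = np.array([True, True, False, True, True, True])
        sp, ac = diff_kinematics([0, 1, 2, 3, 4, 5], valid, rate_hz=30.0)
        assert not sp.valid[2] and not sp.valid[3] and sp.valid[4]
        assert not ac.valid[3] and not ac.valid[4] and ac.valid[5]

    def test_too_short_and_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="3 frames"):
            diff_kinematics([0, 1], rate_hz=30.0)
        with pytest.raises(ValueError, match="finite"):
            diff_kinematics([0, np.nan, 2], rate_hz=30.0)


# ---------------------------------------------------------------------------
# startle magnitude

class TestStartleMagnitude:
    def test_spike_inside_window_is_the_peak(self, config):
        v = np.zeros(400)
        v[110] = 9.0
        r = startle_magnitude(series(v, 200.0, t0=100), config)
        assert r.magnitude == 9.0
        assert r.peak_frame == 110
        assert r.window_frames == (100, 240)  # 0.7 s at 200 Hz = 140

    def test_spike_outside_window_ignored(self, config):
        v = np.zeros(400)
        v[250] = 9.0  # t0 + 150 > t0 + 139
        r = startle_magnitude(series(v, 200.0, t0=100), config)
        assert r.magnitude == 0.0

    def test_window_rounding_across_rates(self):
        assert window_frames(0.7, 200.0) == 140
        assert window_frames(0.7, 30.0) == 21
        assert window_frames(0.7, 400.0) == 280

    def test_short_series_refused_not_truncated(self, config):
        with pytest.raises(ValueError, match="window"):
            startle_magnitude(series(np.zeros(120), 200.0, t0=50), config)

    def test_tie_resolves_to_earliest_frame(self, config):
        v = np.zeros(200)
        v[[20, 40]] = 3.0
        r = startle_magnitude(series(v, 200.0, t0=10), config)
        assert r.peak_frame == 20

    def test_scaling_series_scales_magnitude(self, config):
        rng = np.random.default_rng(0)
        v = rng.random(300)
        m1 = startle_magnitude(series(v, 200.0, t0=50), config).magnitude
        m3 = startle_magnitude(series(3 * v, 200.0, t0=50), config).magnitude
        assert m3 == pytest.approx(3 * m1)


# ---------------------------------------------------------------------------
# freeze detection

def brute_force_freezes(values, valid, threshold, t0, rate_hz,
                        min_freeze_s, record_window_s):
    """Independent run enumeration by a plain python scan."""
    end = min(t0 + round(record_window_s * rate_hz), len(values))
    intervals = []
    run_start = None
    for i in range(t0, end + 1):
        frozen = (i < end and valid[i] and values[i] < threshold)
        if frozen and run_start is None:
            run_start = i
        elif not frozen and run_start is not None:
            if i - run_start >= round(min_freeze_s * rate_hz):
                intervals.append((run_start, i))
            run_start = None
    total = sum(b - a for a, b in intervals) / rate_hz
    return intervals, total


class TestDetectFreezes:
    def test_exact_400_frame_run_is_two_seconds(self, config):
        v = np.full(6200, 5.0)
        v[300:700] = 0.1
        r = detect_freezes(series(v, 200.0, t0=100), 1.0, config)
        assert r.intervals == ((300, 700),)
        assert r.total_duration_s == 2.0

    def test_minimum_run_rule_discards_short_run(self, config):
        v = np.full(6200, 5.0)
        v[300:360] = 0.1    # 0.3 s: dropped
        v[1000:1200] = 0.1  # 1.0 s: kept
        r = detect_freezes(series(v, 200.0, t0=100), 1.0, config)
        assert r.total_duration_s == 1.0

    def test_never_below_threshold_means_no_freeze(self, config):
        v = np.full(6200, 5.0)
        r = detect_freezes(series(v, 200.0, t0=100), 1.0, config)
        assert r.intervals == () and r.total_duration_s == 0.0

    def test_nonpositive_threshold_rejected(self, config):
        with pytest.raises(ValueError, match="threshold"):
            detect_freezes(series(np.zeros(6200), 200.0, t0=100), 0.0,
                           config)

    def test_run_truncated_by_window_end_still_counts(self, config):
        # 30 s window at 200 Hz ends at frame 100 + 6000; freeze covers
        # the last second of it and beyond
        v = np.full(6500, 5.0)
        v[5900:] = 0.1
        r = detect_freezes(series(v, 200.0, t0=100), 1.0, config)
        assert r.intervals == ((5900, 6100),)
        assert r.total_duration_s == pytest.approx(1.0)

    def test_invalid_frames_break_runs(self, config):
        v = np.full(6200, 0.1)
        valid = np.ones(6200, dtype=bool)
        valid[500] = False
        r = detect_freezes(series(v, 200.0, t0=100, valid=valid), 1.0,
                           config)
        assert (100, 500) in r.intervals and (501, 6100) in r.intervals

    def test_intervals_reconstruct_total_duration(self, config):
        rng = np.random.default_rng(3)
        v = rng.random(6200) * 2
        r = detect_freezes(series(v, 200.0, t0=100), 1.0, config)
        assert r.total_duration_s == pytest.approx(
            sum(b - a for a, b in r.intervals) / 200.0)

    @given(st.lists(st.floats(0, 2), min_size=10, max_size=50),
           st.floats(0.05, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_on_short_series(self, values, threshold):
        cfg = AnalysisConfig(record_window_s=1.0, min_freeze_s=0.1)
        s = series(values, rate_hz=10.0, t0=0)
        r = detect_freezes(s, threshold, cfg)
        intervals, total = brute_force_freezes(
            s.values, s.valid, threshold, 0, 10.0, 0.1, 1.0)
        assert list(r.intervals) == intervals
        assert r.total_duration_s == pytest.approx(total)

    @given(st.floats(0.1, 1.0), st.floats(1.0, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_total_duration_monotone_in_threshold(self, t_low, t_gap):
        rng = np.random.default_rng(7)
        s = series(rng.random(6200) * 3, 200.0, t0=100)
        cfg = AnalysisConfig()
        d_low = detect_freezes(s, t_low, cfg).total_duration_s
        d_high = detect_freezes(s, t_low + t_gap, cfg).total_duration_s
        assert d_high >= d_low

    def test_recovers_injected_freeze_durations(self, config):
        # freeze intervals well separated from motion noise: recovery
        # within +-2 frames per interval
        rng = np.random.default_rng(11)
        rate = 200.0
        v = np.abs(rng.normal(1.0, 0.2, 6200))
        truth = [(800, 1400), (3000, 4000)]
        for a, b in truth:
            v[a:b] = np.abs(rng.normal(0.0, 0.005, b - a))
        r = detect_freezes(series(v, rate, t0=100), 0.3, config)
        assert len(r.intervals) == len(truth)
        for (a, b), (ta, tb) in zip(r.intervals, truth):
            assert abs(a - ta) <= 2 and abs(b - tb) <= 2
        true_total = sum(b - a for a, b in truth) / rate
        assert abs(r.total_duration_s - true_total) <= 2 * 2 / rate


# ---------------------------------------------------------------------------
# threshold calibration

def _bimodal_corpus(n=20, rate=30.0, theta_low=0.1, theta_high=10.0,
                    seed=0):
    """Series whose values are either clearly frozen (~theta_low) or
    clearly moving (~theta_high): any threshold in between is exact."""
    rng = np.random.default_rng(seed)
    out, durations = [], []
    T = 1 + round(31 * rate)
    for i in range(n):
        v = np.full(T, theta_high)
        if i % 2 == 0:
            dur = rng.integers(1, 8) * round(rate)  # whole seconds
            start = 30 + int(rng.integers(0, 200))
            v[start:start + dur] = theta_low
            durations.append(dur / rate)
        else:
            durations.append(0.0)
        out.append(series(v, rate, t0=15))
    return out, durations


class TestCalibrateThreshold:
    def test_separable_corpus_zero_heldout_error(self):
        cfg = AnalysisConfig(cv_folds=5, cv_reps=2, rng_seed=1)
        s, d = _bimodal_corpus()
        cal = calibrate_threshold(s, d, cfg)
        assert 0.1 < cal.threshold <= 10.0
        assert len(cal.per_fold_errors) == 5 * 2
        assert all(e == 0.0 for e in cal.per_fold_errors)

    def test_degenerate_no_freeze_corpus(self):
        cfg = AnalysisConfig(cv_folds=5, cv_reps=2, rng_seed=1)
        s = [series(np.full(1000, 5.0), 30.0, t0=10) for _ in range(10)]
        cal = calibrate_threshold(s, [0.0] * 10, cfg)
        assert all(e == 0.0 for e in cal.per_fold_errors)

    def test_seeded_determinism(self):
        cfg = AnalysisConfig(cv_folds=5, cv_reps=3, rng_seed=7)
        s, d = _bimodal_corpus(seed=5)
        assert calibrate_threshold(s, d, cfg) == \
            calibrate_threshold(s, d, cfg)

    def test_fewer_tests_than_folds_rejected(self):
        cfg = AnalysisConfig(cv_folds=10)
        s, d = _bimodal_corpus(n=4)
        with pytest.raises(ValueError, match="cv_folds"):
            calibrate_threshold(s, d, cfg)


# ---------------------------------------------------------------------------
# config and series invariants

class TestTypes:
    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            AnalysisConfig(startle_window_s=0)
        with pytest.raises(ValueError):
            AnalysisConfig(top_k=200, n_init_points=150)
        with pytest.raises(ValueError):
            AnalysisConfig(cv_folds=1)
        with pytest.raises(ValueError):
            AnalysisConfig(min_freeze_s=40.0, record_window_s=30.0)

    def test_series_invariants_enforced(self):
        with pytest.raises(ValueError):
            MotionSeries(np.array([-1.0, 0.0, 1.0]), 30.0, 0, "g")
        with pytest.raises(ValueError):
            MotionSeries(np.zeros(10), 30.0, 10, "g")
        with pytest.raises(ValueError):
            MotionSeries(np.zeros(10), 0.0, 0, "g")
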