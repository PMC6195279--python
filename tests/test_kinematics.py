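"""Analytic and invariance checks for the per-trial movement metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from reachrank import kinematics as K
from reachrank.simulate import simulate_trajectory

from conftest import bump_trajectory, path_trajectory

HOME = np.zeros(3)
TGT_X = np.array([0.15, 0.0, 0.0])


def minjerk(n_sub=1, noise=0.0, seed=0, **kw):
    return simulate_trajectory(HOME, TGT_X, n_sub, 1.0, noise, 100.0, seed, **kw)


class TestSpeed:
    def test_constant_velocity_is_exact_on_interior(self):
        t = np.arange(0, 2, 0.01)
        pos = np.outer(t, [0.2, 0.0, 0.0])
        traj = K.Trajectory(t, pos, HOME, np.array([0.4, 0, 0]))
        sp = K.compute_speed(traj, smooth_cutoff=None)
        assert np.allclose(sp.speed[1:-1], 0.2, atol=1e-12)

    def test_stationary_speed_is_zero(self):
        t = np.arange(0, 1, 0.01)
        traj = K.Trajectory(t, np.zeros((len(t), 3)), HOME, TGT_X)
        assert K.compute_speed(traj, None).max_speed == 0.0

    def test_minimum_jerk_peak_speed_matches_closed_form(self):
        # quintic profile peaks at 15*D/(8*T) mid-reach
        sp = K.compute_speed(minjerk())
        assert sp.max_speed == pytest.approx(15 * 0.15 / 8.0, rel=0.01)

    def test_non_monotone_times_rejected(self):
        t = np.arange(0, 1, 0.01).copy()
        t[5] = t[7]
        with pytest.raises(ValueError, match="strictly increasing"):
            K.Trajectory(t, np.zeros((len(t), 3)), HOME, TGT_X)


def ramp_trajectory():
    """Still until 0.3 s, then speed 0.6*(t-0.3) along x: position is a
    quadratic, so central differences recover the speed exactly."""
    t = np.arange(0, 1.0005, 0.01)
    x = np.where(t < 0.3, 0.0, 0.3 * (t - 0.3) ** 2)
    pos = np.column_stack([x, np.zeros_like(t), np.zeros_like(t)])
    return K.Trajectory(t, pos, HOME, np.array([1.0, 0, 0]))


class TestOnsetTiming:
    def test_reaction_time_interpolates_threshold_crossing(self):
        traj = ramp_trajectory()
        sp = K.compute_speed(traj, None)
        # 0.6*(t-0.3) = 0.06  =>  t = 0.4
        assert K.reaction_time(traj, sp, 0.06) == pytest.approx(0.4, abs=1e-3)

    def test_already_moving_at_cue_gives_zero(self):
        t = np.arange(0, 1, 0.01)
        pos = np.outer(t, [0.2, 0, 0])
        traj = K.Trajectory(t, pos, HOME, np.array([0.4, 0, 0]), cue_time=0.5)
        sp = K.compute_speed(traj, None)
        assert K.reaction_time(traj, sp, 0.06) == 0.0

    def test_zero_threshold_crosses_at_cue_with_any_movement(self):
        traj = ramp_trajectory()
        sp = K.compute_speed(traj, None)
        assert K.reaction_time(traj, sp, 0.0) == 0.0

    def test_never_mover_is_missing(self):
        t = np.arange(0, 1, 0.01)
        traj = K.Trajectory(t, np.zeros((len(t), 3)), HOME, TGT_X)
        sp = K.compute_speed(traj, None)
        assert np.isnan(K.reaction_time(traj, sp, 0.06))
        assert np.isnan(K.movement_onset(traj, sp, 0.06))

    def test_onset_is_cue_plus_reaction_time(self):
        traj = ramp_trajectory()
        sp = K.compute_speed(traj, None)
        rt = K.reaction_time(traj, sp, 0.06)
        assert K.movement_onset(traj, sp, 0.06) == pytest.approx(
            traj.cue_time + rt, abs=1e-12
        )


class TestInitialDirectionError:
    @pytest.mark.parametrize(
        "first_dir,expected",
        [
            ([1, 0, 0], 0.0),
            ([0, 1, 0], np.pi / 2),
            ([np.sqrt(0.5), np.sqrt(0.5), 0], np.pi / 4),
        ],
    )
    def test_angle_between_first_burst_and_target_line(self, first_dir, expected):
        traj = bump_trajectory(
            [0.3, 0.3], [first_dir, [1, 0, 0]], width=0.2, gap=0.5
        )
        traj.target = traj.home + np.array([1.0, 0.0, 0.0])
        sp = K.compute_speed(traj, None)
        onset = K.movement_onset(traj, sp, 0.01)
        assert K.initial_direction_error(
            traj, onset, sp, K.KinematicsConfig(smooth_cutoff=None)
        ) == pytest.approx(expected, abs=1e-6)


class TestPreMovementSpeed:
    def test_still_before_onset_is_near_zero(self):
        dt = 0.005
        t = np.arange(0, 1 + dt / 2, dt)
        x = np.where(t < 0.5, 0.0, 0.3 * (t - 0.5))  # abrupt move at 0.5 s
        pos = np.column_stack([x, np.zeros_like(t), np.zeros_like(t)])
        traj = K.Trajectory(t, pos, HOME, np.array([0.4, 0, 0]))
        sp = K.compute_speed(traj, None)
        onset = K.movement_onset(traj, sp, 0.06)
        assert K.pre_movement_speed(sp, 0.0, onset) == pytest.approx(0.0, abs=5e-3)

    def test_constant_drift_recovered(self):
        t = np.arange(0, 1, 0.005)
        pos = np.outer(t, [0.02, 0, 0])
        traj = K.Trajectory(t, pos, HOME, np.array([0.4, 0, 0]))
        sp = K.compute_speed(traj, None)
        assert K.pre_movement_speed(sp, 0.0, 0.5) == pytest.approx(0.02, abs=1e-10)

    def test_linear_ramp_gives_trapezoid_mean(self):
        t = np.arange(0, 1.0005, 0.005)
        pos = np.column_stack([0.02 * t**2, np.zeros_like(t), np.zeros_like(t)])
        traj = K.Trajectory(t, pos, HOME, np.array([0.4, 0, 0]))
        sp = K.compute_speed(traj, None)  # speed ramps 0 -> 0.04 over [0, 1]
        assert K.pre_movement_speed(sp, 0.0, 1.0) == pytest.approx(0.02, rel=1e-3)


class TestSpeedRatio:
    def test_single_peak_ratio_is_one(self):
        sp = K.compute_speed(minjerk())
        assert K.speed_ratio(sp, 0.0) == pytest.approx(1.0)

    def test_growing_bursts_first_over_max(self):
        traj = bump_trajectory([0.2, 0.4], [[1, 0, 0], [1, 0, 0]])
        sp = K.compute_speed(traj, None)
        assert K.speed_ratio(sp, 0.0, K.KinematicsConfig(smooth_cutoff=None)) == \
            pytest.approx(0.5, abs=1e-3)

    def test_decaying_bursts_ratio_is_one(self):
        traj = bump_trajectory([0.3, 0.25, 0.2], [[1, 0, 0]] * 3)
        sp = K.compute_speed(traj, None)
        assert K.speed_ratio(sp, 0.0, K.KinematicsConfig(smooth_cutoff=None)) == \
            pytest.approx(1.0, abs=1e-6)


class TestPathGeometry:
    def test_straight_reach_plr_one_pmtd_100_mpd_zero(self):
        traj = minjerk()
        assert K.path_length_ratio(traj) == pytest.approx(1.0, abs=1e-12)
        assert K.pmtd(traj) == pytest.approx(100.0, abs=1e-9)
        assert K.max_perpendicular_distance(traj) == pytest.approx(0.0, abs=1e-12)

    def test_semicircle_plr_is_half_pi_and_mpd_half_chord(self):
        D = 0.2
        theta = np.pi * np.linspace(0, 1, 101)  # 100 Hz over 1 s
        pos = np.column_stack(
            [D / 2 * (1 - np.cos(theta)), D / 2 * np.sin(theta), np.zeros_like(theta)]
        )
        traj = K.Trajectory(np.linspace(0, 1, 101), pos, HOME, np.array([D, 0, 0]))
        assert K.path_length_ratio(traj) == pytest.approx(np.pi / 2, abs=1e-3)
        assert K.max_perpendicular_distance(traj) == pytest.approx(D / 2, abs=1e-4)

    def test_out_and_back_plr_two(self):
        L = 0.1
        traj = path_trajectory(
            [[0, 0, 0], [1.5 * L, 0, 0], [L, 0, 0]], HOME, [L, 0, 0]
        )
        assert K.path_length_ratio(traj) == pytest.approx(2.0, abs=1e-9)

    def test_detour_point_line_distance(self):
        traj = path_trajectory(
            [[0, 0, 0], [0.5, 0.2, 0], [1, 0, 0]], HOME, [1, 0, 0]
        )
        assert K.max_perpendicular_distance(traj) == pytest.approx(0.2, abs=1e-12)

    def test_pmtd_dogleg_hand_computation(self):
        traj = path_trajectory([[0, 0, 0], [0, 1, 0], [1, 0, 0]], HOME, [1, 0, 0])
        expected = 100 * (0 + 1) / (1 + np.sqrt(2))
        assert K.pmtd(traj) == pytest.approx(expected, abs=1e-9)

    def test_pure_retreat_pmtd_minus_100(self):
        traj = path_trajectory([[0, 0, 0], [-1, 0, 0]], HOME, [1, 0, 0])
        assert K.pmtd(traj) == pytest.approx(-100.0, abs=1e-12)


class TestSpeedPeaksAndArrest:
    @pytest.mark.parametrize("n_sub", [1, 2, 3, 4, 5])
    def test_submovement_count_recovered(self, n_sub):
        traj = minjerk(n_sub=n_sub, seed=3)
        sp = K.compute_speed(traj)
        assert K.num_speed_peaks(sp) == n_sub

    def test_flat_trial_has_zero_peaks(self):
        t = np.arange(0, 1, 0.01)
        traj = K.Trajectory(t, np.zeros((len(t), 3)), HOME, TGT_X)
        assert K.num_speed_peaks(K.compute_speed(traj, None)) == 0.0

    def test_constant_speed_never_arrested(self):
        t = np.arange(0, 1, 0.01)
        pos = np.outer(t, [0.2, 0, 0])
        traj = K.Trajectory(t, pos, HOME, np.array([0.4, 0, 0]))
        assert K.arrest_period_ratio(K.compute_speed(traj, None)) == 0.0

    def test_half_stationary_trial_arrest_ratio_half(self):
        dt = 0.005
        t = np.arange(0, 1 + dt / 2, dt)
        x = np.where(t < 0.5, 0.0, 0.3 * (t - 0.5))
        pos = np.column_stack([x, np.zeros_like(t), np.zeros_like(t)])
        traj = K.Trajectory(t, pos, HOME, np.array([0.4, 0, 0]))
        apr = K.arrest_period_ratio(K.compute_speed(traj, None))
        assert apr == pytest.approx(0.5, abs=2 * dt)

    def test_all_stationary_arrest_missing(self):
        t = np.arange(0, 1, 0.01)
        traj = K.Trajectory(t, np.zeros((len(t), 3)), HOME, TGT_X)
        assert np.isnan(K.arrest_period_ratio(K.compute_speed(traj, None)))


class TestExtractTrialMetrics:
    def test_straight_single_burst_composition(self):
        m = K.extract_trial_metrics(minjerk())
        assert m.initial_direction_error == pytest.approx(0.0, abs=1e-6)
        assert m.path_length_ratio == pytest.approx(1.0, abs=1e-9)
        assert m.pmtd == pytest.approx(100.0, abs=1e-6)
        assert m.num_speed_peaks == 1
        assert m.max_perpendicular_distance == pytest.approx(0.0, abs=1e-9)
        assert m.speed_ratio == pytest.approx(1.0)
        assert not m.flags

    def test_three_burst_trial_nsp3_and_curved_path(self):
        m = K.extract_trial_metrics(minjerk(n_sub=3, seed=5))
        assert m.num_speed_peaks == 3
        assert m.path_length_ratio > 1.0

    def test_stationary_trial_flags_speed_metrics(self):
        t = np.arange(0, 1, 0.01)
        traj = K.Trajectory(t, np.zeros((len(t), 3)), HOME, TGT_X)
        m = K.extract_trial_metrics(traj)
        assert np.isnan(m.reaction_time)
        assert np.isnan(m.speed_ratio)
        assert np.isnan(m.arrest_period_ratio)
        assert m.flags

    def test_initial_movement_ratio_between_zero_and_plr(self):
        m = K.extract_trial_metrics(minjerk(n_sub=3, noise=0.001, seed=9))
        assert 0.0 <= m.initial_movement_ratio <= m.path_length_ratio


def _metrics_vector(traj):
    m = K.extract_trial_metrics(traj)
    return np.array([getattr(m, name) for name in K.METRIC_NAMES])


class TestInvariances:
    @pytest.mark.parametrize("rot_seed", [0, 1, 2])
    def test_rigid_motion_leaves_all_metrics_unchanged(self, rot_seed):
        traj = minjerk(n_sub=3, noise=0.001, seed=11, reaction_delay=0.2,
                       hold_time=0.3)
        R = Rotation.random(rng=np.random.default_rng(rot_seed)).as_matrix()
        shift = np.array([0.3, -0.2, 0.5])
        moved = K.Trajectory(
            traj.times, traj.positions @ R.T + shift,
            traj.home @ R.T + shift, traj.target @ R.T + shift,
            cue_time=traj.cue_time,
        )
        base, rot = _metrics_vector(traj), _metrics_vector(moved)
        np.testing.assert_allclose(rot, base, rtol=1e-9, atol=1e-9)

    def test_uniform_scaling_splits_metrics_as_expected(self):
        traj = minjerk(n_sub=3, seed=13, reaction_delay=0.2, hold_time=0.3)
        c = 2.0
        scaled = K.Trajectory(
            traj.times, traj.positions * c, traj.home * c, traj.target * c,
            cue_time=traj.cue_time,
        )
        m0 = K.extract_trial_metrics(traj, K.KinematicsConfig(v_thresh=0.06))
        m1 = K.extract_trial_metrics(
            scaled, K.KinematicsConfig(v_thresh=0.06 * c)  # threshold in scaled units
        )
        for name in ("path_length_ratio", "pmtd", "speed_ratio",
                     "arrest_period_ratio", "num_speed_peaks",
                     "initial_direction_error", "initial_movement_ratio"):
            assert getattr(m1, name) == pytest.approx(
                getattr(m0, name), rel=1e-9, abs=1e-9
            ), name
        for name in ("max_speed", "max_perpendicular_distance",
                     "pre_movement_speed"):
            assert getattr(m1, name) == pytest.approx(
                c * getattr(m0, name), rel=1e-9, abs=1e-12
            ), name

    def test_resampling_stability_under_doubled_rate(self):
        kw = dict(reaction_delay=0.2, hold_time=0.3)
        lo = minjerk(n_sub=3, seed=17, **kw)
        hi = simulate_trajectory(HOME, TGT_X, 3, 1.0, 0.0, 200.0, 17, **kw)
        v0, v1 = _metrics_vector(lo), _metrics_vector(hi)
        # near-zero metrics (pre-movement speed) compared absolutely
        np.testing.assert_allclose(v1, v0, rtol=0.01, atol=2e-4)
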