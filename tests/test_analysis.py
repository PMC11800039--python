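"""Rupture/maximum-force detection on analytic fixtures; energy windows."""

import numpy as np
import pytest

from dnaunwind.analysis import (detect_fmax, detect_rupture, force_extension,
                                stage_energy_change)
from dnaunwind.trajectory import Trajectory, scripted_trajectory

RATE = 0.20  # pN/fs tension ramp used throughout the fixtures


def v_fixture(t_star=500.0, v0=6.4, vertex=5.6, dt=1.0):
    """Symmetric V dip to ``vertex`` at t*, then linear rise through 8.2 Å.

    Returns (times, tension, cm) with the tension ramping at 0.20 pN/fs.
    Crossing time solves vertex + slope (t - t*) = 8.2.
    """
    slope = (v0 - vertex) / t_star

    def cm(t):
        return vertex + slope * abs(t - t_star)

    t_cross = t_star + (8.2 - vertex) / slope
    traj = scripted_trajectory([cm], dt, t_cross + 300.0,
                               tension_function=lambda t: RATE * t)
    return traj.times, traj.tension, traj.cm[:, 0], t_star, t_cross


class TestDetectRupture:
    def test_v_fixture_recovers_vertex_exactly(self):
        t, tension, cm, t_star, _ = v_fixture()
        rup = detect_rupture(t, tension, cm, smooth_window_fs=200.0)
        assert rup.found
        assert rup.t == t_star
        assert rup.force == RATE * t_star

    def test_unsmoothed_detection_also_exact(self):
        t, tension, cm, t_star, _ = v_fixture()
        rup = detect_rupture(t, tension, cm, smooth_window_fs=0.0)
        assert (rup.t, rup.force) == (t_star, RATE * t_star)

    def test_monotone_series_flags_no_rupture(self):
        traj = scripted_trajectory([lambda t: 5.8 + 0.002 * t], 1.0, 2000.0,
                                   tension_function=lambda t: RATE * t)
        rup = detect_rupture(traj.times, traj.tension, traj.cm[:, 0],
                             smooth_window_fs=0.0)
        assert not rup.found
        assert rup.t == traj.times[0]

    def test_two_minima_take_the_later(self):
        """W-shaped series: minima at 400 and 1200 fs; the later one is the
        rupture point."""
        def cm(t):
            if t <= 800.0:
                return 6.4 + 0.002 * abs(t - 400.0)
            return 5.9 + 0.003 * abs(t - 1200.0)

        traj = scripted_trajectory([cm], 1.0, 2400.0,
                                   tension_function=lambda t: RATE * t)
        rup = detect_rupture(traj.times, traj.tension, traj.cm[:, 0],
                             smooth_window_fs=0.0)
        assert rup.t == 1200.0
        assert rup.force == RATE * 1200.0

    def test_flat_minimum_ties_to_later_sample(self):
        cm = np.array([6.0, 5.5, 5.5, 5.5, 6.0, 7.0, 8.3])
        t = np.arange(7.0)
        tension = RATE * t
        rup = detect_rupture(t, tension, cm, smooth_window_fs=0.0)
        assert rup.t == 3.0

    def test_time_shift_invariance(self):
        t, tension, cm, t_star, _ = v_fixture()
        r0 = detect_rupture(t, tension, cm, smooth_window_fs=0.0)
        r1 = detect_rupture(t + 5000.0, tension, cm, smooth_window_fs=0.0)
        assert r1.t == r0.t + 5000.0
        assert r1.force == r0.force

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            detect_rupture(np.array([]), np.array([]), np.array([]))


class TestDetectFmax:
    def test_linear_ramp_crossing_closed_form(self):
        """cm = 5.8 + 0.0012 t crosses 8.2 at t = 2000 exactly on the grid."""
        traj = scripted_trajectory([lambda t: 5.8 + 0.0012 * t], 1.0, 2500.0,
                                   tension_function=lambda t: RATE * t)
        fmax, t_max = detect_fmax(traj.times, traj.tension, traj.cm[:, 0])
        assert t_max == 2000.0
        assert fmax == RATE * 2000.0

    def test_fmax_bounds_frup_on_v_fixture(self):
        t, tension, cm, _, _ = v_fixture()
        rup = detect_rupture(t, tension, cm, smooth_window_fs=200.0)
        fmax, _ = detect_fmax(t, tension, cm)
        assert fmax >= rup.force

    def test_exact_touch_is_the_crossing(self):
        cm = np.array([5.8, 6.5, 8.2, 8.4])
        t = np.arange(4.0)
        fmax, t_max = detect_fmax(t, RATE * t, cm)
        assert t_max == 2.0

    def test_no_crossing_rejected(self):
        t = np.arange(100.0)
        with pytest.raises(ValueError, match="threshold"):
            detect_fmax(t, RATE * t, np.full(100, 6.0))


def make_traj(times, potential):
    n = len(times)
    return Trajectory(times=np.asarray(times, dtype=float),
                      cm=np.zeros((n, 1)), tension=np.full(n, np.nan),
                      active_pair=np.full(n, -1),
                      potential=np.asarray(potential, dtype=float))


class TestStageEnergyChange:
    def test_identical_windows_zero(self):
        traj = make_traj(np.arange(100.0), np.linspace(0, 5, 100))
        assert stage_energy_change(traj, (0, 50), (0, 50)) == 0.0

    def test_constructed_step_of_ten(self):
        t = np.arange(200.0)
        pot = np.where(t < 100, 3.0, 13.0)
        traj = make_traj(t, pot)
        assert stage_energy_change(traj, (0, 99), (100, 199)) == pytest.approx(10.0)

    def test_stationary_noise_within_three_se(self):
        rng = np.random.default_rng(7)
        t = np.arange(4000.0)
        pot = rng.standard_normal(4000)
        traj = make_traj(t, pot)
        de = stage_energy_change(traj, (0, 1999), (2000, 3999))
        se = np.sqrt(2) * 1.0 / np.sqrt(2000)
        assert abs(de) < 3 * se

    def test_partial_overlap_rejected(self):
        traj = make_traj(np.arange(100.0), np.zeros(100))
        with pytest.raises(ValueError, match="overlap"):
            stage_energy_change(traj, (0, 60), (50, 99))

    def test_out_of_range_rejected(self):
        traj = make_traj(np.arange(100.0), np.zeros(100))
        with pytest.raises(ValueError):
            stage_energy_change(traj, (0, 50), (60, 150))


class TestForceExtension:
    def test_linear_in_time_gives_straight_line(self):
        t = np.arange(1000.0)
        cm = 5.8 + 0.002 * t
        tension = RATE * t
        curve = force_extension(t, tension, cm)
        slopes = np.diff(curve.tension) / np.diff(curve.separation)
        assert np.allclose(slopes, slopes[0])

    def test_plateau_then_rise_knee_located(self):
        t = np.arange(2000.0)
        cm = 5.8 + 0.001 * t
        tension = np.where(t < 1000, 0.01 * t, 10.0 + 1.0 * (t - 1000))
        curve = force_extension(t, tension, cm)
        assert curve.plateau_end is not None
        knee_time = t[curve.plateau_end]
        assert 950 <= knee_time <= 1050

    def test_short_window_has_no_annotation(self):
        curve = force_extension(np.arange(2.0), np.arange(2.0),
                                np.arange(2.0))
        assert curve.plateau_end is None
        assert len(curve.separation) == 2

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="match"):
            force_extension(np.arange(5.0), np.arange(4.0), np.arange(5.0))


class TestScriptedTrajectory:
    def test_constant_separation_never_crosses(self):
        traj = scripted_trajectory([lambda t: 5.8] * 3, 1.0, 1000.0)
        assert (traj.cm < 8.2).all()

    def test_positions_consistent_with_separations(self):
        traj = scripted_trajectory([lambda t: 5.8 + 0.001 * t,
                                    lambda t: 6.0], 1.0, 100.0)
        for j in range(2):
            d = np.linalg.norm(traj.positions[:, 2 * j + 1]
                               - traj.positions[:, 2 * j], axis=1)
            assert np.allclose(d, traj.cm[:, j], atol=1e-12)

    def test_linear_ramp_crossing_time_analytic(self):
        traj = scripted_trajectory([lambda t: 5.8 + 0.0024 * t], 1.0, 1100.0)
        cross = traj.times[np.argmax(traj.cm[:, 0] >= 8.2)]
        assert cross == 1000.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            scripted_trajectory([], 1.0, 10.0)
        with pytest.raises(ValueError):
            scripted_trajectory([lambda t: 5.8], -1.0, 10.0)
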