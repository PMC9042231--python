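"""Freezing/running bouts and trial-level escape scores."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethoflight import (SimSpec, accuracy_from_distance, arrival_time,
                        classify_success, compute_kinematics,
                        detect_escape_runs, detect_freezing,
                        detect_running_bouts, escape_accuracy,
                        escape_latency, escape_linearity,
                        profile_vs_normalized_distance, score_escape_trial,
                        sim_freezing_speed_series, sim_goal_directed_escape,
                        time_to_max_speed)
from ethoflight.defensive_metrics import Bout, escape_latency as _lat

from conftest import make_track

FPS = 30.0


def _time(n):
    return np.arange(n) / FPS


class TestFreezing:
    def test_immobile_session_is_one_bout(self):
        bouts, total = detect_freezing(np.zeros(300), _time(300))
        assert len(bouts) == 1
        assert total == pytest.approx(10.0)

    def test_fast_locomotion_yields_none(self):
        bouts, total = detect_freezing(np.full(300, 4.0), _time(300),
                                       threshold=2.0)
        assert bouts == [] and total == 0.0

    def test_recovers_planted_bouts(self):
        speed, time, truth = sim_freezing_speed_series(SimSpec(seed=21))
        bouts, total = detect_freezing(speed, time)
        n = len(truth["bouts"])
        assert len(bouts) == n
        assert total == pytest.approx(truth["total"], abs=2 * n / FPS)
        for (t0, dur), b in zip(truth["bouts"], bouts):
            assert b.start == pytest.approx(t0, abs=2 / FPS)
            assert b.duration == pytest.approx(dur, abs=4 / FPS)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(thr=st.floats(0.5, 8.0), mind=st.floats(0.2, 3.0))
    def test_total_monotone_in_parameters(self, thr, mind):
        rng = np.random.default_rng(5)
        speed = np.abs(rng.normal(3.0, 3.0, 600))
        _, total = detect_freezing(speed, _time(600), thr, mind)
        _, lower_thr = detect_freezing(speed, _time(600), thr / 2, mind)
        _, longer_min = detect_freezing(speed, _time(600), thr, mind * 2)
        assert lower_thr <= total + 1e-12
        assert longer_min <= total + 1e-12


class TestRunningBouts:
    def test_sustained_run_is_single_bout(self):
        bouts = detect_running_bouts(np.full(120, 35.0), _time(120))
        assert len(bouts) == 1
        assert bouts[0].duration == pytest.approx(4.0)

    def test_below_running_threshold_is_not_running(self):
        # 20 cm/s is below the 0.3 m/s running criterion
        assert detect_running_bouts(np.full(120, 20.0), _time(120)) == []

    def test_brief_gap_merged(self):
        speed = np.full(90, 40.0)
        speed[30:33] = 5.0  # 0.1-s dip
        bouts = detect_running_bouts(speed, _time(90), merge_gap=0.2)
        assert len(bouts) == 1

    def test_long_gap_not_merged(self):
        speed = np.full(120, 40.0)
        speed[30:60] = 5.0  # 1-s gap
        assert len(detect_running_bouts(speed, _time(120))) == 2


class TestEscapeLatency:
    def test_oriented_and_moving_at_onset(self, barnes_arena):
        track, _ = sim_goal_directed_escape(SimSpec(seed=1, noise_sd=0.0),
                                            barnes_arena, (0.0, 36.0))
        kin = compute_kinematics(track, barnes_arena)
        assert escape_latency(kin) == pytest.approx(0.0, abs=1 / FPS)

    def test_frozen_window_is_null(self, barnes_arena):
        track = make_track(np.tile([[0.0, 36.0]], (270, 1)), heading_deg=0.0)
        kin = compute_kinematics(track, barnes_arena)
        assert escape_latency(kin) is None

    def test_commanded_onset_recovered(self, barnes_arena):
        track, truth = sim_goal_directed_escape(
            SimSpec(seed=4, noise_sd=0.0), barnes_arena, (0.0, 36.0),
            onset_delay=1.5)
        kin = compute_kinematics(track, barnes_arena)
        assert escape_latency(kin) == pytest.approx(truth["movement_onset"],
                                                    abs=2 / FPS)


class TestAccuracy:
    @pytest.mark.parametrize("d_over_D,expected",
                             [(0.0, 100.0), (1.0, 90.0), (5.0, 50.0)])
    def test_formula_fidelity(self, d_over_D, expected):
        D = 10.0
        assert accuracy_from_distance(d_over_D * D, D) == pytest.approx(expected)

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 80, 50)
        acc = [accuracy_from_distance(x, 10.0) for x in d]
        assert all(a > b for a, b in zip(acc, acc[1:]))
        assert acc[0] == 100.0

    def test_eval_time_uses_nearest_valid_frame(self):
        dist = np.full(300, 12.0)
        dist[200:] = np.nan
        t = _time(300)
        # eval at 9 s: nearest valid frame is beyond 0.5 s away -> None
        assert escape_accuracy(dist, t, 10.0, eval_time=9.0) is None
        dist[280] = 7.0
        assert escape_accuracy(dist, t, 10.0, eval_time=9.5) == pytest.approx(93.0)


class TestLinearity:
    def test_straight_escape_is_100(self):
        xy = np.column_stack([np.zeros(50), np.linspace(36.0, -36.0, 50)])
        assert escape_linearity(xy, (0.0, -36.0)) == pytest.approx(100.0)

    def test_semicircular_path_analytic(self):
        # semicircle of radius r between onset and a shelter 2r apart:
        # path/chord = pi/2 -> 157.08 %
        r = 20.0
        theta = np.linspace(0, math.pi, 2000)
        xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        lin = escape_linearity(xy, (-r, 0.0))
        assert lin == pytest.approx(100.0 * math.pi / 2.0, rel=0.005)

    def test_onset_inside_shelter_is_null(self):
        xy = np.array([[0.0, -36.0], [0.0, -36.5]])
        assert escape_linearity(xy, (0.0, -36.0)) is None


class TestTimeToMaxSpeed:
    def test_monotonic_profile_peaks_at_end(self):
        speed = np.linspace(0, 50, 60)
        assert time_to_max_speed(speed, _time(60)) == pytest.approx(59 / FPS)

    def test_tie_breaks_to_first_occurrence(self):
        speed = np.array([0.0, 5.0, 9.0, 3.0, 9.0, 1.0])
        assert time_to_max_speed(speed, _time(6)) == pytest.approx(2 / FPS)

    def test_commanded_peak_recovered(self, barnes_arena):
        track, truth = sim_goal_directed_escape(SimSpec(seed=6, noise_sd=0.0),
                                                barnes_arena, (0.0, 36.0))
        kin = compute_kinematics(track, barnes_arena)
        end = truth["arrival_time"] + 1 / FPS
        win = kin.slice(0.0, end)
        got = time_to_max_speed(win.speed, win.time)
        assert got == pytest.approx(truth["peak_time"], abs=2 / FPS)


class TestSuccess:
    def test_arriving_trajectory_is_success(self, barnes_arena):
        xy = np.column_stack([np.zeros(150), np.linspace(20.0, -36.0, 150)])
        kin = compute_kinematics(make_track(xy), barnes_arena)
        assert classify_success(kin.in_shelter, kin.time, onset=0.0)

    def test_never_in_shelter_is_failure(self, barnes_arena):
        xy = np.column_stack([np.zeros(150), np.linspace(20.0, 40.0, 150)])
        kin = compute_kinematics(make_track(xy), barnes_arena)
        assert not classify_success(kin.in_shelter, kin.time, onset=0.0)

    def test_agrees_with_brute_force_scan(self, barnes_arena):
        rng = np.random.default_rng(12)
        for _ in range(20):
            xy = rng.uniform(-45, 45, size=(100, 2))
            kin = compute_kinematics(make_track(xy), barnes_arena)
            expected = any(
                math.hypot(x - 0.0, y - (-36.0)) <= 5.0 + 1e-12
                for x, y in xy if math.hypot(x, y) >= 0)
            got = classify_success(kin.in_shelter, kin.time, onset=0.0,
                                   window=100 / FPS)
            assert got == expected


class TestEscapeRuns:
    def _session(self, n_exits, fast_exits, mean_speed=6.0):
        """Zone/speed series with n_exits odor->water crossings, the first
        fast_exits of them at 3x the ambulation speed."""
        fps = int(FPS)
        zone, speed = [], []
        for k in range(n_exits):
            zone += ["odor"] * fps * 2 + ["water"] * fps * 2
            block = [mean_speed] * (fps * 4)
            if k < fast_exits:
                block[fps * 2] = mean_speed * 3.0
            speed += block
        return (np.array(zone, dtype=object), np.array(speed),
                np.arange(len(zone)) / FPS)

    def test_no_exits_no_events(self):
        zone = np.array(["odor"] * 300, dtype=object)
        speed = np.full(300, 5.0)
        count, _ = detect_escape_runs(zone, speed, _time(300), "odor")
        assert count == 0

    def test_single_fast_exit_detected(self):
        zone, speed, t = self._session(1, 1)
        count, times = detect_escape_runs(zone, speed, t, "odor")
        assert count == 1

    def test_commanded_fast_exit_count(self):
        zone, speed, t = self._session(6, 3)
        count, _ = detect_escape_runs(zone, speed, t, "odor")
        assert count == 3

    def test_missing_odor_zone_is_config_error(self):
        from ethoflight.exceptions import ConfigError
        zone = np.array(["water"] * 100, dtype=object)
        with pytest.raises(ConfigError):
            detect_escape_runs(zone, np.full(100, 5.0), _time(100), "odor")


class TestProfile:
    def test_straight_constant_speed_profile(self, barnes_arena):
        xy = np.column_stack([np.zeros(200), np.linspace(36.0, -30.9, 200)])
        kin = compute_kinematics(make_track(xy), barnes_arena)
        prof = profile_vs_normalized_distance([kin], n_bins=10)
        speeds = prof["speed_mean"].dropna()
        assert speeds.std() < 0.05 * speeds.mean()  # flat profile
        assert (prof["angle_mean"].dropna() < 5.0).all()

    def test_goal_directed_peak_in_middle_third(self, barnes_arena):
        trials = []
        for s in range(5):
            track, truth = sim_goal_directed_escape(
                SimSpec(seed=100 + s, noise_sd=0.05), barnes_arena, (0.0, 36.0))
            kin = compute_kinematics(track, barnes_arena)
            trials.append(kin.slice(0.0, truth["arrival_time"] + 1 / FPS))
        prof = profile_vs_normalized_distance(trials, n_bins=20)
        peak_bin = prof["speed_mean"].idxmax()
        assert 1 / 3 <= prof.loc[peak_bin, "bin_center"] <= 2 / 3

    def test_empty_trial_list_is_error(self):
        with pytest.raises(ValueError):
            profile_vs_normalized_distance([])


class TestTrialOrchestration:
    def test_noise_free_goal_directed_scores(self, barnes_arena):
        track, truth = sim_goal_directed_escape(SimSpec(seed=3, noise_sd=0.0),
                                                barnes_arena, (0.0, 36.0))
        res = score_escape_trial(track, barnes_arena, onset=0.0)
        assert res.arrived
        assert res.accuracy == 100.0
        assert res.linearity == pytest.approx(100.0, abs=0.5)
        assert res.arrival_time == pytest.approx(truth["arrival_time"],
                                                 abs=2 / FPS)
        assert res.peak_speed <= 60.0 + 1.0
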