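"""Speed, head angle, target distance and zone occupancy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ethoflight import (compute_speed, distance_to_target,
                        head_direction_angle, zone_occupancy)
from ethoflight.io_formats import ArenaGeometry, Circle, Partition, Rectangle

from conftest import make_track


def brute_force_speed(xy_cm, fps):
    """Independent per-segment displacement/elapsed-time loop (no vectorized
    numpy): centered over two frame intervals inside, one-sided at the ends."""
    n = len(xy_cm)
    out = []
    for i in range(n):
        if i == 0:
            a, b, dt = xy_cm[0], xy_cm[1], 1.0 / fps
        elif i == n - 1:
            a, b, dt = xy_cm[-2], xy_cm[-1], 1.0 / fps
        else:
            a, b, dt = xy_cm[i - 1], xy_cm[i + 1], 2.0 / fps
        out.append(math.hypot(b[0] - a[0], b[1] - a[1]) / dt)
    return np.array(out)


class TestSpeed:
    def test_stationary_is_zero(self, barnes_arena):
        track = make_track(np.tile([[5.0, 5.0]], (30, 1)))
        assert np.allclose(compute_speed(track, barnes_arena), 0.0)

    def test_constant_velocity_analytic(self, barnes_arena):
        # 1 cm per frame at 30 Hz -> 30 cm/s everywhere (one-sided ends too)
        xy = np.column_stack([np.arange(40.0), np.zeros(40)])
        track = make_track(xy)
        np.testing.assert_allclose(compute_speed(track, barnes_arena), 30.0)

    def test_matches_brute_force_oracle(self, barnes_arena):
        rng = np.random.default_rng(42)
        xy = np.cumsum(rng.normal(0, 0.5, size=(100, 2)), axis=0)
        track = make_track(xy)
        got = compute_speed(track, barnes_arena, smooth_window=1)
        np.testing.assert_allclose(got, brute_force_speed(xy, 30.0), atol=1e-9)

    def test_invariant_under_rigid_motion(self, barnes_arena):
        rng = np.random.default_rng(7)
        xy = np.cumsum(rng.normal(0, 0.5, size=(60, 2)), axis=0)
        base = compute_speed(make_track(xy), barnes_arena)
        for theta, shift in [(0.3, (5, -2)), (2.0, (-11, 4)), (4.4, (0, 9))]:
            R = np.array([[np.cos(theta), -np.sin(theta)],
                          [np.sin(theta), np.cos(theta)]])
            moved = xy @ R.T + shift
            np.testing.assert_allclose(
                compute_speed(make_track(moved), barnes_arena), base, atol=1e-9)

    def test_missing_frames_propagate_nan(self, barnes_arena):
        xy = np.column_stack([np.arange(20.0), np.zeros(20)])
        track = make_track(xy)
        track.coords["centre"][10] = np.nan
        sp = compute_speed(track, barnes_arena)
        assert np.isnan(sp[10])

    def test_all_missing_is_error(self, barnes_arena):
        track = make_track(np.zeros((10, 2)))
        track.coords["centre"][:] = np.nan
        from ethoflight.exceptions import PoseDataError
        with pytest.raises(PoseDataError):
            compute_speed(track, barnes_arena)


class TestHeadAngle:
    def _single_frame_track(self, centre, nose, px_per_cm=5.0):
        track = make_track(np.tile(centre, (2, 1)), px_per_cm=px_per_cm)
        track.coords["nose"][:] = np.asarray(nose) * px_per_cm
        return track

    def test_cardinal_angles(self, barnes_arena):
        target = (10.0, 0.0)
        cases = [((1.0, 0.0), 0.0),     # nose on segment centre->target
                 ((-1.0, 0.0), 180.0),  # diametrically opposite
                 ((0.0, 1.0), 90.0)]    # perpendicular
        for nose, expected in cases:
            track = self._single_frame_track((0.0, 0.0), nose)
            ang = head_direction_angle(track, barnes_arena, target)
            np.testing.assert_allclose(ang, expected, atol=1e-9)

    def test_zero_head_vector_is_nan(self, barnes_arena):
        track = self._single_frame_track((0.0, 0.0), (0.0, 0.0))
        assert np.isnan(head_direction_angle(track, barnes_arena, (10, 0))).all()

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(cx=st.floats(-20, 20), cy=st.floats(-20, 20),
           nx=st.floats(-20, 20), ny=st.floats(-20, 20),
           tx=st.floats(-20, 20), ty=st.floats(-20, 20))
    def test_reflection_supplementary(self, cx, cy, nx, ny, tx, ty):
        """angle(target) + angle(point reflection of target) == 180 deg."""
        if (nx, ny) == (cx, cy) or (tx, ty) == (cx, cy):
            return
        geom = ArenaGeometry(px_per_cm=1.0,
                             arena=Circle(center=(0, 0), radius=1000.0))
        track = make_track(np.tile([[cx, cy]], (2, 1)), px_per_cm=1.0)
        track.coords["nose"][:] = (nx, ny)
        a1 = head_direction_angle(track, geom, (tx, ty))[0]
        a2 = head_direction_angle(track, geom, (2 * cx - tx, 2 * cy - ty))[0]
        assert a1 + a2 == pytest.approx(180.0, abs=1e-6)


class TestDistance:
    def test_at_target_and_pythagorean(self, barnes_arena):
        track = make_track([[0.0, 0.0], [3.0, 4.0]])
        d = distance_to_target(track, barnes_arena, (0.0, 0.0))
        np.testing.assert_allclose(d, [0.0, 5.0])

    def test_matches_elementwise_oracle(self, barnes_arena):
        rng = np.random.default_rng(3)
        xy = rng.uniform(-40, 40, size=(50, 2))
        target = (4.0, -7.0)
        got = distance_to_target(make_track(xy), barnes_arena, target)
        expected = [math.hypot(x - target[0], y - target[1]) for x, y in xy]
        np.testing.assert_allclose(got, expected, atol=1e-9)


class TestZoneOccupancy:
    def test_entirely_inside_shelter(self, barnes_arena):
        track = make_track(np.tile([[0.0, -36.0]], (60, 1)))
        _, durations = zone_occupancy(track, barnes_arena)
        assert durations == {"shelter": pytest.approx(60 / 30.0)}

    def test_partition_line_tie_breaks_to_first_zone(self, two_chamber_arena):
        track = make_track(np.tile([[22.5, 10.0]], (5, 1)))
        labels, _ = zone_occupancy(track, two_chamber_arena)
        assert set(labels) == {"stim"}

    def test_alternating_sides_counting_oracle(self, two_chamber_arena):
        xy = np.tile([[10.0, 10.0], [35.0, 10.0]], (150, 1))  # 300 frames
        track = make_track(xy)
        labels, durations = zone_occupancy(track, two_chamber_arena)
        assert durations["stim"] == pytest.approx(5.0)
        assert durations["nonstim"] == pytest.approx(5.0)
        # brute-force recount
        count = sum(1 for x, _ in xy if x <= 22.5)
        assert durations["stim"] == pytest.approx(count / 30.0)

    def test_durations_conserve_session_time(self, two_chamber_arena):
        rng = np.random.default_rng(8)
        xy = rng.uniform([1, 1], [44, 19], size=(200, 2))
        track = make_track(xy)
        track.coords["centre"][rng.random(200) < 0.2] = np.nan
        labels, durations = zone_occupancy(track, two_chamber_arena)
        missing = sum(1 for z in labels if z is None) / 30.0
        assert sum(durations.values()) + missing == pytest.approx(
            track.duration, abs=1e-9)
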