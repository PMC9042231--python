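import numpy as np
import pytest

from ethoflight import (ArenaGeometry, Circle, Partition, PoseTrack,
                        Rectangle, SimSpec, default_barnes_arena,
                        default_two_chamber_arena)


@pytest.fixture
def barnes_arena() -> ArenaGeometry:
    """92-cm circular platform with a 10-cm shelter at one hole."""
    return default_barnes_arena()


@pytest.fixture
def two_chamber_arena() -> ArenaGeometry:
    return default_two_chamber_arena()


def make_track(centre_cm, frame_rate=30.0, px_per_cm=5.0, heading_deg=None,
               nose_offset=1.5, confidence=1.0) -> PoseTrack:
    """Build a PoseTrack from a centre path in cm.

    The nose is placed ``nose_offset`` cm ahead of the centre along
    ``heading_deg`` (0 = +y, clockwise; default: along the direction of
    travel, or +y when stationary); tail base mirrors it behind.
    """
    centre = np.asarray(centre_cm, dtype=float)
    n = len(centre)
    if heading_deg is None:
        d = np.diff(centre, axis=0)
        step_heading = np.degrees(np.arctan2(d[:, 0], d[:, 1]))
        moving = np.hypot(d[:, 0], d[:, 1]) > 0
        heading = np.zeros(n)
        last = 0.0
        for i in range(n - 1):
            if moving[i]:
                last = step_heading[i]
            heading[i] = last
        if n > 1:
            heading[-1] = last
    else:
        heading = np.broadcast_to(np.asarray(heading_deg, dtype=float), (n,))
    rad = np.radians(heading)
    u = np.column_stack([np.sin(rad), np.cos(rad)])
    nose = centre + nose_offset * u
    tail = centre - 2.0 * u
    coords = {"nose": nose * px_per_cm, "centre": centre * px_per_cm,
              "tail_base": tail * px_per_cm}
    conf = {p: np.full(n, confidence, dtype=float) for p in coords}
    return PoseTrack(frame_index=np.arange(n), coords=coords,
                     confidence=conf, frame_rate=frame_rate)


@pytest.fixture
def make_pose_track():
    return make_track
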