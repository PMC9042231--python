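"""Per-frame kinematic series derived from a pose track.

The quantities here mirror what shelter-escape assays report per frame:
locomotion speed of the body centre (cm/s), unsigned head-direction angle to
a target in [0, 180] degrees, Euclidean distance to a target (cm), and zone
occupancy (shelter / chamber labels) from a point-in-region test on the body
centre.

Speed uses centered finite differences (one-sided at the endpoints) followed
by a short moving average; the body centre is used rather than the nose
because nose jitter inflates speed estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, PoseDataError
from .io_formats import ArenaGeometry, PoseTrack

DEFAULT_SMOOTH_WINDOW = 5


@dataclass
class KinematicSeries:
    """Per-frame kinematics on the same timebase as the source track."""

    time: np.ndarray
    speed: np.ndarray                  # cm/s, NaN where centre missing
    head_angle: np.ndarray | None      # deg in [0, 180], NaN where undefined
    dist_to_target: np.ndarray | None  # cm
    in_shelter: np.ndarray | None      # bool
    zone: np.ndarray | None            # object labels, None where missing
    frame_rate: float

    def __len__(self) -> int:
        return len(self.time)

    def slice(self, t0: float, t1: float) -> "KinematicSeries":
        """Sub-series with t0 <= time < t1."""
        m = (self.time >= t0 - 1e-9) & (self.time < t1 - 1e-9)
        pick = lambda a: a[m] if a is not None else None
        return KinematicSeries(time=self.time[m], speed=self.speed[m],
                               head_angle=pick(self.head_angle),
                               dist_to_target=pick(self.dist_to_target),
                               in_shelter=pick(self.in_shelter),
                               zone=pick(self.zone), frame_rate=self.frame_rate)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy export: time, speed, head_angle, dist, zone."""
        data = {"time": self.time, "speed": self.speed}
        if self.head_angle is not None:
            data["head_angle"] = self.head_angle
        if self.dist_to_target is not None:
            data["dist"] = self.dist_to_target
        if self.zone is not None:
            data["zone"] = self.zone
        return pd.DataFrame(data)


def compute_speed(track: PoseTrack, geometry: ArenaGeometry,
                  smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Body-centre speed in cm/s.

    Centered finite differences over 2/frame_rate at interior frames,
    one-sided at the endpoints, then a centered moving average of
    ``smooth_window`` frames (odd, >= 1; 1 disables smoothing).  Frames where
    the centre is missing yield NaN both before and after smoothing.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    xy = track.xy_cm("centre", geometry)
    valid = np.all(np.isfinite(xy), axis=1)
    if valid.sum() < 2:
        raise PoseDataError("fewer than 2 valid centre frames; cannot compute speed")
    n = len(xy)
    dt = 1.0 / track.frame_rate
    vel = np.full((n, 2), np.nan)
    if n >= 3:
        vel[1:-1] = (xy[2:] - xy[:-2]) / (2.0 * dt)
    vel[0] = (xy[1] - xy[0]) / dt
    vel[-1] = (xy[-1] - xy[-2]) / dt
    raw = np.hypot(vel[:, 0], vel[:, 1])
    raw[~valid] = np.nan  # a frame with no centre has no speed
    if smooth_window == 1:
        return raw
    sm = (pd.Series(raw)
          .rolling(smooth_window, center=True, min_periods=1)
          .mean()
          .to_numpy())
    sm[np.isnan(raw)] = np.nan  # missing frames propagate
    return sm


def head_direction_angle(track: PoseTrack, geometry: ArenaGeometry,
                         target_cm: tuple[float, float]) -> np.ndarray:
    """Unsigned angle (deg, [0, 180]) between centre->nose and centre->target.

    NaN where nose or centre is missing, where the nose coincides with the
    centre (zero head vector), or where the centre sits on the target.
    """
    nose = track.xy_cm("nose", geometry)
    centre = track.xy_cm("centre", geometry)
    head = nose - centre
    to_target = np.asarray(target_cm, dtype=float) - centre
    nh = np.hypot(head[:, 0], head[:, 1])
    nt = np.hypot(to_target[:, 0], to_target[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (head[:, 0] * to_target[:, 0] + head[:, 1] * to_target[:, 1]) / (nh * nt)
    cosang = np.clip(cosang, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    ang[(nh == 0) | (nt == 0)] = np.nan
    return ang


def distance_to_target(track: PoseTrack, geometry: ArenaGeometry,
                       target_cm: tuple[float, float],
                       part: str = "centre") -> np.ndarray:
    """Per-frame Euclidean distance (cm) of ``part`` from a target point."""
    xy = track.xy_cm(part, geometry)
    t = np.asarray(target_cm, dtype=float)
    return np.hypot(xy[:, 0] - t[0], xy[:, 1] - t[1])


def zone_occupancy(track: PoseTrack, geometry: ArenaGeometry
                   ) -> tuple[np.ndarray, dict[str, float]]:
    """Per-frame zone labels plus per-zone total durations in seconds.

    The zone is assigned by a point-in-region test on the body centre
    (boundaries count as inside; a centre exactly on the partition line goes
    to the first-listed zone).  Frames with a missing centre get ``None`` and
    are excluded from the durations, so per-zone durations plus missing time
    always sum to the session duration.
    """
    if geometry.shelter is None and geometry.partition is None:
        raise ConfigError("geometry defines neither shelter nor partition")
    from collections import Counter

    labels = geometry.zone_of(track.xy_cm("centre", geometry))
    dt = 1.0 / track.frame_rate
    durations = {z: n * dt for z, n in Counter(labels).items() if z is not None}
    return labels, durations


def compute_kinematics(track: PoseTrack, geometry: ArenaGeometry,
                       target_cm: tuple[float, float] | None = None,
                       smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> KinematicSeries:
    """Bundle speed, head angle, target distance and zone labels.

    ``target_cm`` defaults to the shelter centre when the geometry has a
    shelter; head angle and distance are omitted when no target is available.
    """
    if target_cm is None and geometry.shelter is not None:
        target_cm = geometry.shelter_center
    speed = compute_speed(track, geometry, smooth_window=smooth_window)
    head = dist = None
    if target_cm is not None:
        head = head_direction_angle(track, geometry, target_cm)
        dist = distance_to_target(track, geometry, target_cm)
    zone = in_shelter = None
    if geometry.shelter is not None or geometry.partition is not None:
        zone, _ = zone_occupancy(track, geometry)
        in_shelter = np.asarray([z == "shelter" for z in zone], dtype=bool)
    return KinematicSeries(time=track.time, speed=speed, head_angle=head,
                           dist_to_target=dist, in_shelter=in_shelter,
                           zone=zone, frame_rate=track.frame_rate)
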