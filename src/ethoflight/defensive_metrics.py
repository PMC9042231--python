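"""Escape and freezing scores for defensive-behavior trials.

This module implements the trial-level statistics used to quantify
goal-directed escape to a remembered shelter and its breakdown:

* freezing bouts — maximal runs of sub-threshold speed sustained for a
  minimum duration (freezing = no locomotion besides respiration);
* running bouts — maximal runs of supra-threshold speed (default 30 cm/s,
  i.e. 0.3 m/s), merged across brief gaps;
* escape latency — time from stimulus onset until the animal is oriented at
  the shelter and moving toward it;
* escape accuracy — ``100% - 10% * (d / D)`` where ``d`` is the body-centre
  distance from the shelter at the trial evaluation time and ``D`` the
  shelter diameter;
* escape linearity — 100 x (path length) / (straight-line distance from the
  onset position to the shelter); 100% means a perfectly straight flight;
* time-to-max-speed, peak speed, success classification (body centre enters
  the shelter within the stimulus window);
* escape-run events out of an odor-paired chamber, defined by a within-event
  peak speed exceeding a multiple of the session's mean ambulation speed;
* speed / head-angle profiles against normalized distance from the shelter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io_formats import ArenaGeometry, Circle, PoseTrack, Region
from .kinematics import KinematicSeries, compute_kinematics

# defaults; the assays only define these verbally, so they are parameters
FREEZING_SPEED_THRESHOLD = 2.0   # cm/s
FREEZING_MIN_DURATION = 1.0      # s
RUNNING_SPEED_THRESHOLD = 30.0   # cm/s  (0.3 m/s)
RUNNING_MERGE_GAP = 0.2          # s
LATENCY_ANGLE_THRESHOLD = 45.0   # deg
LATENCY_MOVE_THRESHOLD = 2.0     # cm/s
LATENCY_SUSTAIN = 0.2            # s
ESCAPE_RUN_SPEED_FACTOR = 1.5    # x mean ambulation speed
STIMULUS_DURATION = 9.0          # s, ultrasound stimulus length
LINEARITY_EPSILON = 1.0          # cm, minimum onset->shelter displacement


@dataclass(frozen=True)
class Bout:
    """Half-open [start, end) interval of one behavior."""
    start: float
    end: float
    kind: str

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError("bout end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EscapeTrialResult:
    """Per-trial escape scores (times in s, speeds cm/s, scores in %)."""

    trial_id: int
    onset: float
    stimulus_duration: float
    start_x: float
    start_y: float
    arrived: bool
    arrival_time: float | None
    latency: float | None
    accuracy: float | None
    linearity: float | None
    time_to_max_speed: float | None
    peak_speed: float
    freezing_time: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where ``mask`` is True."""
    out = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_freezing(speed: np.ndarray, time: np.ndarray,
                    threshold: float = FREEZING_SPEED_THRESHOLD,
                    min_duration: float = FREEZING_MIN_DURATION
                    ) -> tuple[list[Bout], float]:
    """Freezing bouts (speed < threshold sustained >= min_duration) and total.

    NaN speed frames break bouts; an empty series yields no bouts.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_duration <= 0:
        raise ValueError("min_duration must be > 0")
    speed = np.asarray(speed, dtype=float)
    time = np.asarray(time, dtype=float)
    if len(speed) == 0:
        return [], 0.0
    dt = float(np.median(np.diff(time))) if len(time) > 1 else 0.0
    with np.errstate(invalid="ignore"):
        mask = speed < threshold
    mask &= np.isfinite(speed)
    bouts = []
    for i, j in _runs(mask):
        dur = (j - i) * dt
        if dur >= min_duration - 1e-9:
            bouts.append(Bout(start=time[i], end=time[i] + dur, kind="freezing"))
    return bouts, sum(b.duration for b in bouts)


def detect_running_bouts(speed: np.ndarray, time: np.ndarray,
                         threshold: float = RUNNING_SPEED_THRESHOLD,
                         merge_gap: float = RUNNING_MERGE_GAP) -> list[Bout]:
    """Running bouts: maximal runs with speed > threshold (default 0.3 m/s),
    merged across gaps <= ``merge_gap`` seconds."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    speed = np.asarray(speed, dtype=float)
    time = np.asarray(time, dtype=float)
    if len(speed) == 0:
        return []
    dt = float(np.median(np.diff(time))) if len(time) > 1 else 0.0
    with np.errstate(invalid="ignore"):
        mask = speed > threshold
    mask &= np.isfinite(speed)
    raw = [Bout(start=time[i], end=time[i] + (j - i) * dt, kind="running")
           for i, j in _runs(mask)]
    merged: list[Bout] = []
    for b in raw:
        if merged and b.start - merged[-1].end <= merge_gap + 1e-9:
            merged[-1] = Bout(start=merged[-1].start, end=b.end, kind="running")
        else:
            merged.append(b)
    return merged


def escape_latency(window: KinematicSeries,
                   move_threshold: float = LATENCY_MOVE_THRESHOLD,
                   angle_threshold: float = LATENCY_ANGLE_THRESHOLD,
                   sustain: float = LATENCY_SUSTAIN) -> float | None:
    """Latency (s) from window start until the animal has turned its head to
    the shelter (head angle < ``angle_threshold``) and is moving (speed >
    ``move_threshold``), sustained for ``sustain`` seconds.  ``None`` if the
    criterion is never met (e.g. the animal freezes the whole window)."""
    if window.head_angle is None:
        raise ConfigError("kinematic series lacks a shelter target (head angle)")
    n_sustain = max(1, int(round(sustain * window.frame_rate)))
    with np.errstate(invalid="ignore"):
        ok = (window.head_angle < angle_threshold) & (window.speed > move_threshold)
    ok &= np.isfinite(window.head_angle) & np.isfinite(window.speed)
    for i, j in _runs(ok):
        if j - i >= n_sustain:
            return float(window.time[i] - window.time[0])
    return None


def shelter_diameter(region: Region) -> float:
    """Characteristic shelter diameter (cm): the circle diameter, or the mean
    of width and height for a rectangular shelter box."""
    if isinstance(region, Circle):
        return 2.0 * region.radius
    return ((region.xmax - region.xmin) + (region.ymax - region.ymin)) / 2.0


def accuracy_from_distance(d: float, shelter_diameter: float,
                           clamp: bool = False) -> float:
    """Accuracy % = 100 - 10 * (d / D) for distance ``d`` (cm) from the
    shelter and shelter diameter ``D`` (cm).  By default not clamped below
    zero (the published formula has no clamp)."""
    if shelter_diameter <= 0:
        raise ValueError("shelter diameter must be > 0")
    acc = 100.0 - 10.0 * (d / shelter_diameter)
    return max(acc, 0.0) if clamp else acc


def escape_accuracy(dist: np.ndarray, time: np.ndarray, shelter_diameter: float,
                    eval_time: float, to_boundary: bool = False,
                    clamp: bool = False, max_gap_s: float = 0.5) -> float | None:
    """Accuracy evaluated at ``eval_time`` (min of arrival and stimulus end).

    The distance series ``dist`` is taken at the frame nearest ``eval_time``;
    if that frame is missing, the nearest valid frame within ``max_gap_s`` is
    used, otherwise ``None``.  ``to_boundary`` measures the miss distance to
    the shelter boundary instead of its center.
    """
    dist = np.asarray(dist, dtype=float)
    time = np.asarray(time, dtype=float)
    ok = np.isfinite(dist)
    if not ok.any():
        return None
    offsets = np.abs(time - eval_time)
    offsets[~ok] = np.inf
    i = int(np.argmin(offsets))
    if offsets[i] > max_gap_s:
        return None
    d = dist[i]
    if to_boundary:
        d = max(0.0, d - shelter_diameter / 2.0)
    return accuracy_from_distance(d, shelter_diameter, clamp=clamp)


def path_length(xy: np.ndarray) -> float:
    """Polyline length of a trajectory, skipping missing (NaN) rows."""
    xy = np.asarray(xy, dtype=float)
    xy = xy[np.all(np.isfinite(xy), axis=1)]
    if len(xy) < 2:
        return 0.0
    seg = np.diff(xy, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def escape_linearity(xy: np.ndarray, shelter_center: tuple[float, float],
                     epsilon: float = LINEARITY_EPSILON) -> float | None:
    """Linearity % = 100 x path length / straight-line onset->shelter distance.

    ``xy`` is the centre trajectory (cm) from escape onset to shelter
    arrival; defined only when the onset position is more than ``epsilon``
    cm from the shelter (otherwise ``None``).  Because arrival is scored
    when the centre crosses the shelter boundary, the sampled path is closed
    to the shelter center before measuring, so linearity is always >= 100,
    with equality iff the samples are collinear with the shelter.
    """
    xy = np.asarray(xy, dtype=float)
    valid = xy[np.all(np.isfinite(xy), axis=1)]
    if len(valid) == 0:
        return None
    chord = math.hypot(valid[0, 0] - shelter_center[0],
                       valid[0, 1] - shelter_center[1])
    if chord <= epsilon:
        return None
    closed = np.vstack([valid, np.asarray(shelter_center, dtype=float)])
    return 100.0 * path_length(closed) / chord


def time_to_max_speed(speed: np.ndarray, time: np.ndarray,
                      movement_onset: float | None = None) -> float | None:
    """Time (s) from escape-movement onset to the first frame attaining the
    window's maximum speed.  Ties break to the first occurrence; an empty or
    all-missing window yields ``None``."""
    speed = np.asarray(speed, dtype=float)
    time = np.asarray(time, dtype=float)
    if len(speed) == 0 or not np.isfinite(speed).any():
        return None
    i = int(np.nanargmax(speed))
    t0 = movement_onset if movement_onset is not None else time[0]
    return float(time[i] - t0)


def classify_success(in_shelter: np.ndarray, time: np.ndarray, onset: float,
                     window: float = STIMULUS_DURATION, grace: float = 0.0) -> bool:
    """True iff the body centre enters the shelter region within
    [onset, onset + window + grace]."""
    in_shelter = np.asarray(in_shelter, dtype=bool)
    time = np.asarray(time, dtype=float)
    m = (time >= onset - 1e-9) & (time <= onset + window + grace + 1e-9)
    return bool(in_shelter[m].any())


def arrival_time(in_shelter: np.ndarray, time: np.ndarray, onset: float,
                 window: float = STIMULUS_DURATION, grace: float = 0.0
                 ) -> float | None:
    """First time >= onset (within the stimulus window) the centre is inside
    the shelter; ``None`` if it never enters."""
    in_shelter = np.asarray(in_shelter, dtype=bool)
    time = np.asarray(time, dtype=float)
    m = (time >= onset - 1e-9) & (time <= onset + window + grace + 1e-9) & in_shelter
    idx = np.flatnonzero(m)
    return float(time[idx[0]]) if len(idx) else None


def detect_escape_runs(zone: np.ndarray, speed: np.ndarray, time: np.ndarray,
                       odor_zone: str,
                       speed_factor: float = ESCAPE_RUN_SPEED_FACTOR,
                       move_threshold: float = LATENCY_MOVE_THRESHOLD,
                       window_s: float = 0.5) -> tuple[int, list[float]]:
    """Escape-run events: crossings out of the odor-paired chamber whose
    within-event peak speed exceeds ``speed_factor`` x the session's mean
    ambulation speed (mean over frames moving faster than
    ``move_threshold``).  Returns the count and the crossing times.
    """
    zone = np.asarray(zone, dtype=object)
    speed = np.asarray(speed, dtype=float)
    time = np.asarray(time, dtype=float)
    present = {z for z in zone if z is not None}
    if odor_zone not in present:
        raise ConfigError(
            f"odor zone {odor_zone!r} not among session zones {sorted(map(str, present))}")
    with np.errstate(invalid="ignore"):
        moving = speed > move_threshold
    moving &= np.isfinite(speed)
    if not moving.any():
        return 0, []
    mean_amb = float(speed[moving].mean())
    events: list[float] = []
    for i in range(1, len(zone)):
        if zone[i - 1] == odor_zone and zone[i] is not None and zone[i] != odor_zone:
            t = time[i]
            w = (time >= t - window_s) & (time <= t + window_s)
            if np.isfinite(speed[w]).any():
                peak = float(np.nanmax(speed[w]))
                if peak > speed_factor * mean_amb:
                    events.append(float(t))
    return len(events), events


def profile_vs_normalized_distance(trials: list[KinematicSeries],
                                   n_bins: int = 20) -> pd.DataFrame:
    """Binned mean speed and head angle against normalized shelter distance.

    Each trial (an onset-to-arrival kinematic slice with a shelter target)
    has its distance normalized by the onset distance; frames fall into
    ``n_bins`` equal bins on [0, 1].  Returns per-bin mean and sd across
    trials.  Trials with zero onset distance are excluded; an empty trial
    list (or all-excluded) is an error.
    """
    if not trials:
        raise ValueError("no trials supplied")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    per_trial_speed, per_trial_angle = [], []
    for tr in trials:
        if tr.dist_to_target is None:
            raise ConfigError("trial lacks distance-to-shelter series")
        d = np.asarray(tr.dist_to_target, dtype=float)
        ok = np.isfinite(d)
        if not ok.any() or d[ok][0] <= 0:
            continue
        nd = np.clip(d / d[ok][0], 0.0, 1.0)
        which = np.clip(np.digitize(nd, edges) - 1, 0, n_bins - 1)
        sp = np.full(n_bins, np.nan)
        an = np.full(n_bins, np.nan)
        for b in range(n_bins):
            m = (which == b) & ok
            if m.any():
                sp[b] = np.nanmean(tr.speed[m])
                if tr.head_angle is not None:
                    an[b] = np.nanmean(tr.head_angle[m])
        per_trial_speed.append(sp)
        per_trial_angle.append(an)
    if not per_trial_speed:
        raise ValueError("no usable trials (all had zero onset distance)")
    S = np.vstack(per_trial_speed)
    A = np.vstack(per_trial_angle)
    import warnings

    with warnings.catch_warnings():
        # bins no trial visited are reported as NaN, not warned about
        warnings.simplefilter("ignore", RuntimeWarning)
        df = pd.DataFrame({
            "bin_center": (edges[:-1] + edges[1:]) / 2.0,
            "speed_mean": np.nanmean(S, axis=0),
            "speed_sd": np.nanstd(S, axis=0),
            "angle_mean": np.nanmean(A, axis=0),
            "angle_sd": np.nanstd(A, axis=0),
            "n_trials": np.sum(np.isfinite(S), axis=0),
        })
    return df


def score_escape_trial(track: PoseTrack, geometry: ArenaGeometry, onset: float,
                       stimulus_duration: float = STIMULUS_DURATION,
                       grace: float = 0.0, trial_id: int = 0,
                       smooth_window: int = 5,
                       freezing_threshold: float = FREEZING_SPEED_THRESHOLD,
                       freezing_min_duration: float = FREEZING_MIN_DURATION,
                       clamp_accuracy: bool = False) -> EscapeTrialResult:
    """Score one escape trial end to end.

    Evaluation windows follow the assay conventions: accuracy is evaluated at
    min(arrival time, stimulus end), with arrived trials scored as a direct
    hit (distance 0, accuracy 100); linearity is defined for arrived trials
    only; freezing is summed between onset and min(arrival, stimulus end);
    time-to-max-speed is measured from the detected escape-movement onset.
    """
    if geometry.shelter is None:
        raise ConfigError("escape scoring requires a shelter region")
    kin = compute_kinematics(track, geometry, smooth_window=smooth_window)
    stim_end = onset + stimulus_duration
    arr = arrival_time(kin.in_shelter, kin.time, onset, stimulus_duration, grace)
    arrived = arr is not None
    window_end = arr if arrived else stim_end
    win = kin.slice(onset, window_end + 1.0 / kin.frame_rate)

    latency = escape_latency(win)
    shelter_diam = shelter_diameter(geometry.shelter)
    if arrived:
        accuracy = accuracy_from_distance(0.0, shelter_diam, clamp=clamp_accuracy)
    else:
        accuracy = escape_accuracy(kin.dist_to_target, kin.time, shelter_diam,
                                   eval_time=stim_end, clamp=clamp_accuracy)
    xy = track.xy_cm("centre", geometry)
    m = (kin.time >= onset - 1e-9) & (kin.time <= window_end + 1e-9)
    linearity = (escape_linearity(xy[m], geometry.shelter_center)
                 if arrived else None)

    movement_onset = onset + latency if latency is not None else onset
    tmax = time_to_max_speed(win.speed, win.time, movement_onset=movement_onset)
    peak = float(np.nanmax(win.speed)) if np.isfinite(win.speed).any() else float("nan")
    _, freezing_total = detect_freezing(win.speed, win.time,
                                        threshold=freezing_threshold,
                                        min_duration=freezing_min_duration)
    start = xy[np.searchsorted(kin.time, onset - 1e-9)]
    return EscapeTrialResult(
        trial_id=trial_id, onset=onset, stimulus_duration=stimulus_duration,
        start_x=float(start[0]), start_y=float(start[1]),
        arrived=arrived, arrival_time=arr, latency=latency,
        accuracy=accuracy, linearity=linearity, time_to_max_speed=tmax,
        peak_speed=peak, freezing_time=freezing_total,
    )
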