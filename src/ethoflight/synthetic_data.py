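"""Ground-truthed synthetic inputs for every pipeline stage.

No public recordings accompany the behavioral assays this package scores, so
each analysis stage ships with a generator that emulates the relevant raw
data and emits a machine-readable ground-truth record for tests:

* goal-directed escapes — the animal turns to the shelter, then runs a
  near-straight path whose speed follows a raised cosine peaking at the path
  midpoint (the signature of shelter-directed flight);
* disorganized escapes — slow flights whose heading wanders around the
  shelter bearing with AR(1) noise; a single ``disorganization`` parameter
  scales both the heading noise and the collapse of running speed;
* two-chamber sessions — a two-state continuous-time Markov occupancy model
  whose stay time in the stimulated chamber shrinks with an avoidance
  parameter, with a closed-form expected aversion index;
* restraint sensor traces — i.i.d. Bernoulli movement samples;
* c-Fos ROI images — circular Gaussian-profile cells plus elongated bar
  artifacts on a noisy background.

All randomness flows from ``SimSpec.seed`` through numpy's default
PCG64 generator, so every output is bit-for-bit reproducible per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import GeometryError
from .epoch_analysis import BinaryMovementSeries
from .io_formats import (ArenaGeometry, Circle, Partition, PoseTrack,
                         Rectangle)

V_FLOOR = 5.0          # cm/s, minimum commanded speed once escape has begun
NOSE_OFFSET = 1.5      # cm ahead of the body centre
TAIL_OFFSET = 2.0      # cm behind the body centre
AR1_PHI = 0.9          # heading-noise autocorrelation per frame at 30 Hz
HEADING_SD_PER_LEVEL = 50.0   # deg of AR(1) stationary sd per disorganization unit
HEADING_CLIP_DEG = 80.0       # keeps radial progress positive -> arrival certain
SPEED_COLLAPSE = 14.0         # v = v_max / (1 + SPEED_COLLAPSE * disorganization)


@dataclass(frozen=True)
class SimSpec:
    """Simulation parameters; ``seed`` fixes every output bit-for-bit."""

    seed: int
    frame_rate: float = 30.0
    v_max: float = 60.0            # cm/s peak goal-directed running speed
    turn_rate: float = 360.0       # deg/s orient-to-shelter turning speed
    disorganization: float = 0.0   # heading-noise scale, >= 0
    freeze_prob: float = 0.0       # per-second probability of a 1-s freeze
    avoidance_strength: float = 0.0
    noise_sd: float = 0.1          # cm positional tracking jitter

    def __post_init__(self):
        if self.frame_rate <= 0 or self.v_max <= 0 or self.turn_rate <= 0:
            raise ValueError("frame_rate, v_max and turn_rate must be positive")
        if (self.disorganization < 0 or self.avoidance_strength < 0
                or self.noise_sd < 0 or not 0 <= self.freeze_prob <= 1):
            raise ValueError("parameter outside its domain")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# standard arenas
# ---------------------------------------------------------------------------

def default_barnes_arena(px_per_cm: float = 5.0) -> ArenaGeometry:
    """92-cm circular platform with 20 equally spaced holes and a shelter box
    (modeled as a 10-cm circle) at one hole position."""
    hole_r = 38.5  # hole centers: 5-cm holes 5 cm in from the border
    holes = [(hole_r * math.sin(2 * math.pi * k / 20),
              hole_r * math.cos(2 * math.pi * k / 20)) for k in range(20)]
    return ArenaGeometry(
        px_per_cm=px_per_cm,
        arena=Circle(center=(0.0, 0.0), radius=46.0),
        shelter=Circle(center=(0.0, -36.0), radius=5.0),
        holes=holes)


def default_two_chamber_arena(px_per_cm: float = 5.0,
                              zones: tuple[str, str] = ("stim", "nonstim")
                              ) -> ArenaGeometry:
    """45 x 20 cm two-chamber box split at the midline."""
    return ArenaGeometry(
        px_per_cm=px_per_cm,
        arena=Rectangle(0.0, 45.0, 0.0, 20.0),
        partition=Partition(axis="x", value=22.5, zones=zones))


# ---------------------------------------------------------------------------
# pose assembly
# ---------------------------------------------------------------------------

def _pose_from_path(centre_cm: np.ndarray, heading_deg: np.ndarray,
                    spec: SimSpec, geometry: ArenaGeometry,
                    rng: np.random.Generator) -> PoseTrack:
    """Assemble a 3-part pose track from a centre path and heading series."""
    n = len(centre_cm)
    rad = np.radians(heading_deg)
    u = np.column_stack([np.sin(rad), np.cos(rad)])  # unit heading
    jitter = rng.normal(0.0, spec.noise_sd, size=(n, 2))
    centre = centre_cm + jitter
    nose = centre + NOSE_OFFSET * u
    tail = centre - TAIL_OFFSET * u
    coords = {"nose": geometry.to_px(nose), "centre": geometry.to_px(centre),
              "tail_base": geometry.to_px(tail)}
    conf = {p: np.ones(n) for p in coords}
    return PoseTrack(frame_index=np.arange(n), coords=coords,
                     confidence=conf, frame_rate=spec.frame_rate)


def _bearing_deg(frm: np.ndarray, to: np.ndarray) -> float:
    """Heading (deg, 0 = +y, clockwise positive) from one point to another."""
    d = np.asarray(to, dtype=float) - np.asarray(frm, dtype=float)
    return math.degrees(math.atan2(d[0], d[1]))


# ---------------------------------------------------------------------------
# escape simulators
# ---------------------------------------------------------------------------

def sim_goal_directed_escape(spec: SimSpec, arena: ArenaGeometry,
                             onset_pos: tuple[float, float],
                             onset_delay: float = 0.0,
                             max_duration: float = 9.0,
                             hold_after_arrival: float = 0.5
                             ) -> tuple[PoseTrack, dict]:
    """Goal-directed escape: orient to the shelter, then run straight at it
    with a raised-cosine speed profile peaking at the path midpoint.

    During ``onset_delay`` the agent sits still facing away from the
    shelter, completing its turn (at ``spec.turn_rate``) within the delay so
    movement starts shelter-oriented at exactly the commanded onset.  With
    zero positional jitter the trajectory is perfectly straight (linearity
    100%) and always arrives, so accuracy is 100 by construction.
    """
    if arena.shelter is None:
        raise GeometryError("goal-directed escape needs a shelter")
    p0 = np.asarray(onset_pos, dtype=float)
    if bool(arena.in_shelter(p0)[0]):
        raise GeometryError("onset position lies inside the shelter")
    rng = spec.rng()
    S = np.asarray(arena.shelter_center, dtype=float)
    L = float(np.hypot(*(S - p0)))
    dt = 1.0 / spec.frame_rate
    bearing = _bearing_deg(p0, S)
    turn_time = min(180.0 / spec.turn_rate, onset_delay) if onset_delay > 0 else 0.0

    centre, heading = [], []
    t, traveled = 0.0, 0.0
    pos = p0.copy()
    arrival = None
    peak_time = None
    while t < max_duration - 1e-9:
        if t < onset_delay - 1e-9:
            # stationary; rotate into the shelter bearing over the last
            # turn_time seconds of the delay
            if turn_time > 0 and t >= onset_delay - turn_time:
                frac = (t - (onset_delay - turn_time)) / turn_time
                h = bearing + 180.0 * (1.0 - frac)
            else:
                h = bearing + 180.0
            v = 0.0
        else:
            u = min(traveled / L, 1.0)
            v = V_FLOOR + (spec.v_max - V_FLOOR) * 0.5 * (1.0 - math.cos(2 * math.pi * u))
            if peak_time is None and u >= 0.5:
                peak_time = t
            h = bearing
            step = v * dt
            direction = (S - pos)
            dist = float(np.hypot(*direction))
            if dist > 0:
                pos = pos + direction / dist * min(step, dist)
            traveled += step
        centre.append(pos.copy())
        heading.append(h)
        if arrival is None and bool(arena.in_shelter(pos)[0]):
            arrival = t
        if arrival is not None and t >= arrival + hold_after_arrival:
            break
        t += dt

    centre = np.asarray(centre)
    heading = np.asarray(heading)
    track = _pose_from_path(centre, heading, spec, arena, rng)
    truth = {"kind": "goal_directed", "movement_onset": onset_delay,
             "arrival_time": arrival, "peak_time": peak_time,
             "onset_pos": tuple(p0), "shelter_center": tuple(S),
             "path_cm": centre, "chord_cm": L}
    return track, truth


def sim_disorganized_escape(spec: SimSpec, arena: ArenaGeometry,
                            onset_pos: tuple[float, float],
                            max_duration: float = 9.0) -> tuple[PoseTrack, dict]:
    """Slow, disorganized flight: heading = shelter bearing + AR(1) noise.

    The ``disorganization`` level d sets the stationary heading-noise sd
    (50 deg per unit, clipped at +/-80 deg so the radial component of motion
    stays positive) and collapses speed as v_max / (1 + 14 d), emulating the
    slow meandering flights seen without a remembered shelter.  At d = 0 the
    flight is straight at v_max and recovers goal-directed statistics.
    ``freeze_prob`` interleaves 1-s freezing pauses.
    """
    if arena.shelter is None:
        raise GeometryError("escape simulation needs a shelter target")
    p0 = np.asarray(onset_pos, dtype=float)
    if bool(arena.in_shelter(p0)[0]):
        raise GeometryError("onset position lies inside the shelter")
    rng = spec.rng()
    S = np.asarray(arena.shelter_center, dtype=float)
    d = spec.disorganization
    v = spec.v_max / (1.0 + SPEED_COLLAPSE * d)
    sd = HEADING_SD_PER_LEVEL * d
    innov_sd = sd * math.sqrt(1.0 - AR1_PHI ** 2)
    dt = 1.0 / spec.frame_rate

    centre, heading = [], []
    pos = p0.copy()
    e = rng.normal(0.0, sd) if sd > 0 else 0.0
    arrival = None
    freeze_left = 0.0
    t = 0.0
    while t < max_duration - 1e-9:
        bearing = _bearing_deg(pos, S)
        if sd > 0:
            e = AR1_PHI * e + rng.normal(0.0, innov_sd)
        e_clipped = float(np.clip(e, -HEADING_CLIP_DEG, HEADING_CLIP_DEG))
        h = bearing + e_clipped
        if freeze_left > 0:
            step = 0.0
            freeze_left -= dt
        else:
            if spec.freeze_prob > 0 and rng.random() < spec.freeze_prob * dt:
                freeze_left = 1.0
                step = 0.0
            else:
                step = v * dt
        rad = math.radians(h)
        cand = pos + step * np.array([math.sin(rad), math.cos(rad)])
        # reflect off the arena wall by clamping to the boundary
        if not bool(arena.arena.contains(cand)[0]):
            if isinstance(arena.arena, Circle):
                c = np.asarray(arena.arena.center)
                r = float(np.hypot(*(cand - c)))
                cand = c + (cand - c) * (arena.arena.radius / r)
            else:
                cand[0] = np.clip(cand[0], arena.arena.xmin, arena.arena.xmax)
                cand[1] = np.clip(cand[1], arena.arena.ymin, arena.arena.ymax)
        pos = cand
        centre.append(pos.copy())
        heading.append(h)
        if arrival is None and bool(arena.in_shelter(pos)[0]):
            arrival = t
            break
        t += dt

    centre = np.asarray(centre)
    heading = np.asarray(heading)
    track = _pose_from_path(centre, heading, spec, arena, rng)
    truth = {"kind": "disorganized", "arrival_time": arrival,
             "onset_pos": tuple(p0), "shelter_center": tuple(S),
             "path_cm": centre, "commanded_speed": v,
             "disorganization": d}
    return track, truth


# ---------------------------------------------------------------------------
# two-chamber occupancy
# ---------------------------------------------------------------------------

@dataclass
class ChamberSession:
    """Per-frame chamber occupancy from the two-state Markov model."""
    time: np.ndarray
    zone: np.ndarray            # object array of labels
    frame_rate: float
    truth: dict = field(default_factory=dict)


def expected_aversion(avoidance_strength: float) -> float:
    """Stationary aversion index of the occupancy model: -a / (2 + a).

    The leave rate from the stimulated chamber is (1 + a) times the baseline
    leave rate, so the stationary occupancy of that chamber is 1 / (2 + a);
    a = 0 gives index 0 and a -> infinity gives -1.
    """
    a = avoidance_strength
    return -a / (2.0 + a)


def avoidance_for_aversion(index: float) -> float:
    """Inverse of :func:`expected_aversion` (valid for index in (-1, 0])."""
    if not -1.0 < index <= 0.0:
        raise ValueError("expected aversion index must lie in (-1, 0]")
    return -2.0 * index / (1.0 + index)


def sim_two_chamber(spec: SimSpec, duration: float = 1200.0,
                    stim_side: str = "stim",
                    zones: tuple[str, str] = ("stim", "nonstim"),
                    base_leave_rate: float = 0.05) -> ChamberSession:
    """Two-state continuous-time Markov chamber occupancy.

    The agent leaves the non-stimulated chamber at ``base_leave_rate`` (per
    second; mean stay 20 s by default) and the stimulated chamber at
    ``base_leave_rate * (1 + avoidance_strength)``.  Truth records the
    avoidance level and the closed-form expected aversion index.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if stim_side not in zones:
        raise ValueError(f"stim_side {stim_side!r} not in zones {zones}")
    rng = spec.rng()
    a = spec.avoidance_strength
    other = zones[0] if zones[1] == stim_side else zones[1]
    rates = {stim_side: base_leave_rate * (1.0 + a), other: base_leave_rate}
    n_frames = int(round(duration * spec.frame_rate))
    labels = np.empty(n_frames, dtype=object)
    state = zones[rng.integers(0, 2)]
    i = 0
    while i < n_frames:
        stay = rng.exponential(1.0 / rates[state])
        k = max(1, int(round(stay * spec.frame_rate)))
        k = min(k, n_frames - i)
        labels[i:i + k] = state
        i += k
        state = other if state == stim_side else stim_side
    time = np.arange(n_frames) / spec.frame_rate
    truth = {"avoidance_strength": a,
             "expected_aversion": expected_aversion(a),
             "stim_side": stim_side, "zones": zones}
    return ChamberSession(time=time, zone=labels, frame_rate=spec.frame_rate,
                          truth=truth)


def sim_conditioning_pair(spec: SimSpec, shift: float,
                          duration_pre: float = 300.0,
                          duration_post: float = 300.0,
                          stim_side: str = "stim",
                          zones: tuple[str, str] = ("stim", "nonstim")
                          ) -> tuple[ChamberSession, ChamberSession, dict]:
    """Pre/post session pair with a planted conditioning shift.

    The pre session uses ``spec.avoidance_strength``; the post session's
    avoidance is chosen so that the expected post aversion index equals the
    expected pre index plus ``shift``, making ``shift`` the expected
    conditioned place aversion (CPA) index.
    """
    pre_expected = expected_aversion(spec.avoidance_strength)
    post_expected = pre_expected + shift
    a_post = avoidance_for_aversion(post_expected)
    seeds = np.random.SeedSequence(spec.seed).spawn(2)
    pre = sim_two_chamber(replace(spec, seed=int(seeds[0].generate_state(1)[0] % (2**31))),
                          duration=duration_pre, stim_side=stim_side, zones=zones)
    post_spec = replace(spec,
                        seed=int(seeds[1].generate_state(1)[0] % (2**31)),
                        avoidance_strength=a_post)
    post = sim_two_chamber(post_spec, duration=duration_post,
                           stim_side=stim_side, zones=zones)
    truth = {"shift": shift, "expected_pre": pre_expected,
             "expected_post": post_expected, "avoidance_post": a_post}
    return pre, post, truth


# ---------------------------------------------------------------------------
# restraint and freezing series
# ---------------------------------------------------------------------------

def sim_restraint(spec: SimSpec, duration: float = 1800.0,
                  p_move: float = 0.3,
                  sample_rate: float = 10.0) -> BinaryMovementSeries:
    """i.i.d. Bernoulli(p_move) restraint-sensor movement samples."""
    if not 0.0 <= p_move <= 1.0:
        raise ValueError("p_move must be in [0, 1]")
    rng = spec.rng()
    n = int(round(duration * sample_rate))
    movement = (rng.random(n) < p_move).astype(np.int8)
    time = np.arange(n) / sample_rate
    return BinaryMovementSeries(time=time, movement=movement,
                                sample_rate=sample_rate)


def sim_freezing_speed_series(spec: SimSpec, duration: float = 60.0,
                              bout_durations: tuple[float, ...] = (3.0, 4.0, 5.0),
                              base_speed: float = 10.0,
                              freeze_speed: float = 0.3,
                              speed_jitter: float = 0.5
                              ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Speed series with planted freezing bouts at random, separated onsets.

    Returns (speed, time, truth); truth lists the planted bouts (aligned to
    frame boundaries) and their total duration.
    """
    rng = spec.rng()
    fps = spec.frame_rate
    n = int(round(duration * fps))
    time = np.arange(n) / fps
    speed = np.abs(base_speed + rng.normal(0.0, speed_jitter, n))
    # place bouts without overlap, separated by at least 1 s
    placed: list[tuple[float, float]] = []
    for dur in bout_durations:
        for _ in range(1000):
            start = rng.uniform(0.0, duration - dur)
            start = round(start * fps) / fps
            if all(start + dur + 1.0 <= s or start >= s + d + 1.0
                   for s, d in placed):
                placed.append((start, dur))
                break
        else:
            raise RuntimeError("could not place freezing bouts without overlap")
    for start, dur in placed:
        i0, i1 = int(round(start * fps)), int(round((start + dur) * fps))
        speed[i0:i1] = np.abs(rng.normal(freeze_speed, 0.1, i1 - i0))
    truth = {"bouts": sorted(placed), "total": float(sum(d for _, d in placed))}
    return speed, time, truth


# ---------------------------------------------------------------------------
# c-Fos ROI images
# ---------------------------------------------------------------------------

def sim_fos_image(spec: SimSpec, n_cells: int = 10, n_artifacts: int = 5,
                  size: int = 256, cell_radius: float = 6.0,
                  bar_length: float = 30.0, bar_width: float = 4.5,
                  amplitude: float = 1.0, background: float = 0.1,
                  noise: float = 0.02, max_tries: int = 5000
                  ) -> tuple[np.ndarray, dict]:
    """Synthetic ROI image: circular cells plus elongated bar artifacts.

    Cells are radial Gaussian blobs of nominal radius ``cell_radius``; bars
    are capsules of length ``bar_length`` and width ``bar_width`` (aspect
    ratio >= 3) at random orientations.  Objects are placed without overlap
    on a noisy background; truth lists positions and classes.  Raises if the
    requested objects cannot be placed.
    """
    rng = spec.rng()
    margin = bar_length / 2.0 + 4.0
    min_sep = bar_length + 2.0 * cell_radius
    centers: list[tuple[float, float]] = []
    for _ in range(n_cells + n_artifacts):
        for _ in range(max_tries):
            c = rng.uniform(margin, size - margin, 2)
            if all(np.hypot(c[0] - x, c[1] - y) >= min_sep for x, y in centers):
                centers.append((float(c[0]), float(c[1])))
                break
        else:
            raise RuntimeError("could not place objects without overlap; "
                               "reduce counts or enlarge the image")
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = np.full((size, size), background)
    sigma_cell = cell_radius / 1.6
    cells = centers[:n_cells]
    bars = []
    for cx, cy in cells:
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        img += amplitude * np.exp(-r2 / (2.0 * sigma_cell ** 2))
    sigma_bar = bar_width / 2.35
    half = (bar_length - bar_width) / 2.0
    for cx, cy in centers[n_cells:]:
        theta = rng.uniform(0.0, math.pi)
        ux, uy = math.cos(theta), math.sin(theta)
        # distance from each pixel to the bar's central segment
        px, py = xx - cx, yy - cy
        tproj = np.clip(px * ux + py * uy, -half, half)
        d2 = (px - tproj * ux) ** 2 + (py - tproj * uy) ** 2
        img += amplitude * np.exp(-d2 / (2.0 * sigma_bar ** 2))
        bars.append((cx, cy, theta))
    img += rng.normal(0.0, noise, img.shape)
    truth = {"cells": cells, "artifacts": bars, "size": size,
             "cell_radius": cell_radius, "bar_length": bar_length,
             "bar_width": bar_width}
    return img, truth
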