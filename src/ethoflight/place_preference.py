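"""Real-time and conditioned place-aversion indices for two-chamber sessions.

Index conventions (all unitless):

* preference index (pre-conditioning) = (time in preferred side - time in
  less preferred side) / total chamber time, in [0, 1] because the preferred
  side is by definition the larger-occupancy one;
* aversion index = (time in stimulation side - time in non-stimulation
  side) / total chamber time, in [-1, 1]; -1 is complete avoidance;
* conditioned place aversion (CPA) index = post-conditioning aversion index
  minus pre-conditioning aversion index, in [-2, 2].

Time "in" a chamber counts only frames with a valid tracked body centre;
denominators use this valid time, so tracking dropouts shrink both numerator
and denominator rather than biasing the index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .io_formats import ArenaGeometry, PoseTrack

DEFAULT_BIN_S = 300.0  # 5-min bins: a 20-min session yields 4 bins


@dataclass
class BinnedIndex:
    start: float
    end: float
    index: float | None     # None when the bin holds no valid frames
    valid_time: float       # s of valid occupancy inside the bin
    partial: bool = False   # final bin shorter than the nominal width


@dataclass
class PreferenceResult:
    """Session-level place-preference summary."""
    pre_index: float | None
    aversion_index: float
    cpa_index: float | None
    binned_aversion: list[BinnedIndex] = field(default_factory=list)
    distance_travelled: float | None = None


def occupancy_durations(zone: np.ndarray, frame_rate: float,
                        zones: tuple[str, str] | None = None) -> dict[str, float]:
    """Per-zone durations (s) from per-frame labels; ``None`` frames excluded.

    When ``zones`` is given, both labels are present in the result (possibly
    with zero time), which is what the index functions expect.
    """
    from collections import Counter

    dt = 1.0 / frame_rate
    out: dict[str, float] = {z: 0.0 for z in zones} if zones else {}
    for z, n in Counter(zone).items():
        if z is not None:
            out[z] = out.get(z, 0.0) + n * dt
    return out


def preference_index(occupancy: dict[str, float]) -> float:
    """(t_preferred - t_other) / t_total for a two-zone occupancy table."""
    if len(occupancy) != 2:
        raise ValueError("preference index needs exactly two zones")
    total = sum(occupancy.values())
    if total <= 0:
        raise ValueError("zero total occupancy time")
    a, b = sorted(occupancy.values())
    return (b - a) / total


def aversion_index(occupancy: dict[str, float], stim_side: str) -> float:
    """(t_stim - t_nonstim) / t_total; -1 when the stimulation side is never
    entered, 0 for equal occupancy."""
    if stim_side not in occupancy:
        raise ValueError(f"unknown stimulation side {stim_side!r}; "
                         f"zones are {sorted(occupancy)}")
    total = sum(occupancy.values())
    if total <= 0:
        raise ValueError("zero total occupancy time")
    t_stim = occupancy[stim_side]
    return (t_stim - (total - t_stim)) / total


def cpa_index(pre: float, post: float) -> float:
    """Conditioned place aversion: post-conditioning minus pre-conditioning
    aversion index (same side labeling for both)."""
    return post - pre


def binned_aversion(zone: np.ndarray, frame_rate: float, stim_side: str,
                    bin_s: float = DEFAULT_BIN_S,
                    zones: tuple[str, str] | None = None) -> list[BinnedIndex]:
    """Aversion index per time bin (default 5 min).

    The session is split into consecutive bins of ``bin_s`` seconds; a final
    partial bin is kept but flagged.  The session-level index always equals
    the valid-time-weighted mean of the bin indices.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be > 0")
    zone = np.asarray(zone, dtype=object)
    n_per_bin = int(round(bin_s * frame_rate))
    if n_per_bin < 1:
        raise ValueError("bin width shorter than one frame")
    out: list[BinnedIndex] = []
    dt = 1.0 / frame_rate
    for i0 in range(0, len(zone), n_per_bin):
        chunk = zone[i0:i0 + n_per_bin]
        occ = occupancy_durations(chunk, frame_rate, zones=zones)
        valid = sum(occ.values())
        idx = aversion_index(occ, stim_side) if valid > 0 else None
        out.append(BinnedIndex(start=i0 * dt, end=(i0 + len(chunk)) * dt,
                               index=idx, valid_time=valid,
                               partial=len(chunk) < n_per_bin))
    return out


def distance_travelled(track: PoseTrack, geometry: ArenaGeometry,
                       smooth_window: int = 5) -> float:
    """Total centre path length (cm) over valid frames after position
    smoothing; displacement across missing gaps is not counted."""
    import pandas as pd

    xy = track.xy_cm("centre", geometry)
    if smooth_window > 1:
        xy = (pd.DataFrame(xy)
              .rolling(smooth_window, center=True, min_periods=1)
              .mean()
              .to_numpy())
        xy[~track.valid("centre")] = np.nan
    seg = np.diff(xy, axis=0)
    d = np.hypot(seg[:, 0], seg[:, 1])
    return float(np.nansum(d))


def score_place_session(zone: np.ndarray, frame_rate: float, stim_side: str,
                        bin_s: float = DEFAULT_BIN_S,
                        zones: tuple[str, str] | None = None,
                        pre_zone: np.ndarray | None = None,
                        track: PoseTrack | None = None,
                        geometry: ArenaGeometry | None = None) -> PreferenceResult:
    """Bundle session indices; ``pre_zone`` (a habituation/pre-conditioning
    label series) enables the preference and CPA indices."""
    occ = occupancy_durations(zone, frame_rate, zones=zones)
    av = aversion_index(occ, stim_side)
    pre = cpa = None
    if pre_zone is not None:
        pre_occ = occupancy_durations(pre_zone, frame_rate, zones=zones)
        pre = aversion_index(pre_occ, stim_side)
        cpa = cpa_index(pre, av)
    dist = (distance_travelled(track, geometry)
            if track is not None and geometry is not None else None)
    return PreferenceResult(
        pre_index=pre, aversion_index=av, cpa_index=cpa,
        binned_aversion=binned_aversion(zone, frame_rate, stim_side,
                                        bin_s=bin_s, zones=zones),
        distance_travelled=dist)
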