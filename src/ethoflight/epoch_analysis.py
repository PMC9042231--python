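"""Light ON/OFF epoch comparisons and restraint struggle quantification.

Optostimulation sessions alternate baseline (light OFF) and stimulation
(light ON, 6 or 20 Hz) epochs; metrics are computed strictly within each
epoch and pooled per frequency label.  The light-induced speed change is the
normalized difference (ON - OFF) / (ON + OFF).

During physical restraint a collar sensor reports movement as a binary
value per sample; the struggle index is the fraction of moving samples per
10-s bin over the whole session (30 min -> 180 bins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, PoseDataError
from .defensive_metrics import (FREEZING_MIN_DURATION, FREEZING_SPEED_THRESHOLD,
                                detect_freezing)
from .io_formats import EpochSchedule
from .kinematics import KinematicSeries

STRUGGLE_BIN_S = 10.0
RESTRAINT_SESSION_S = 1800.0


@dataclass
class BinaryMovementSeries:
    """Restraint-sensor output: one 0/1 movement sample per tick."""

    time: np.ndarray
    movement: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.movement = np.asarray(self.movement)
        if np.any(np.diff(self.time) <= 0):
            raise PoseDataError("movement series time must be strictly increasing")
        if not np.isin(self.movement, (0, 1)).all():
            raise ValueError("movement values must be 0 or 1")
        self.movement = self.movement.astype(np.int8)

    def __len__(self) -> int:
        return len(self.time)


def speed_increase_index(speed_on: float, speed_off: float) -> float:
    """Normalized light-induced speed change (ON - OFF) / (ON + OFF).

    Antisymmetric in its arguments, in [-1, 1]; defined as 0 when the animal
    is stationary in both epochs.
    """
    if speed_on < 0 or speed_off < 0:
        raise ValueError("mean speeds must be non-negative")
    denom = speed_on + speed_off
    if denom == 0:
        return 0.0
    return (speed_on - speed_off) / denom


def epoch_metrics(series: KinematicSeries, schedule: EpochSchedule,
                  freezing_threshold: float = FREEZING_SPEED_THRESHOLD,
                  freezing_min_duration: float = FREEZING_MIN_DURATION
                  ) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Per-epoch mean speed and freezing time, plus per-label aggregates.

    Metrics use only frames with epoch.start <= t < epoch.end.  Aggregates
    pool epochs sharing a label (e.g. both ON_6Hz periods): mean speed is
    frame-weighted, freezing time is summed.
    """
    t0 = series.time[0] if len(series) else 0.0
    t_end = series.time[-1] + 1.0 / series.frame_rate if len(series) else 0.0
    rows = []
    for ep in schedule:
        if ep.start < t0 - 1e-9 or ep.end > t_end + 1e-9:
            raise ConfigError(
                f"epoch [{ep.start}, {ep.end}) lies outside the session "
                f"[{t0}, {t_end})")
        m = (series.time >= ep.start - 1e-9) & (series.time < ep.end - 1e-9)
        sp = series.speed[m]
        n_valid = int(np.isfinite(sp).sum())
        mean_speed = float(np.nanmean(sp)) if n_valid else float("nan")
        _, fr = detect_freezing(sp, series.time[m], threshold=freezing_threshold,
                                min_duration=freezing_min_duration)
        rows.append({"label": ep.label, "start": ep.start, "end": ep.end,
                     "mean_speed": mean_speed, "freezing_time": fr,
                     "n_valid_frames": n_valid})
    df = pd.DataFrame(rows)
    aggregates: dict[str, dict[str, float]] = {}
    for label, grp in df.groupby("label"):
        w = grp["n_valid_frames"].to_numpy(dtype=float)
        ms = grp["mean_speed"].to_numpy(dtype=float)
        ok = w > 0
        pooled = float(np.sum(ms[ok] * w[ok]) / np.sum(w[ok])) if ok.any() else float("nan")
        aggregates[label] = {"mean_speed": pooled,
                             "freezing_time": float(grp["freezing_time"].sum()),
                             "duration": float((grp["end"] - grp["start"]).sum())}
    return df, aggregates


def struggle_index(series: BinaryMovementSeries, bin_s: float = STRUGGLE_BIN_S,
                   session_s: float | None = None) -> pd.DataFrame:
    """Struggle index per bin: the mean of the binary movement samples in
    each ``bin_s``-second bin (fraction of time moving, in [0, 1]).

    The grand mean weighted by per-bin sample counts equals the overall
    movement fraction exactly.  A bin with no samples means the sensor
    coverage has a gap longer than the bin, which is an error.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be > 0")
    if session_s is None:
        session_s = float(series.time[-1]) + 1.0 / series.sample_rate
    n_bins = int(np.ceil(session_s / bin_s - 1e-9))
    which = np.floor(series.time / bin_s).astype(int)
    rows = []
    for b in range(n_bins):
        vals = series.movement[which == b]
        if len(vals) == 0:
            raise ConfigError(f"no movement samples in bin {b} "
                              f"[{b * bin_s}, {(b + 1) * bin_s}) s: coverage gap")
        rows.append({"bin_start": b * bin_s, "bin_end": min((b + 1) * bin_s, session_s),
                     "index": float(vals.mean()), "n_samples": int(len(vals))})
    return pd.DataFrame(rows)


def struggle_grand_mean(bins: pd.DataFrame) -> float:
    """Sample-count-weighted mean struggle index (= overall moving fraction)."""
    w = bins["n_samples"].to_numpy(dtype=float)
    return float(np.sum(bins["index"].to_numpy() * w) / np.sum(w))
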