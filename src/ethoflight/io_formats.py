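"""Reading and writing the external representations used by the pipeline.

Three families of inputs are handled here:

* per-frame pose estimates for the three tracked body parts (nose, body
  centre, tail base) in either the markerless-tracker CSV dialect (three
  header rows: scorer / bodyparts / coords, with x, y, likelihood columns
  per part) or a flat single-header dialect;
* arena geometry and epoch schedules as YAML configs (lengths in cm, times
  in s, with a pixel-per-cm calibration for the pose data);
* tidy CSV results tables that round-trip at double precision.

Coordinate convention: image coordinates at ingest (origin top-left, y
increasing downward, units pixels); everything downstream works in cm after
dividing by ``px_per_cm``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    ConfigError,
    GeometryError,
    PoseDataError,
    PoseFormatError,
    SchemaError,
)

BODY_PARTS = ("nose", "centre", "tail_base")

#: default likelihood below which a tracked point is treated as missing
DEFAULT_CONFIDENCE_THRESHOLD = 0.9
#: gaps up to this many consecutive missing frames are linearly interpolated
DEFAULT_MAX_GAP = 5
#: default acquisition rate (Hz) when the caller does not supply one
DEFAULT_FRAME_RATE = 30.0


# ---------------------------------------------------------------------------
# pose tracks
# ---------------------------------------------------------------------------

@dataclass
class PoseTrack:
    """Time-stamped per-frame coordinates and confidence for 3 body parts.

    Coordinates are stored in pixels; missing points are NaN.  ``time`` is
    derived from the frame index and the frame rate, so frame spacing is
    exactly ``1/frame_rate``.
    """

    frame_index: np.ndarray
    coords: dict[str, np.ndarray]        # part -> (n, 2) float array, px
    confidence: dict[str, np.ndarray]    # part -> (n,) float array in [0, 1]
    frame_rate: float

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if np.any(np.diff(self.frame_index) <= 0):
            raise PoseDataError("frame index must be strictly increasing")
        for part in BODY_PARTS:
            if part not in self.coords or part not in self.confidence:
                raise PoseFormatError(f"missing body part: {part}")
            self.coords[part] = np.asarray(self.coords[part], dtype=float)
            self.confidence[part] = np.asarray(self.confidence[part], dtype=float)
            if self.coords[part].shape != (len(self.frame_index), 2):
                raise PoseDataError(f"coordinate array for {part!r} has wrong shape")
            conf = self.confidence[part]
            valid = np.isfinite(conf)
            if np.any((conf[valid] < 0) | (conf[valid] > 1)):
                raise PoseDataError(f"confidence for {part!r} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def time(self) -> np.ndarray:
        """Frame times in seconds (frame_index / frame_rate)."""
        return self.frame_index / self.frame_rate

    @property
    def duration(self) -> float:
        """Session duration in seconds, counting the last frame's interval."""
        return len(self) / self.frame_rate

    def xy(self, part: str) -> np.ndarray:
        """(n, 2) pixel coordinates for ``part`` (NaN where missing)."""
        return self.coords[part]

    def xy_cm(self, part: str, geometry: "ArenaGeometry") -> np.ndarray:
        """(n, 2) coordinates for ``part`` in cm."""
        return self.coords[part] / geometry.px_per_cm

    def valid(self, part: str) -> np.ndarray:
        """Boolean mask of frames where ``part`` has finite coordinates."""
        return np.all(np.isfinite(self.coords[part]), axis=1)


def _fill_short_gaps(xy: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior missing runs of length <= max_gap."""
    xy = xy.copy()
    valid = np.all(np.isfinite(xy), axis=1)
    if valid.all() or not valid.any() or max_gap < 1:
        return xy
    idx = np.arange(len(xy))
    # locate runs of missing frames
    missing = ~valid
    starts = np.flatnonzero(missing & ~np.roll(missing, 1))
    if missing[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    for s in starts:
        e = s
        while e < len(xy) and missing[e]:
            e += 1
        interior = s > 0 and e < len(xy)
        if interior and (e - s) <= max_gap:
            for col in range(2):
                xy[s:e, col] = np.interp(idx[s:e], idx[valid], xy[valid, col])
    return xy


def read_pose_csv(
    path: str | Path,
    frame_rate: float = DEFAULT_FRAME_RATE,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    max_gap: int = DEFAULT_MAX_GAP,
) -> PoseTrack:
    """Read a pose-estimation CSV into a :class:`PoseTrack`.

    Both the three-header-row tracker dialect (scorer / bodyparts / coords)
    and the flat dialect (columns ``<part>_x, <part>_y, <part>_conf``) are
    accepted.  Points with likelihood below ``confidence_threshold`` are
    marked missing; interior gaps of at most ``max_gap`` consecutive frames
    are then linearly interpolated, longer gaps stay missing and are excluded
    from downstream metric windows.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.split(",")[0].strip().lower() == "scorer":
        frame_idx, coords, conf = _read_dlc_dialect(path)
    else:
        frame_idx, coords, conf = _read_flat_dialect(path)

    if np.any(np.diff(frame_idx) <= 0):
        raise PoseDataError("non-monotonic frame index in pose CSV")

    for part in BODY_PARTS:
        low = conf[part] < confidence_threshold
        coords[part][low] = np.nan
        coords[part] = _fill_short_gaps(coords[part], max_gap)

    return PoseTrack(frame_index=frame_idx, coords=coords, confidence=conf,
                     frame_rate=frame_rate)


def _read_dlc_dialect(path: Path):
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                     float_precision="round_trip")
    df.columns = df.columns.droplevel(0)  # drop the scorer level
    coords: dict[str, np.ndarray] = {}
    conf: dict[str, np.ndarray] = {}
    for part in BODY_PARTS:
        for coord in ("x", "y", "likelihood"):
            if (part, coord) not in df.columns:
                raise PoseFormatError(
                    f"pose CSV lacks {coord!r} column for body part {part!r}: {part}")
        coords[part] = df[[(part, "x"), (part, "y")]].to_numpy(dtype=float)
        conf[part] = df[(part, "likelihood")].to_numpy(dtype=float)
    frame_idx = df.index.to_numpy()
    try:
        frame_idx = frame_idx.astype(int)
    except (TypeError, ValueError) as exc:
        raise PoseDataError("frame index is not integer") from exc
    return frame_idx, coords, conf


def _read_flat_dialect(path: Path):
    df = pd.read_csv(path, float_precision="round_trip")
    coords: dict[str, np.ndarray] = {}
    conf: dict[str, np.ndarray] = {}
    for part in BODY_PARTS:
        cols = (f"{part}_x", f"{part}_y", f"{part}_conf")
        for c in cols:
            if c not in df.columns:
                raise PoseFormatError(f"pose CSV lacks column {c!r}: {part}")
        coords[part] = df[[cols[0], cols[1]]].to_numpy(dtype=float)
        conf[part] = df[cols[2]].to_numpy(dtype=float)
    if "frame" in df.columns:
        frame_idx = df["frame"].to_numpy(dtype=int)
    else:
        frame_idx = np.arange(len(df))
    return frame_idx, coords, conf


def write_pose_csv(track: PoseTrack, path: str | Path) -> Path:
    """Write a track in the three-header-row dialect (inverse of reading)."""
    path = Path(path)
    cols = {}
    for part in BODY_PARTS:
        cols[(part, "x")] = track.coords[part][:, 0]
        cols[(part, "y")] = track.coords[part][:, 1]
        cols[(part, "likelihood")] = track.confidence[part]
    df = pd.DataFrame(cols, index=track.frame_index)
    df.columns = pd.MultiIndex.from_tuples(
        [("ethoflight",) + c for c in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    df.index.name = None
    df.to_csv(path)
    return path


# ---------------------------------------------------------------------------
# arena geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Circle:
    """Circular region; center and radius in cm."""
    center: tuple[float, float]
    radius: float

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d = np.hypot(xy[:, 0] - self.center[0], xy[:, 1] - self.center[1])
        return d <= self.radius + 1e-12  # boundary counts as inside

    @property
    def bound_radius(self) -> float:
        return self.radius


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned rectangular region in cm."""
    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        eps = 1e-12
        return ((xy[:, 0] >= self.xmin - eps) & (xy[:, 0] <= self.xmax + eps)
                & (xy[:, 1] >= self.ymin - eps) & (xy[:, 1] <= self.ymax + eps))

    @property
    def center(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    @property
    def bound_radius(self) -> float:
        return math.hypot(self.xmax - self.xmin, self.ymax - self.ymin) / 2.0


Region = Circle | Rectangle


@dataclass(frozen=True)
class Partition:
    """Dividing line splitting the arena into two labeled chambers.

    ``axis`` is the coordinate compared against ``value``; points with
    coordinate <= value belong to the first-listed zone (the tie-break rule
    for animals sitting exactly on the line).
    """
    axis: str                 # 'x' or 'y'
    value: float              # cm
    zones: tuple[str, str]

    def __post_init__(self):
        if self.axis not in ("x", "y"):
            raise ConfigError(f"partition axis must be 'x' or 'y', got {self.axis!r}")
        if len(set(self.zones)) != 2:
            raise ConfigError("partition zones must be a two-element set of labels")

    def zone_of(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        coord = xy[:, 0] if self.axis == "x" else xy[:, 1]
        return np.where(coord <= self.value, self.zones[0], self.zones[1])


@dataclass
class ArenaGeometry:
    """Calibration plus the regions needed to score a session.

    All lengths are cm; ``px_per_cm`` converts the pose pixels into the same
    frame.  ``shelter`` and ``partition`` are optional because open-field,
    shelter-escape and two-chamber assays need different subsets.
    """

    px_per_cm: float
    arena: Region
    shelter: Region | None = None
    partition: Partition | None = None
    holes: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be > 0")
        if self.shelter is not None and not self._region_inside(self.shelter):
            raise GeometryError("shelter region is not fully inside the arena")

    def _region_inside(self, region: Region) -> bool:
        cx, cy = region.center
        if isinstance(region, Circle):
            probes = [(cx + region.radius, cy), (cx - region.radius, cy),
                      (cx, cy + region.radius), (cx, cy - region.radius)]
        else:
            probes = [(region.xmin, region.ymin), (region.xmin, region.ymax),
                      (region.xmax, region.ymin), (region.xmax, region.ymax)]
        return bool(np.all(self.arena.contains(np.asarray(probes))))

    # calibration -----------------------------------------------------------
    def to_cm(self, xy_px: np.ndarray) -> np.ndarray:
        return np.asarray(xy_px, dtype=float) / self.px_per_cm

    def to_px(self, xy_cm: np.ndarray) -> np.ndarray:
        return np.asarray(xy_cm, dtype=float) * self.px_per_cm

    # region queries (arguments in cm) --------------------------------------
    @property
    def shelter_center(self) -> tuple[float, float]:
        if self.shelter is None:
            raise ConfigError("geometry defines no shelter")
        return self.shelter.center

    def in_shelter(self, xy_cm: np.ndarray) -> np.ndarray:
        if self.shelter is None:
            raise ConfigError("geometry defines no shelter")
        return self.shelter.contains(xy_cm)

    def zone_of(self, xy_cm: np.ndarray) -> np.ndarray:
        """Per-point zone labels: 'shelter', a partition zone, or 'arena'.

        Points with non-finite coordinates get ``None``.
        """
        xy = np.atleast_2d(np.asarray(xy_cm, dtype=float))
        out = np.full(len(xy), None, dtype=object)
        ok = np.all(np.isfinite(xy), axis=1)
        if not ok.any():
            return out
        if self.partition is not None:
            out[ok] = self.partition.zone_of(xy[ok])
        else:
            out[ok] = "arena"
        if self.shelter is not None:
            sh = np.zeros(len(xy), dtype=bool)
            sh[ok] = self.shelter.contains(xy[ok])
            out[sh] = "shelter"
        return out


_ARENA_KEYS = {"px_per_cm", "arena", "shelter", "partition", "holes"}


def _parse_region(node: Mapping, what: str) -> Region:
    shape = node.get("shape")
    if shape == "circle":
        center = tuple(float(v) for v in node["center"])
        if "radius" in node:
            radius = float(node["radius"])
        elif "diameter" in node:
            radius = float(node["diameter"]) / 2.0
        else:
            raise ConfigError(f"{what}: circle needs 'radius' or 'diameter'")
        if radius <= 0:
            raise ConfigError(f"{what}: radius must be positive")
        return Circle(center=center, radius=radius)
    if shape == "rectangle":
        if "center" in node and "width" in node and "height" in node:
            cx, cy = (float(v) for v in node["center"])
            w, h = float(node["width"]), float(node["height"])
            return Rectangle(cx - w / 2, cx + w / 2, cy - h / 2, cy + h / 2)
        return Rectangle(*(float(node[k]) for k in ("xmin", "xmax", "ymin", "ymax")))
    raise ConfigError(f"{what}: unknown shape {shape!r}")


def arena_from_dict(cfg: Mapping) -> ArenaGeometry:
    """Build an :class:`ArenaGeometry` from a parsed config mapping."""
    unknown = set(cfg) - _ARENA_KEYS
    if unknown:
        raise ConfigError(f"unknown arena config key(s): {sorted(unknown)}")
    if "px_per_cm" not in cfg or "arena" not in cfg:
        raise ConfigError("arena config requires 'px_per_cm' and 'arena'")
    px_per_cm = float(cfg["px_per_cm"])
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be > 0")
    arena = _parse_region(cfg["arena"], "arena")
    shelter = _parse_region(cfg["shelter"], "shelter") if cfg.get("shelter") else None
    partition = None
    if cfg.get("partition"):
        p = cfg["partition"]
        partition = Partition(axis=p["axis"], value=float(p["value"]),
                              zones=tuple(p["zones"]))
    holes = [tuple(float(v) for v in h) for h in cfg.get("holes", [])]
    return ArenaGeometry(px_per_cm=px_per_cm, arena=arena, shelter=shelter,
                         partition=partition, holes=holes)


def read_arena_config(path: str | Path) -> ArenaGeometry:
    """Read and validate an arena geometry YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError("arena config must be a mapping")
    return arena_from_dict(cfg)


def write_arena_config(geometry: ArenaGeometry, path: str | Path) -> Path:
    """Serialize geometry back to the YAML schema (lengths in cm)."""
    def region_node(r: Region):
        if isinstance(r, Circle):
            return {"shape": "circle", "center": list(r.center), "radius": r.radius}
        return {"shape": "rectangle", "xmin": r.xmin, "xmax": r.xmax,
                "ymin": r.ymin, "ymax": r.ymax}

    cfg: dict = {"px_per_cm": geometry.px_per_cm,
                 "arena": region_node(geometry.arena)}
    if geometry.shelter is not None:
        cfg["shelter"] = region_node(geometry.shelter)
    if geometry.partition is not None:
        cfg["partition"] = {"axis": geometry.partition.axis,
                            "value": geometry.partition.value,
                            "zones": list(geometry.partition.zones)}
    if geometry.holes:
        cfg["holes"] = [list(h) for h in geometry.holes]
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# epoch schedules
# ---------------------------------------------------------------------------

#: default ultrasound stimulus length in seconds (20 kHz sine, 75 dB)
ULTRASOUND_DURATION = 9.0

KNOWN_LABELS = {"OFF", "ON_6Hz", "ON_20Hz", "ULTRASOUND",
                "RESTRAINT_ON", "RESTRAINT_OFF", "ODOR", "WATER"}


@dataclass(frozen=True)
class Epoch:
    start: float
    end: float
    label: str

    def __post_init__(self):
        if not self.end > self.start:
            raise ConfigError(f"epoch {self.label!r}: end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EpochSchedule:
    """Labeled intervals; sorted and non-overlapping within each label track."""

    epochs: list[Epoch]
    ultrasound_duration: float = ULTRASOUND_DURATION

    def __post_init__(self) -> None:
        by_label: dict[str, list[Epoch]] = {}
        for ep in self.epochs:
            by_label.setdefault(ep.label, []).append(ep)
        for label, eps in by_label.items():
            eps_sorted = sorted(eps, key=lambda e: e.start)
            for a, b in zip(eps_sorted, eps_sorted[1:]):
                if b.start < a.end - 1e-9:
                    raise ConfigError(f"overlapping epochs within label {label!r}")
        if self.ultrasound_duration is not None:
            for ep in by_label.get("ULTRASOUND", []):
                if abs(ep.duration - self.ultrasound_duration) > 1e-6:
                    raise ConfigError(
                        "ULTRASOUND epoch duration "
                        f"{ep.duration} != configured {self.ultrasound_duration}")
        self.epochs = sorted(self.epochs, key=lambda e: (e.start, e.label))

    def __iter__(self):
        return iter(self.epochs)

    def __len__(self):
        return len(self.epochs)

    def with_label(self, label: str) -> list[Epoch]:
        return [e for e in self.epochs if e.label == label]


def read_epoch_config(path: str | Path,
                      ultrasound_duration: float = ULTRASOUND_DURATION) -> EpochSchedule:
    """Read an epoch schedule YAML ({'epochs': [{start, end, label}, ...]})."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "epochs" not in cfg:
        raise ConfigError("epoch config must contain an 'epochs' list")
    epochs = [Epoch(start=float(e["start"]), end=float(e["end"]),
                    label=str(e["label"])) for e in cfg["epochs"]]
    return EpochSchedule(epochs=epochs, ultrasound_duration=ultrasound_duration)


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

_RESULTS_HEADER = (
    "# ethoflight results table. Units: times s, lengths cm, speeds cm/s,\n"
    "# accuracy/linearity percent, indices unitless.\n"
)


def write_results(records: Sequence, path: str | Path) -> Path:
    """Write per-trial / per-session metric records as a commented CSV.

    ``records`` may be dataclass instances or mappings; all must share the
    same keys (stable column order taken from the first record).  Values
    round-trip losslessly at double precision via :func:`read_results`.
    """
    if not records:
        raise SchemaError("no records to write")
    rows = [asdict(r) if is_dataclass(r) else dict(r) for r in records]
    keys = list(rows[0].keys())
    for r in rows[1:]:
        if list(r.keys()) != keys:
            raise SchemaError("heterogeneous records: differing schemas")
    df = pd.DataFrame(rows, columns=keys)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_RESULTS_HEADER)
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results`."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")
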