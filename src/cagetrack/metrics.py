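"""Region occupancy, locomotion and circadian phase metrics.

Each paired, gap-filled frame is classified into one of four regions —
``house``, ``wheel``, ``outside`` or ``unknown`` — by testing the fused
mouse midpoint against the house and wheel boxes in *both* camera views.
Region times are frame counts divided by the frame rate; *outside
activity* is the cumulative travel distance over consecutive
outside-classified frames; *running speed* combines wheel time with the
hourly revolution counts of a wheel-mounted magnetic counter,
``v = R / t_wheel`` (revolutions per second; optionally metres per second
via the wheel circumference).

Sessions are aggregated over circadian windows anchored to local clock
time.  Two presets mirror a scheduled-feeding study design under a 12/12 h
light/dark cycle with feeding at 1 P.M.:

``periods``
    FAA 9 A.M.–1 P.M. (food-anticipatory), PA 2–6 P.M. (postprandial),
    NA 6 P.M.–6 A.M. (night), PRA 6–9 A.M. (preprandial); the 1–2 P.M.
    feeding hour is excluded from analysis.
``phases``
    Light Phase 1 3–6 P.M., Dark Phase 6 P.M.–6 A.M.,
    Light Phase 2 6 A.M.–1 P.M.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, SchemaError
from .geometry import (
    BoundingBox,
    Calibration,
    Position3D,
    ViewPoint2D,
    fuse_views,
    fuse_views_arrays,
    in_region_both_views,
    points_in_box,
)

__all__ = [
    "REGIONS",
    "PhaseWindow",
    "PERIOD_SCHEDULE",
    "PHASE_SCHEDULE",
    "SCHEDULES",
    "FrameClassification",
    "classify_frame",
    "classify_frames",
    "accumulate_times",
    "region_counts",
    "outside_activity",
    "running_speed",
    "SpeedResult",
    "segment_phases",
    "hourly_region_seconds",
    "aggregate_report",
    "read_revolutions",
    "PhaseMetrics",
    "MetricsReport",
]

REGIONS = ("house", "wheel", "outside", "unknown")
_DAY_S = 86_400.0


def parse_clock(value: str | _dt.time | float) -> float:
    """Local time of day -> seconds since midnight."""
    if isinstance(value, _dt.time):
        return value.hour * 3600.0 + value.minute * 60.0 + value.second
    if isinstance(value, (int, float)):
        v = float(value)
        if not 0 <= v < _DAY_S:
            raise ConfigError(f"clock seconds must be in [0, 86400), got {v}")
        return v
    parts = str(value).strip().split(":")
    try:
        h = int(parts[0])
        m = int(parts[1]) if len(parts) > 1 else 0
        s = float(parts[2]) if len(parts) > 2 else 0.0
    except (ValueError, IndexError) as exc:
        raise ConfigError(f"unparseable clock time {value!r}") from exc
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ConfigError(f"clock time out of range: {value!r}")
    return h * 3600.0 + m * 60.0 + s


@dataclass(frozen=True)
class PhaseWindow:
    """Half-open clock window [start, end); end before start spans midnight.

    ``excluded`` windows (e.g. the feeding hour) are carved out of the
    analysis: their frames are booked under ``"excluded"``.
    """

    name: str
    start_clock: str | _dt.time | float
    end_clock: str | _dt.time | float
    excluded: bool = False

    @property
    def start_s(self) -> float:
        return parse_clock(self.start_clock)

    @property
    def end_s(self) -> float:
        return parse_clock(self.end_clock)

    def contains_clock(self, clock_s: np.ndarray | float) -> np.ndarray | bool:
        c = np.asarray(clock_s, dtype=float) % _DAY_S
        s, e = self.start_s, self.end_s
        if s < e:
            return (c >= s) & (c < e)
        return (c >= s) | (c < e)  # spans midnight


PERIOD_SCHEDULE: tuple[PhaseWindow, ...] = (
    PhaseWindow("FAA", "09:00", "13:00"),
    PhaseWindow("feeding", "13:00", "14:00", excluded=True),
    PhaseWindow("PA", "14:00", "18:00"),
    PhaseWindow("NA", "18:00", "06:00"),
    PhaseWindow("PRA", "06:00", "09:00"),
)

PHASE_SCHEDULE: tuple[PhaseWindow, ...] = (
    PhaseWindow("light1", "15:00", "18:00"),
    PhaseWindow("dark", "18:00", "06:00"),
    PhaseWindow("light2", "06:00", "13:00"),
)

SCHEDULES: dict[str, tuple[PhaseWindow, ...]] = {
    "periods": PERIOD_SCHEDULE,
    "phases": PHASE_SCHEDULE,
}


def _validate_schedule(schedule: Sequence[PhaseWindow]) -> None:
    names = [w.name for w in schedule]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate phase names in schedule: {names}")
    probes = np.arange(0, _DAY_S, 60.0)  # minute resolution
    cover = np.zeros(len(probes), dtype=int)
    for w in schedule:
        if not w.excluded:
            cover += w.contains_clock(probes).astype(int)
    if (cover > 1).any():
        raise ConfigError("schedule has overlapping non-excluded windows")


@dataclass(frozen=True)
class FrameClassification:
    frame_index: int
    region: str
    position: Position3D | None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise InputError(f"unknown region {self.region!r}")


_BoxPair = tuple[BoundingBox, BoundingBox]


def _box_params(box) -> tuple:
    """BoundingBox or (x, y, w, h) arrays -> broadcastable parameters."""
    if isinstance(box, BoundingBox):
        return box.x, box.y, box.w, box.h
    x, y, w, h = box
    return np.asarray(x, float), np.asarray(y, float), np.asarray(w, float), np.asarray(h, float)


def classify_frames(
    front_xy: np.ndarray,
    side_xy: np.ndarray,
    house_boxes: tuple,
    wheel_boxes: tuple,
    precedence: Sequence[str] = ("wheel", "house"),
    known: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised frame classification.

    ``front_xy``/``side_xy`` are ``(n, 2)`` mouse midpoints (NaN rows =
    unknown); ``house_boxes``/``wheel_boxes`` are ``(front, side)`` pairs
    of :class:`BoundingBox` or per-frame parameter arrays.  ``precedence``
    orders the regions tried first when the 2D projections overlap — the
    wheel sits above the cage floor, so its image can overlap the house's;
    by default a midpoint inside both books as wheel.

    Returns ``(regions, positions)``: an object array of region names and
    the ``(n, 3)`` fused positions (NaN where unknown).
    """
    if set(precedence) != {"wheel", "house"}:
        raise ConfigError(f"precedence must order ('wheel', 'house'), got {tuple(precedence)}")
    front_xy = np.asarray(front_xy, dtype=float)
    side_xy = np.asarray(side_xy, dtype=float)
    n = len(front_xy)
    if known is None:
        known = np.isfinite(front_xy).all(axis=1) & np.isfinite(side_xy).all(axis=1)

    in_region = {}
    for name, (bf, bs) in (("house", house_boxes), ("wheel", wheel_boxes)):
        fx, fy, fw, fh = _box_params(bf)
        sx, sy, sw, sh = _box_params(bs)
        in_region[name] = points_in_box(front_xy[:, 0], front_xy[:, 1], fx, fy, fw, fh) & points_in_box(
            side_xy[:, 0], side_xy[:, 1], sx, sy, sw, sh
        )

    regions = np.full(n, "outside", dtype=object)
    for name in reversed(list(precedence)):
        regions[in_region[name]] = name
    regions[~known] = "unknown"

    x, y, z = fuse_views_arrays(front_xy[:, 0], front_xy[:, 1], side_xy[:, 0], side_xy[:, 1])
    positions = np.column_stack([x, y, z])
    positions[~known] = np.nan
    return regions, positions


def classify_frame(
    frame_index: int,
    mouse_front: ViewPoint2D | None,
    mouse_side: ViewPoint2D | None,
    house_boxes: _BoxPair,
    wheel_boxes: _BoxPair,
    precedence: Sequence[str] = ("wheel", "house"),
) -> FrameClassification:
    """Single-frame classification (record-level convenience).

    Region is decided by the two-view conjunction against the wheel box
    first, then the house box (configurable precedence); frames with a
    missing mouse position in either view are ``unknown``.
    """
    if set(precedence) != {"wheel", "house"}:
        raise ConfigError(f"precedence must order ('wheel', 'house'), got {tuple(precedence)}")
    if mouse_front is None or mouse_side is None:
        return FrameClassification(frame_index, "unknown", None)
    boxes = {"house": house_boxes, "wheel": wheel_boxes}
    for name in precedence:
        bf, bs = boxes[name]
        if in_region_both_views(mouse_front, mouse_side, bf, bs):
            return FrameClassification(frame_index, name, fuse_views(mouse_front, mouse_side))
    return FrameClassification(frame_index, "outside", fuse_views(mouse_front, mouse_side))


def region_counts(regions: np.ndarray) -> dict[str, int]:
    """Frame counts per region (all four regions always present)."""
    regions = np.asarray(regions)
    return {r: int(np.count_nonzero(regions == r)) for r in REGIONS}


def accumulate_times(regions: np.ndarray, fps: float) -> dict[str, float]:
    """Region occupancy in seconds: frame count over frame rate."""
    if fps <= 0:
        raise ConfigError(f"fps must be positive, got {fps}")
    return {r: c / fps for r, c in region_counts(regions).items()}


def outside_activity(
    regions: np.ndarray,
    positions: np.ndarray,
    calibration: Calibration | None = None,
    mode: str = "euclidean",
) -> float:
    """Distance travelled outside house and wheel.

    Sums step distances over consecutive frame pairs that are *both*
    classified outside; runs interrupted by any other region contribute no
    distance across the interruption.  With a calibration the result is in
    metres, otherwise pixels.
    """
    regions = np.asarray(regions)
    pts = np.asarray(positions, dtype=float)
    if len(regions) != len(pts):
        raise InputError("regions and positions length mismatch")
    if len(pts) < 2:
        return 0.0
    if calibration is not None:
        x, y, z = calibration.arrays_to_mm(pts[:, 0], pts[:, 1], pts[:, 2])
        pts = np.column_stack([x, y, z])
    both_outside = (regions[:-1] == "outside") & (regions[1:] == "outside")
    if not both_outside.any():
        return 0.0
    d = np.diff(pts, axis=0)
    sq = np.sum(d**2, axis=1)
    steps = sq if mode == "squared" else np.sqrt(sq)
    total = float(np.nansum(steps[both_outside]))
    return total / 1000.0 if calibration is not None else total


@dataclass(frozen=True)
class SpeedResult:
    """Wheel running speed: revolutions over wheel-occupancy time."""

    rev_per_s: float
    m_per_s: float | None = None
    undefined: bool = False


def running_speed(
    revolutions: float, t_wheel: float, wheel_diameter_m: float | None = None
) -> SpeedResult:
    """``v = R / t_wheel`` in revolutions/second; with the wheel diameter
    also in metres/second via the circumference pi*d.

    Zero wheel time with zero revolutions is a well-defined zero; nonzero
    revolutions without wheel time is flagged undefined (counter activity
    the tracker never saw).
    """
    if revolutions < 0 or t_wheel < 0:
        raise InputError("revolutions and wheel time must be non-negative")
    if t_wheel == 0:
        if revolutions == 0:
            return SpeedResult(0.0, 0.0 if wheel_diameter_m else None, undefined=False)
        return SpeedResult(float("nan"), float("nan") if wheel_diameter_m else None, undefined=True)
    v = revolutions / t_wheel
    return SpeedResult(v, v * np.pi * wheel_diameter_m if wheel_diameter_m else None)


def segment_phases(
    timestamps_s: np.ndarray,
    schedule: Sequence[PhaseWindow] | str,
    session_start_clock: str | _dt.time | float,
) -> np.ndarray:
    """Assign each frame to its circadian window.

    ``timestamps_s`` are seconds since session start; the session's local
    start clock anchors them to time of day.  Frames in an excluded window
    get ``"excluded"``, frames covered by no window ``"unassigned"``.
    Windows may span midnight (e.g. night activity 6 P.M.–6 A.M.).
    """
    if isinstance(schedule, str):
        try:
            schedule = SCHEDULES[schedule]
        except KeyError:
            raise ConfigError(f"unknown phase preset {schedule!r}; options: {sorted(SCHEDULES)}")
    _validate_schedule(schedule)
    t = np.asarray(timestamps_s, dtype=float)
    clock = (parse_clock(session_start_clock) + t) % _DAY_S
    out = np.full(len(t), "unassigned", dtype=object)
    for w in schedule:
        if not w.excluded:
            out[w.contains_clock(clock)] = w.name
    for w in schedule:
        if w.excluded:
            out[w.contains_clock(clock)] = "excluded"
    return out


def hourly_region_seconds(
    regions: np.ndarray, timestamps_s: np.ndarray, fps: float
) -> pd.DataFrame:
    """Per-session-hour occupancy seconds, one column per region.

    Hours are binned from session start (hour_index 0 = first 3600 s); the
    natural granularity for comparison with hourly wheel-counter sums.
    """
    if fps <= 0:
        raise ConfigError(f"fps must be positive, got {fps}")
    t = np.asarray(timestamps_s, dtype=float)
    hours = np.floor(t / 3600.0).astype(np.int64)
    df = pd.DataFrame({"hour_index": hours, "region": np.asarray(regions)})
    counts = df.groupby(["hour_index", "region"], sort=True).size().unstack(fill_value=0)
    for r in REGIONS:
        if r not in counts.columns:
            counts[r] = 0
    out = (counts[list(REGIONS)] / fps).reset_index()
    out.columns = ["hour_index"] + [f"{r}_s" for r in REGIONS]
    return out


def read_revolutions(path: str | Path) -> pd.DataFrame:
    """Read an hourly wheel-revolution CSV.

    Required columns: ``hour_start_clock`` (HH:MM local time of the hour's
    start) and ``revolutions``; an optional ``hour_index`` disambiguates
    sessions longer than 24 h.
    """
    df = pd.read_csv(path)
    for col in ("hour_start_clock", "revolutions"):
        if col not in df.columns:
            raise SchemaError(f"{path}: revolutions CSV missing column {col!r}")
    df["revolutions"] = pd.to_numeric(df["revolutions"], errors="coerce")
    if df["revolutions"].isna().any() or (df["revolutions"] < 0).any():
        raise SchemaError(f"{path}: revolutions must be non-negative numbers")
    return df


@dataclass
class PhaseMetrics:
    """Occupancy and activity of one circadian window (or the session)."""

    name: str
    n_frames: int
    counts: dict[str, int]
    t_house: float
    t_wheel: float
    t_outside: float
    t_unknown: float
    outside_activity: float
    revolutions: float | None = None
    speed_rev_s: float | None = None
    speed_m_s: float | None = None
    speed_undefined: bool = False
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_frames": self.n_frames,
            "counts": dict(self.counts),
            "t_house_s": self.t_house,
            "t_wheel_s": self.t_wheel,
            "t_outside_s": self.t_outside,
            "t_unknown_s": self.t_unknown,
            "outside_activity": self.outside_activity,
            "revolutions": self.revolutions,
            "speed_rev_s": self.speed_rev_s,
            "speed_m_s": self.speed_m_s,
            "speed_undefined": self.speed_undefined,
            "empty": self.empty,
        }


@dataclass
class MetricsReport:
    """Per-phase and whole-session behavioral metrics."""

    phases: dict[str, PhaseMetrics]
    session: PhaseMetrics
    fps: float
    distance_unit: str = "px"
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fps": self.fps,
            "distance_unit": self.distance_unit,
            "session": self.session.to_dict(),
            "phases": {k: v.to_dict() for k, v in self.phases.items()},
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tidy_frame(self) -> pd.DataFrame:
        """One row per phase x metric, for CSV export."""
        rows = []
        for name, pm in [("session", self.session), *self.phases.items()]:
            d = pm.to_dict()
            for key in (
                "n_frames",
                "t_house_s",
                "t_wheel_s",
                "t_outside_s",
                "t_unknown_s",
                "outside_activity",
                "revolutions",
                "speed_rev_s",
                "speed_m_s",
            ):
                rows.append({"phase": name, "metric": key, "value": d[key]})
        return pd.DataFrame(rows)


def _phase_metrics(
    name: str,
    regions: np.ndarray,
    positions: np.ndarray,
    fps: float,
    calibration: Calibration | None,
    mode: str,
    revolutions: float | None,
    wheel_diameter_m: float | None,
) -> PhaseMetrics:
    counts = region_counts(regions)
    times = accumulate_times(regions, fps)
    act = outside_activity(regions, positions, calibration, mode)
    speed = None
    if revolutions is not None:
        speed = running_speed(float(revolutions), times["wheel"], wheel_diameter_m)
    return PhaseMetrics(
        name=name,
        n_frames=int(len(regions)),
        counts=counts,
        t_house=times["house"],
        t_wheel=times["wheel"],
        t_outside=times["outside"],
        t_unknown=times["unknown"],
        outside_activity=act,
        revolutions=None if revolutions is None else float(revolutions),
        speed_rev_s=None if speed is None else speed.rev_per_s,
        speed_m_s=None if speed is None else speed.m_per_s,
        speed_undefined=bool(speed.undefined) if speed is not None else False,
        empty=len(regions) == 0,
    )


def _revolutions_by_phase(
    revolutions: pd.DataFrame,
    schedule: Sequence[PhaseWindow] | str,
    session_start_clock: str | _dt.time | float,
) -> tuple[dict[str, float], float]:
    """Sum hourly counts into phases: an hour belongs to the window that
    contains its start clock."""
    if isinstance(schedule, str):
        schedule = SCHEDULES[schedule]
    per_phase: dict[str, float] = {}
    total = 0.0
    for row in revolutions.itertuples(index=False):
        clock = parse_clock(row.hour_start_clock)
        total += float(row.revolutions)
        assigned = "unassigned"
        for w in schedule:
            if bool(w.contains_clock(clock)):
                assigned = "excluded" if w.excluded else w.name
                break
        per_phase[assigned] = per_phase.get(assigned, 0.0) + float(row.revolutions)
    return per_phase, total


def aggregate_report(
    regions: np.ndarray,
    positions: np.ndarray,
    timestamps_s: np.ndarray,
    fps: float,
    schedule: Sequence[PhaseWindow] | str = "phases",
    session_start_clock: str | _dt.time | float = "15:00",
    revolutions: pd.DataFrame | None = None,
    calibration: Calibration | None = None,
    wheel_diameter_m: float | None = None,
    distance_mode: str = "euclidean",
    diagnostics: dict | None = None,
) -> MetricsReport:
    """Build the full per-phase :class:`MetricsReport`.

    The session block covers every frame (excluded windows included) so
    the conservation identity sum(region times) = n_frames / fps holds for
    the whole recording; each phase block satisfies it for its own frames.
    Outside-activity runs are broken at phase boundaries, so phase
    activities sum to at most the session activity.
    """
    regions = np.asarray(regions)
    positions = np.asarray(positions, dtype=float)
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    if not (len(regions) == len(positions) == len(timestamps_s)):
        raise InputError("regions, positions and timestamps must have equal length")
    if isinstance(schedule, str):
        schedule_windows = SCHEDULES.get(schedule)
        if schedule_windows is None:
            raise ConfigError(f"unknown phase preset {schedule!r}; options: {sorted(SCHEDULES)}")
    else:
        schedule_windows = tuple(schedule)

    phase_names = segment_phases(timestamps_s, schedule_windows, session_start_clock)
    rev_by_phase: dict[str, float] = {}
    rev_total: float | None = None
    if revolutions is not None:
        rev_by_phase, rev_total = _revolutions_by_phase(
            revolutions, schedule_windows, session_start_clock
        )

    session = _phase_metrics(
        "session", regions, positions, fps, calibration, distance_mode, rev_total, wheel_diameter_m
    )
    phases: dict[str, PhaseMetrics] = {}
    ordered = [w.name for w in schedule_windows if not w.excluded]
    extras = [n for n in ("excluded", "unassigned") if (phase_names == n).any()]
    for name in ordered + extras:
        mask = phase_names == name
        rev = rev_by_phase.get(name) if revolutions is not None else None
        if revolutions is not None and rev is None and name in ordered:
            rev = 0.0
        pm = _phase_metrics(
            name,
            regions[mask],
            # phase frames are contiguous runs in time; masking positions keeps
            # outside runs intact within the phase and breaks them at its edges
            positions[mask],
            fps,
            calibration,
            distance_mode,
            rev,
            wheel_diameter_m,
        )
        phases[name] = pm
    return MetricsReport(
        phases=phases,
        session=session,
        fps=fps,
        distance_unit="m" if calibration is not None else "px",
        diagnostics=diagnostics or {},
    )
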