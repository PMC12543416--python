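"""End-to-end evaluation: detection streams in, metrics report out.

The stages mirror what the recording rig's evaluation unit does:

1. reduce each view's raw stream to the best box per label per frame;
2. carry the static house/wheel boxes across frames where the detector
   missed them (they do not move);
3. pair front and side frames by nearest timestamp under the inter-camera
   latency tolerance;
4. fill mouse-detection gaps per view (last-known-position by default,
   capped so a long-lost animal books `unknown`, not occupancy);
5. classify every paired frame into house / wheel / outside / unknown and
   fuse the 3D position;
6. aggregate region times, outside activity and running speed over the
   configured circadian windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError
from .geometry import Calibration
from .metrics import (
    MetricsReport,
    SCHEDULES,
    aggregate_report,
    classify_frames,
    read_revolutions,
)
from .streams import GapReport, fill_gaps, pair_frames, read_stream, select_best_stream

__all__ = ["PipelineConfig", "evaluate_session", "evaluate_files", "ClassifiedSession"]


@dataclass(frozen=True)
class PipelineConfig:
    """Evaluation settings.

    ``max_gap_frames`` defaults to two seconds of frames (2 x fps);
    ``sync_tolerance_s`` to the 0.3 s latency the dual-camera recording
    tolerates.  ``phase_preset`` selects the circadian schedule
    (``"phases"`` or ``"periods"``); a custom window list can be passed to
    :func:`cagetrack.metrics.aggregate_report` directly.
    """

    fps: float = 15.0
    sync_tolerance_s: float = 0.3
    gap_policy: str = "hold_last"
    max_gap_frames: int | None = None
    distance_mode: str = "euclidean"
    region_precedence: tuple[str, str] = ("wheel", "house")
    phase_preset: str = "phases"
    session_start_clock: str = "15:00"
    wheel_diameter_m: float | None = 0.115
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")
        if self.sync_tolerance_s <= 0:
            raise ConfigError("sync_tolerance_s must be positive")
        if self.phase_preset not in SCHEDULES:
            raise ConfigError(
                f"unknown phase preset {self.phase_preset!r}; options: {sorted(SCHEDULES)}"
            )

    @property
    def effective_max_gap(self) -> int:
        return int(2 * self.fps) if self.max_gap_frames is None else int(self.max_gap_frames)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cal = d.pop("calibration", None)
        if cal is not None and not isinstance(cal, Calibration):
            cal = Calibration(
                scale_x=float(cal["scale_x"]),
                scale_y=float(cal["scale_y"]),
                scale_z=float(cal["scale_z"]),
                cage_dims=tuple(cal["cage_dims"]) if cal.get("cage_dims") else None,
            )
        if "region_precedence" in d:
            d["region_precedence"] = tuple(d["region_precedence"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(calibration=cal, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(data or {})

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if self.calibration is not None:
            d["calibration"] = {
                "scale_x": self.calibration.scale_x,
                "scale_y": self.calibration.scale_y,
                "scale_z": self.calibration.scale_z,
                "cage_dims": list(self.calibration.cage_dims) if self.calibration.cage_dims else None,
            }
        d["region_precedence"] = list(self.region_precedence)
        Path(path).write_text(yaml.safe_dump(d))


@dataclass
class ClassifiedSession:
    """Per-frame pipeline output, before phase aggregation."""

    frame_index: np.ndarray  # front frame index of each pair
    timestamps_s: np.ndarray
    regions: np.ndarray
    positions: np.ndarray  # (n, 3) fused pixel coordinates, NaN if unknown
    gap_report: GapReport


def _ffill_bfill(values: np.ndarray) -> np.ndarray:
    """Forward- then back-fill NaNs in a 1D array (static-object reuse:
    house and wheel do not move, so the latest detected box carries)."""
    present = np.isfinite(values)
    idx = np.where(present, np.arange(len(values)), -1)
    idx = np.maximum.accumulate(idx)
    first = np.flatnonzero(present)[0]
    idx[idx < 0] = first
    return values[idx]


def _per_frame_view(
    stream: pd.DataFrame, fps: float, view_name: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, tuple[np.ndarray, ...]]]:
    """Collapse one view's stream to per-frame arrays: a contiguous frame
    grid, timestamps (derived as frame/fps where absent), mouse midpoints
    (NaN where missed) and forward/back-filled static boxes.

    Column-wise numpy throughout: streams can run to millions of rows."""
    if stream.empty:
        raise InputError(f"{view_name} stream is empty")
    best = select_best_stream(stream)
    frame = best["frame_index"].to_numpy(dtype=np.int64)
    fmin, fmax = int(frame.min()), int(frame.max())
    n = fmax - fmin + 1
    grid = np.arange(fmin, fmax + 1, dtype=np.int64)
    pos = frame - fmin
    cols = {c: best[c].to_numpy(dtype=float) for c in ("timestamp_s", "x", "y", "w", "h")}
    lab = best["label"]
    if isinstance(lab.dtype, pd.CategoricalDtype):
        codes = lab.cat.codes.to_numpy()
        cats = list(lab.cat.categories)
        label_mask = lambda name: codes == cats.index(name) if name in cats else np.zeros(len(codes), bool)
    else:
        labels = lab.to_numpy()
        label_mask = lambda name: labels == name

    ts = np.full(n, np.nan)
    ts[pos] = cols["timestamp_s"]
    missing_ts = ~np.isfinite(ts)
    if missing_ts.any():
        ts[missing_ts] = grid[missing_ts] / fps

    out: dict[str, tuple[np.ndarray, ...]] = {}
    mxy = None
    for label in ("mouse", "house", "wheel"):
        mask = label_mask(label)
        if not mask.any():
            if label == "mouse":
                mxy = np.full((n, 2), np.nan)
                continue
            raise ConfigError(f"{view_name} stream never detected the static {label!r} box")
        lpos = pos[mask]
        if label == "mouse":
            mxy = np.full((n, 2), np.nan)
            mxy[lpos, 0] = cols["x"][mask]
            mxy[lpos, 1] = cols["y"][mask]
        else:
            arrs = []
            for c in ("x", "y", "w", "h"):
                a = np.full(n, np.nan)
                a[lpos] = cols[c][mask]
                arrs.append(_ffill_bfill(a))
            out[label] = tuple(arrs)
    return grid, ts, mxy, out


def evaluate_session(
    front: pd.DataFrame,
    side: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    revolutions: pd.DataFrame | None = None,
) -> tuple[MetricsReport, ClassifiedSession]:
    """Run the full evaluation on two in-memory detection streams.

    Returns the per-phase :class:`MetricsReport` and the per-frame
    :class:`ClassifiedSession` it was aggregated from.
    """
    f_grid, f_ts, f_xy, f_boxes = _per_frame_view(front, config.fps, "front")
    s_grid, s_ts, s_xy, s_boxes = _per_frame_view(side, config.fps, "side")

    fi, si, unmatched_f, unmatched_s = pair_frames(f_ts, s_ts, config.sync_tolerance_s)
    if len(fi) == 0:
        raise InputError("no front/side frame pairs within the sync tolerance")
    pair_frames_idx = f_grid[fi]
    pair_ts = f_ts[fi]

    fxy = f_xy[fi]
    sxy = s_xy[si]
    missing_before = ~(np.isfinite(fxy).all(axis=1) & np.isfinite(sxy).all(axis=1))

    max_gap = config.effective_max_gap
    fxy_filled, f_known, _ = fill_gaps((pair_frames_idx, fxy), config.gap_policy, max_gap)
    sxy_filled, s_known, _ = fill_gaps((pair_frames_idx, sxy), config.gap_policy, max_gap)
    known = f_known & s_known

    report_gaps = GapReport(
        n_frames=int(len(fi)),
        n_missing_mouse=int(missing_before.sum()),
        n_interpolated=int((missing_before & known).sum()),
        n_unknown=int((~known).sum()),
        n_unmatched=int(unmatched_f + unmatched_s),
    )

    house = (
        tuple(a[fi] for a in f_boxes["house"]),
        tuple(a[si] for a in s_boxes["house"]),
    )
    wheel = (
        tuple(a[fi] for a in f_boxes["wheel"]),
        tuple(a[si] for a in s_boxes["wheel"]),
    )
    regions, positions = classify_frames(
        fxy_filled, sxy_filled, house, wheel, precedence=config.region_precedence, known=known
    )
    session = ClassifiedSession(
        frame_index=pair_frames_idx,
        timestamps_s=pair_ts,
        regions=regions,
        positions=positions,
        gap_report=report_gaps,
    )
    report = aggregate_report(
        regions,
        positions,
        pair_ts,
        fps=config.fps,
        schedule=config.phase_preset,
        session_start_clock=config.session_start_clock,
        revolutions=revolutions,
        calibration=config.calibration,
        wheel_diameter_m=config.wheel_diameter_m,
        distance_mode=config.distance_mode,
        diagnostics={"gap_report": dataclasses.asdict(report_gaps)},
    )
    return report, session


def evaluate_files(
    front_path: str | Path,
    side_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    revolutions_path: str | Path | None = None,
) -> tuple[MetricsReport, ClassifiedSession]:
    """File-based wrapper around :func:`evaluate_session`."""
    front = read_stream(front_path, view="front")
    side = read_stream(side_path, view="side")
    revs = read_revolutions(revolutions_path) if revolutions_path else None
    return evaluate_session(front, side, config, revolutions=revs)
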