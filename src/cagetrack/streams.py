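"""Detection-stream I/O and per-frame bookkeeping.

A *detection stream* is everything an object detector emitted for one
camera view: zero or more boxes per frame, each labelled ``mouse``,
``house`` or ``wheel`` with a confidence.  The canonical on-disk form is a
headered CSV (a JSON-lines dialect with the same field names is also
accepted)::

    frame_index,timestamp_s,view,label,x,y,w,h,confidence

In memory a stream is a :class:`pandas.DataFrame` with those columns,
sorted by ``frame_index``; :class:`DetectionRecord` is the record-level
view of one row.  This module reduces raw streams to one box per label per
frame, pairs the two views' frames under a latency tolerance, and fills
detection gaps in the mouse track.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, SchemaError
from .geometry import BoundingBox, View, ViewPoint2D

__all__ = [
    "STREAM_COLUMNS",
    "LABELS",
    "DetectionRecord",
    "GapReport",
    "read_stream",
    "write_stream",
    "select_best",
    "select_best_stream",
    "pair_frames",
    "fill_gaps",
]

STREAM_COLUMNS = (
    "frame_index",
    "timestamp_s",
    "view",
    "label",
    "x",
    "y",
    "w",
    "h",
    "confidence",
)
LABELS = ("mouse", "house", "wheel")


@dataclass(frozen=True)
class DetectionRecord:
    """One object's bounding box in one frame of one view."""

    frame_index: int
    timestamp: float
    label: str
    box: BoundingBox
    confidence: float
    view: View

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise InputError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if not 0.0 <= self.confidence <= 1.0:
            raise InputError(f"confidence must be in [0, 1], got {self.confidence}")
        object.__setattr__(self, "view", View(self.view))


@dataclass
class GapReport:
    """Accounting of mouse-detection gaps in one (or both) view tracks."""

    n_frames: int = 0
    n_missing_mouse: int = 0
    n_interpolated: int = 0
    n_unknown: int = 0
    n_unmatched: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def records_to_frame(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    rows = [
        (r.frame_index, r.timestamp, r.view.value, r.label, r.box.x, r.box.y, r.box.w, r.box.h, r.confidence)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(STREAM_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[DetectionRecord]:
    return [
        DetectionRecord(
            frame_index=int(row.frame_index),
            timestamp=float(row.timestamp_s),
            label=str(row.label),
            box=BoundingBox(float(row.x), float(row.y), float(row.w), float(row.h)),
            confidence=float(row.confidence),
            view=View(row.view),
        )
        for row in df.itertuples(index=False)
    ]


def _validate_stream_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    # timestamp_s may be absent or NaN: the pipeline derives it as frame/fps
    if "timestamp_s" not in df.columns:
        df = df.assign(timestamp_s=np.nan)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")
    df = df.loc[:, list(STREAM_COLUMNS)].copy()
    for col in ("timestamp_s", "x", "y", "w", "h", "confidence"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["frame_index"] = pd.to_numeric(df["frame_index"], errors="coerce")

    numeric_ok = np.isfinite(df[["x", "y", "w", "h", "confidence"]]).all(axis=1)
    ok = (
        numeric_ok.to_numpy()
        & np.isfinite(df["frame_index"].to_numpy(dtype=float))
        & (df["frame_index"].to_numpy(dtype=float) >= 0)
        & (df["w"].to_numpy() > 0)
        & (df["h"].to_numpy() > 0)
        & (df["confidence"].to_numpy() >= 0)
        & (df["confidence"].to_numpy() <= 1)
        & df["label"].isin(LABELS).to_numpy()
        & df["view"].isin([v.value for v in View]).to_numpy()
    )
    if not ok.all():
        # +2: header line plus 1-based numbering of CSV data rows
        bad_lines = (np.flatnonzero(~ok) + 2).tolist()
        warnings.warn(
            f"{source}: rejected {len(bad_lines)} malformed row(s) at line(s) {bad_lines[:20]}"
            + ("..." if len(bad_lines) > 20 else ""),
            stacklevel=3,
        )
        df = df.loc[ok]
    df["frame_index"] = df["frame_index"].astype(np.int64)
    return df


def read_stream(path: str | Path, view: str | View | None = None) -> pd.DataFrame:
    """Read a detection stream (CSV or JSON-lines) into a validated,
    frame-sorted DataFrame.

    Malformed rows (negative extents, confidences outside [0, 1], unknown
    labels...) are dropped with a warning naming their line numbers; a
    missing column raises :class:`SchemaError`.  ``view``, if given,
    restricts the stream to that camera.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".json", ".jsonl", ".ndjson"):
            df = pd.read_json(path, lines=True)
        else:
            df = pd.read_csv(path, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: unparseable stream file: {exc}") from exc
    if df.empty:
        warnings.warn(f"{path}: empty detection stream", stacklevel=2)
        return pd.DataFrame(columns=list(STREAM_COLUMNS)).astype({"frame_index": np.int64})
    df = _validate_stream_frame(df, str(path))
    if view is not None:
        df = df.loc[df["view"] == View(view).value]
    ts = df["timestamp_s"].to_numpy()
    if len(df) > 1 and (np.diff(ts) < 0).any():
        warnings.warn(f"{path}: non-monotone timestamps; records stable-sorted by frame index", stacklevel=2)
    return df.sort_values("frame_index", kind="stable").reset_index(drop=True)


def write_stream(df: pd.DataFrame, path: str | Path) -> None:
    """Write a stream DataFrame in the canonical CSV schema."""
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write stream, missing column(s) {missing}")
    # %.17g guarantees float64 round-trip through the text format
    df.loc[:, list(STREAM_COLUMNS)].to_csv(path, index=False, float_format="%.17g")


def select_best(records: Sequence[DetectionRecord]) -> DetectionRecord | None:
    """Reduce several boxes for one (frame, view, label) to the single
    best: maximal confidence, ties broken by larger box area, then lower x.

    Returns ``None`` for empty input.
    """
    if not records:
        return None
    keys = {(r.frame_index, r.view, r.label) for r in records}
    if len(keys) > 1:
        raise InputError(f"select_best expects one (frame, view, label) group, got {sorted(map(str, keys))}")
    return max(records, key=lambda r: (r.confidence, r.box.area, -r.box.x))


_LABEL_CODE = {"mouse": 0, "house": 1, "wheel": 2}
_VIEW_CODE = {"front": 0, "side": 1}


def _group_key(df: pd.DataFrame) -> np.ndarray:
    """(view, frame, label) packed into one int64 per row."""
    frame = df["frame_index"].to_numpy(dtype=np.int64)
    label = df["label"].map(_LABEL_CODE).to_numpy(dtype=np.int64)
    view = df["view"].map(_VIEW_CODE).to_numpy(dtype=np.int64)
    return (frame << 3) | (label << 1) | view


def select_best_stream(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised best-per-(view, frame, label) reduction of a stream."""
    if df.empty:
        return df
    subset = ["view", "frame_index", "label"]
    if not pd.Index(_group_key(df)).duplicated().any():
        if df["frame_index"].is_monotonic_increasing:
            return df.reset_index(drop=True)
        return df.sort_values("frame_index", kind="stable").reset_index(drop=True)
    work = df.assign(_area=df["w"] * df["h"])
    work = work.sort_values(
        ["view", "frame_index", "label", "confidence", "_area", "x"],
        ascending=[True, True, True, True, True, False],
        kind="stable",
    )
    best = work.drop_duplicates(subset=subset, keep="last").drop(columns="_area")
    return best.sort_values("frame_index", kind="stable").reset_index(drop=True)


def pair_frames(
    front_times: np.ndarray | pd.Series,
    side_times: np.ndarray | pd.Series,
    tolerance: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Greedily match front and side frames by nearest timestamp.

    Both inputs must be sorted.  Each frame is used at most once; a front
    frame takes the nearest still-available side frame within
    ``tolerance`` seconds.  The default tolerance is 0.3 s, the
    inter-camera latency the recording setup tolerates.

    Returns ``(front_idx, side_idx, n_unmatched_front, n_unmatched_side)``
    where the two index arrays have equal length and matched time
    differences are all within tolerance.
    """
    if tolerance <= 0:
        raise ConfigError(f"sync tolerance must be positive, got {tolerance}")
    tf = np.asarray(front_times, dtype=float)
    ts = np.asarray(side_times, dtype=float)
    if (np.diff(tf) < 0).any() or (np.diff(ts) < 0).any():
        raise InputError("pair_frames requires timestamp-sorted streams")
    nf, ns = len(tf), len(ts)

    # fast path: nearest side frame per front frame; valid whenever that
    # assignment is already one-to-one (regular frame grids), where it
    # coincides with the greedy scan below
    if nf and ns:
        right = np.searchsorted(ts, tf)
        left = np.clip(right - 1, 0, ns - 1)
        right = np.clip(right, 0, ns - 1)
        nearest = np.where(np.abs(tf - ts[left]) <= np.abs(tf - ts[right]), left, right)
        ok = np.abs(tf - ts[nearest]) <= tolerance
        cand = nearest[ok]
        if len(cand) and (np.diff(cand) > 0).all():
            fidx = np.flatnonzero(ok)
            return fidx, cand, nf - len(fidx), ns - len(cand)

    fi: list[int] = []
    si: list[int] = []
    i = j = 0
    while i < nf and j < ns:
        d = tf[i] - ts[j]
        if abs(d) <= tolerance:
            if j + 1 < ns and abs(tf[i] - ts[j + 1]) < abs(d):
                j += 1  # a strictly closer side frame exists for this front frame
            else:
                fi.append(i)
                si.append(j)
                i += 1
                j += 1
        elif d > 0:
            j += 1  # side frame too old for any remaining front frame
        else:
            i += 1  # front frame has no side partner within tolerance
    return (
        np.asarray(fi, dtype=np.int64),
        np.asarray(si, dtype=np.int64),
        nf - len(fi),
        ns - len(si),
    )


def _track_to_arrays(
    track: Sequence[tuple[int, ViewPoint2D | None]] | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(track, tuple) and len(track) == 2 and isinstance(track[0], np.ndarray):
        frames, xy = track
        return np.asarray(frames, dtype=np.int64), np.array(xy, dtype=float)
    frames = np.array([f for f, _ in track], dtype=np.int64)
    xy = np.array(
        [(p.x, p.y) if p is not None else (np.nan, np.nan) for _, p in track], dtype=float
    )
    return frames, xy


def fill_gaps(
    track: Sequence[tuple[int, ViewPoint2D | None]] | tuple[np.ndarray, np.ndarray],
    policy: str = "hold_last",
    max_gap: int = 30,
) -> tuple[np.ndarray, np.ndarray, GapReport]:
    """Fill missing mouse positions in a single-view track.

    ``track`` is either a sequence of ``(frame_index, point-or-None)`` or a
    ``(frame_indices, (n, 2) array with NaN rows)`` pair.  ``hold_last``
    repeats the last detected position into a gap; ``linear``
    interpolates between the flanking detections.  Gaps longer than
    ``max_gap`` frames are left absent in full and flagged unknown — a cap
    that keeps a long-lost animal from fabricating occupancy.  A leading
    gap is back-filled from the first detection, a trailing gap held from
    the last, both under the same cap.

    Returns ``(xy_filled, known_mask, report)``: unknown frames keep NaN
    coordinates and ``known_mask`` False.
    """
    if policy not in ("hold_last", "linear"):
        raise ConfigError(f"unknown gap policy {policy!r}")
    if max_gap < 0:
        raise ConfigError("max_gap must be >= 0")
    frames, xy = _track_to_arrays(track)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise InputError(f"track coordinates must be (n, 2), got {xy.shape}")
    n = len(frames)
    present = np.isfinite(xy).all(axis=1)
    if not present.any():
        raise InputError("all-absent track: no known position to fill from")

    out = xy.copy()
    known = present.copy()
    obs = np.flatnonzero(present)
    report = GapReport(n_frames=n, n_missing_mouse=int(n - present.sum()))

    def _book(filled: bool, count: int) -> None:
        if filled:
            report.n_interpolated += count
        else:
            report.n_unknown += count

    # leading gap: back-fill from the first detection
    first = obs[0]
    if first > 0:
        span = int(frames[first] - frames[0])
        if span <= max_gap:
            out[:first] = xy[first]
            known[:first] = True
        _book(span <= max_gap, first)
    # interior gaps
    for a, b in zip(obs[:-1], obs[1:]):
        if b == a + 1:
            continue
        span = int(frames[b] - frames[a] - 1)
        sl = slice(a + 1, b)
        if span <= max_gap:
            if policy == "hold_last":
                out[sl] = xy[a]
            else:
                t = (frames[sl] - frames[a]) / (frames[b] - frames[a])
                out[sl] = xy[a] + t[:, None] * (xy[b] - xy[a])
            known[sl] = True
        _book(span <= max_gap, b - a - 1)
    # trailing gap: hold the last detection
    last = obs[-1]
    if last < n - 1:
        span = int(frames[-1] - frames[last])
        if span <= max_gap:
            out[last + 1 :] = xy[last]
            known[last + 1 :] = True
        _book(span <= max_gap, n - 1 - last)
    return out, known, report
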