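"""Synthetic home-cage sessions with full ground truth.

The simulator emulates a single mouse in a Eurostandard Type 2 cage
(interior 268 x 215 x 141 mm) carrying a shelter house and a top-mounted
running wheel, filmed by two orthogonal cameras at 15 frames/s under a
12/12 h light/dark cycle.  It produces everything the real recording rig
would — dual-view detection streams and hourly wheel-revolution counts —
plus the ground truth those recordings hide: the true 3D trajectory, the
true region occupancy, and the true per-hour wheel seconds.  That makes it
the oracle for every pipeline stage.

Behavioral model
----------------
Region occupancy follows a continuous-time Markov chain over
``{house, wheel, outside}`` with exponential sojourn times; an hour-of-day
activity multiplier shortens house (rest) sojourns and lengthens
wheel/outside sojourns during active hours, producing dark-phase and
pre-feeding activity ramps.  Within a region the mouse performs a
reflected Gaussian random walk confined to a margin-shrunk core of the
region's volume; the margins keep body-centre positions away from region
edges and the image border, so detection jitter cannot flip region
membership and the rendered body is never clipped.  The chain is a
measurement test-bed, not a claim about mouse ethology.

Hourly wheel revolutions are ``rate x wheel-occupancy seconds`` plus
Gaussian counter noise, floored at zero and rounded — the relationship a
wheel-time-vs-revolutions correlation analysis should recover.

All randomness flows from one seed through named substreams (trajectory,
wheel counter, per-view corruption), so e.g. changing the corruption level
never perturbs the trajectory.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .geometry import Calibration
from .streams import STREAM_COLUMNS

__all__ = [
    "Box3D",
    "SimScenario",
    "GroundTruth",
    "substream",
    "simulate_session",
    "project_views",
    "corrupt_stream",
    "simulate_streams",
    "render_frames",
    "render_reference_frame",
]

_STATES = ("house", "wheel", "outside")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG substream keyed by purpose."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(zlib.crc32(name.encode()),)))


@dataclass(frozen=True)
class Box3D:
    """Axis-aligned box in cage coordinates (mm): centre + full extents."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.center) - 0.5 * np.asarray(self.size)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.center) + 0.5 * np.asarray(self.size)

    def shrink(self, margin: float) -> "Box3D":
        size = tuple(max(s - 2 * margin, 1e-6) for s in self.size)
        return Box3D(self.center, size)

    def intersect(self, other: "Box3D") -> "Box3D":
        lo = np.maximum(self.lo, other.lo)
        hi = np.minimum(self.hi, other.hi)
        if (hi <= lo).any():
            raise ConfigError(f"empty box intersection: {self} & {other}")
        return Box3D(tuple((lo + hi) / 2), tuple(hi - lo))


def _default_hourly_activity() -> tuple[float, ...]:
    # 12/12 light/dark, lights on 06:00; elevated dark-phase activity and a
    # pre-feeding (09:00-13:00) ramp ahead of 13:00 feeding
    m = np.full(24, 0.8)
    m[18:24] = 2.0
    m[0:6] = 2.0
    m[9:13] = 1.5
    return tuple(m)


@dataclass(frozen=True)
class SimScenario:
    """Everything that defines a synthetic session.

    Geometry is in cage millimetres; corruption parameters act on the
    projected pixel streams.  Defaults describe the recording rig being
    emulated: 268 x 215 x 141 mm cage, 1640 x 1232 px cameras at 15 FPS,
    an 11.5 cm wheel, sessions starting 3 P.M.
    """

    seed: int = 0
    duration_s: float = 7200.0
    fps: float = 15.0
    cage_dims: tuple[float, float, float] = (268.0, 215.0, 141.0)
    frame_size: tuple[int, int] = (1640, 1232)
    session_start_clock: str = "15:00"
    # region geometry: house on the floor in one corner, wheel mounted high
    # in the opposite corner (z grows downward; the floor is z = 141)
    house_box_mm: Box3D = Box3D((67.0, 54.0, 106.0), (110.0, 90.0, 70.0))
    wheel_box_mm: Box3D = Box3D((201.0, 170.0, 70.0), (115.0, 50.0, 115.0))
    # free-floor corridor disjoint from both region boxes in the depth axis
    outside_zone_mm: Box3D = Box3D((134.0, 124.0, 70.5), (196.0, 32.0, 69.0))
    mean_dwell_s: Mapping[str, float] = field(
        default_factory=lambda: {"house": 240.0, "wheel": 120.0, "outside": 60.0}
    )
    transition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "house": {"wheel": 0.4, "outside": 0.6},
            "wheel": {"house": 0.5, "outside": 0.5},
            "outside": {"house": 0.5, "wheel": 0.5},
        }
    )
    step_mm: Mapping[str, float] = field(
        default_factory=lambda: {"house": 1.0, "wheel": 2.0, "outside": 6.0}
    )
    hourly_activity: tuple[float, ...] = field(default_factory=_default_hourly_activity)
    initial_state: str = "house"
    # stream corruption
    miss_prob: float = 0.0
    jitter_sd_px: float = 0.0
    latency_offset_s: float = 0.0
    false_box_rate: float = 0.0
    # wheel counter
    wheel_rate_rev_s: float = 1.1
    wheel_noise_sd_rev: float = 20.0
    wheel_diameter_m: float = 0.115
    # rendering / detection geometry
    mouse_size_mm: tuple[float, float, float] = (70.0, 30.0, 30.0)
    region_margin_mm: float = 8.0
    edge_margin_mm: float = 36.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def calibration(self) -> Calibration:
        return self.calibration_for(self.frame_size)

    def calibration_for(self, frame_size: Sequence[int]) -> Calibration:
        w, h = frame_size
        return Calibration.from_cage_extents(self.cage_dims, (w, h), (w, h))

    def walk_bounds(self, state: str) -> Box3D:
        """Volume the body centre may occupy in a region: the region box
        shrunk by the classification margin, clipped away from cage walls
        by the render margin."""
        core = Box3D(
            tuple(c / 2 for c in self.cage_dims), tuple(self.cage_dims)
        ).shrink(self.edge_margin_mm)
        if state == "outside":
            return self.outside_zone_mm.intersect(core)
        box = {"house": self.house_box_mm, "wheel": self.wheel_box_mm}[state]
        return box.shrink(self.region_margin_mm).intersect(core)

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ConfigError("duration_s and fps must be positive")
        for p in (self.miss_prob, self.false_box_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probabilities must be in [0, 1], got {p}")
        if len(self.hourly_activity) != 24 or any(m <= 0 for m in self.hourly_activity):
            raise ConfigError("hourly_activity must be 24 positive multipliers")
        if self.initial_state not in _STATES:
            raise ConfigError(f"initial_state must be one of {_STATES}")
        for s in _STATES:
            if self.mean_dwell_s.get(s, 0) <= 0:
                raise ConfigError(f"mean dwell for {s!r} must be positive")
            row = self.transition.get(s)
            if row is None:
                raise ConfigError(f"transition row missing for state {s!r}")
            if s in row:
                raise ConfigError(f"self-transition not allowed for {s!r}")
            if any(p < 0 for p in row.values()) or abs(sum(row.values()) - 1.0) > 1e-9:
                raise ConfigError(f"transition row for {s!r} must be non-negative and sum to 1")
            self.walk_bounds(s)  # raises if geometry is inconsistent


@dataclass
class GroundTruth:
    """The simulator's hidden truth for one session."""

    scenario: SimScenario
    timestamps_s: np.ndarray  # (n,)
    positions_mm: np.ndarray  # (n, 3) cage coordinates
    regions: np.ndarray  # (n,) object array over {house, wheel, outside}
    sojourns: pd.DataFrame  # state, start_s, end_s
    hourly: pd.DataFrame  # hour_index, hour_start_clock, wheel_seconds, revolutions

    @property
    def dwell_seconds(self) -> dict[str, float]:
        """Frame-quantised region occupancy, the quantity a frame-level
        tracker can at best recover."""
        return {
            s: float(np.count_nonzero(self.regions == s)) / self.scenario.fps for s in _STATES
        }

    def outside_activity_m(self, mode: str = "euclidean") -> float:
        both = (self.regions[:-1] == "outside") & (self.regions[1:] == "outside")
        d = np.diff(self.positions_mm, axis=0)
        sq = np.sum(d**2, axis=1)
        steps = sq if mode == "squared" else np.sqrt(sq)
        return float(np.sum(steps[both])) / 1000.0

    def hourly_wheel_seconds(self) -> np.ndarray:
        return self.hourly["wheel_seconds"].to_numpy()


def _fold(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded walk into [lo, hi] (triangle-wave folding —
    the exact law of a reflected random walk)."""
    width = hi - lo
    if width <= 0:
        return np.full_like(u, lo)
    y = np.mod(u - lo, 2.0 * width)
    return lo + np.minimum(y, 2.0 * width - y)


def _clock_hour(scenario: SimScenario, t_s: float) -> int:
    from .metrics import parse_clock

    return int(((parse_clock(scenario.session_start_clock) + t_s) % 86400.0) // 3600)


def simulate_session(scenario: SimScenario) -> GroundTruth:
    """Draw one session: sojourn schedule, trajectory, wheel counts."""
    scenario.validate()
    rng = substream(scenario.seed, "trajectory")
    rng_wheel = substream(scenario.seed, "wheel")
    n = scenario.n_frames
    t = np.arange(n) / scenario.fps

    # --- sojourn schedule -------------------------------------------------
    states: list[str] = []
    starts: list[float] = []
    ends: list[float] = []
    state = scenario.initial_state
    tau = 0.0
    while tau < scenario.duration_s:
        m = scenario.hourly_activity[_clock_hour(scenario, tau)]
        mean = scenario.mean_dwell_s[state]
        mean = mean / m if state == "house" else mean * m
        dwell = float(rng.exponential(mean))
        states.append(state)
        starts.append(tau)
        ends.append(min(tau + dwell, scenario.duration_s))
        tau += dwell
        row = scenario.transition[state]
        nxt = list(row)
        state = str(rng.choice(nxt, p=[row[k] for k in nxt]))
    sojourns = pd.DataFrame({"state": states, "start_s": starts, "end_s": ends})

    # --- per-frame regions ------------------------------------------------
    seg_of_frame = np.searchsorted(np.asarray(ends), t, side="right")
    seg_of_frame = np.minimum(seg_of_frame, len(states) - 1)
    regions = np.asarray(states, dtype=object)[seg_of_frame]

    # --- trajectory: reflected walk per sojourn ---------------------------
    positions = np.empty((n, 3), dtype=float)
    steps = rng.standard_normal((n, 3))
    boundaries = np.searchsorted(seg_of_frame, np.arange(len(states)), side="left")
    boundaries = np.append(boundaries, n)
    for k, state_k in enumerate(states):
        a, b = boundaries[k], boundaries[k + 1]
        if a >= b:
            continue
        box = scenario.walk_bounds(state_k)
        lo, hi = box.lo, box.hi
        start = rng.uniform(lo, hi)
        walk = start + np.cumsum(steps[a:b] * scenario.step_mm[state_k], axis=0)
        for ax in range(3):
            positions[a:b, ax] = _fold(walk[:, ax], lo[ax], hi[ax])

    # --- hourly wheel counter --------------------------------------------
    n_hours = int(np.ceil(scenario.duration_s / 3600.0))
    hour_idx = np.floor(t / 3600.0).astype(np.int64)
    wheel_counts = np.bincount(hour_idx[regions == "wheel"], minlength=n_hours)
    wheel_seconds = wheel_counts / scenario.fps
    noise = rng_wheel.normal(0.0, scenario.wheel_noise_sd_rev, size=n_hours)
    revolutions = np.maximum(scenario.wheel_rate_rev_s * wheel_seconds + noise, 0.0).round()
    from .metrics import parse_clock

    start_clock = parse_clock(scenario.session_start_clock)
    clocks = [(start_clock + 3600.0 * h) % 86400.0 for h in range(n_hours)]
    hourly = pd.DataFrame(
        {
            "hour_index": np.arange(n_hours),
            "hour_start_clock": [f"{int(c // 3600):02d}:{int(c % 3600 // 60):02d}" for c in clocks],
            "wheel_seconds": wheel_seconds,
            "revolutions": revolutions,
        }
    )
    return GroundTruth(
        scenario=scenario,
        timestamps_s=t,
        positions_mm=positions,
        regions=regions,
        sojourns=sojourns,
        hourly=hourly,
    )


def _frame_from_columns(cols: Mapping[str, object]) -> pd.DataFrame:
    """Assemble a DataFrame one block per column (no consolidation copy;
    matters for multi-hour streams)."""
    return pd.concat(
        [pd.Series(v, name=k, copy=False) for k, v in cols.items()], axis=1, copy=False
    )


def _static_boxes_px(scenario: SimScenario, frame_size: Sequence[int]) -> dict[str, dict[str, tuple]]:
    """House and wheel boxes projected to (x, y, w, h) px per view."""
    cal = scenario.calibration_for(frame_size)
    out: dict[str, dict[str, tuple]] = {}
    for label, box in (("house", scenario.house_box_mm), ("wheel", scenario.wheel_box_mm)):
        cx, cy, cz = box.center
        w, d, h = box.size
        out[label] = {
            "front": (cx / cal.scale_x, cz / cal.scale_z, w / cal.scale_x, h / cal.scale_z),
            "side": (cy / cal.scale_y, cz / cal.scale_z, d / cal.scale_y, h / cal.scale_z),
        }
    return out


def project_views(
    truth: GroundTruth, scenario: SimScenario | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project the true trajectory into the two uncorrupted detection
    streams (the exact inverse of position fusion).

    The front view images cage width against height, the side view cage
    depth against height; static house and wheel boxes are emitted every
    frame.  Side timestamps carry the scenario's inter-camera latency
    offset.
    """
    scenario = scenario or truth.scenario
    cal = scenario.calibration
    n = len(truth.timestamps_s)
    t = truth.timestamps_s
    X, Y, Z = truth.positions_mm[:, 0], truth.positions_mm[:, 1], truth.positions_mm[:, 2]
    statics = _static_boxes_px(scenario, scenario.frame_size)
    ml, md, mh = scenario.mouse_size_mm

    def one_view(view: str) -> pd.DataFrame:
        ts = t + (scenario.latency_offset_s if view == "side" else 0.0)
        if view == "front":
            mx, my = X / cal.scale_x, Z / cal.scale_z
            mw, mhh = ml / cal.scale_x, mh / cal.scale_z
        else:
            mx, my = Y / cal.scale_y, Z / cal.scale_z
            mw, mhh = md / cal.scale_y, mh / cal.scale_z
        frames = np.arange(n, dtype=np.int64)
        hb = statics["house"][view]
        wb = statics["wheel"][view]

        # three records per frame, interleaved house/mouse/wheel so the
        # stream is already frame-sorted
        def inter(a, b, c):
            out = np.empty((n, 3))
            out[:, 0], out[:, 1], out[:, 2] = a, b, c
            return out.ravel()

        return _frame_from_columns(
            {
                "frame_index": np.repeat(frames, 3),
                "timestamp_s": np.repeat(ts, 3),
                "view": pd.Categorical.from_codes(
                    np.zeros(3 * n, dtype=np.int8), categories=[view]
                ),
                "label": pd.Categorical.from_codes(
                    np.tile(np.array([0, 1, 2], dtype=np.int8), n),
                    categories=["house", "mouse", "wheel"],
                ),
                "x": inter(hb[0], mx, wb[0]),
                "y": inter(hb[1], my, wb[1]),
                "w": inter(hb[2], mw, wb[2]),
                "h": inter(hb[3], mhh, wb[3]),
                "confidence": inter(0.97, 0.95, 0.97),
            }
        )

    return one_view("front"), one_view("side")


def corrupt_stream(
    stream: pd.DataFrame, scenario: SimScenario, rng: np.random.Generator | str = "corrupt"
) -> pd.DataFrame:
    """Degrade a stream the way a real detector fails.

    Mouse records are independently dropped with ``miss_prob`` (shadowed or
    untrained postures), surviving mouse midpoints get isotropic Gaussian
    pixel jitter, and spurious low-confidence mouse boxes are injected at
    ``false_box_rate`` per frame.  Static-object records are left intact.
    """
    if isinstance(rng, str):
        rng = substream(scenario.seed, rng)
    # column-wise to avoid whole-frame copies on multi-hour streams;
    # view/label stay categorical end to end
    numeric = ("frame_index", "timestamp_s", "x", "y", "w", "h", "confidence")
    cols: dict[str, object] = {c: np.asarray(stream[c]) for c in numeric}
    cols["view"] = stream["view"].array if stream["view"].dtype == "category" else np.asarray(stream["view"])
    cols["label"] = stream["label"].array if stream["label"].dtype == "category" else np.asarray(stream["label"])
    mouse = np.asarray(stream["label"] == "mouse")
    n_mouse = int(mouse.sum())
    if scenario.miss_prob > 0 and n_mouse:
        drop = rng.random(n_mouse) < scenario.miss_prob
        keep = np.ones(len(mouse), dtype=bool)
        keep[np.flatnonzero(mouse)[drop]] = False
        cols = {c: v[keep] for c, v in cols.items()}
        mouse = mouse[keep]
        n_mouse = int(mouse.sum())
    if scenario.jitter_sd_px > 0 and n_mouse:
        jit = rng.normal(0.0, scenario.jitter_sd_px, size=(n_mouse, 2))
        x = np.array(cols["x"], dtype=float)
        y = np.array(cols["y"], dtype=float)
        x[mouse] += jit[:, 0]
        y[mouse] += jit[:, 1]
        cols["x"], cols["y"] = x, y
    if scenario.false_box_rate > 0:
        frame = np.asarray(cols["frame_index"])
        first = np.ones(len(frame), dtype=bool)
        first[1:] = frame[1:] != frame[:-1]
        uf = frame[first]
        uts = np.asarray(cols["timestamp_s"])[first]
        hit = rng.random(len(uf)) < scenario.false_box_rate
        n_fake = int(hit.sum())
        if n_fake:
            w, h = scenario.frame_size
            view_value = str(np.asarray(stream["view"])[0]) if len(stream) else "front"
            fake = pd.DataFrame(
                {
                    "frame_index": uf[hit],
                    "timestamp_s": uts[hit],
                    "view": view_value,
                    "label": "mouse",
                    "x": rng.uniform(0, w, size=n_fake),
                    "y": rng.uniform(0, h, size=n_fake),
                    "w": rng.uniform(20, 80, size=n_fake),
                    "h": rng.uniform(20, 80, size=n_fake),
                    "confidence": rng.uniform(0.1, 0.5, size=n_fake),
                }
            )
            base = _frame_from_columns(cols)
            for c in ("view", "label"):
                base[c] = base[c].astype(str)
            df = pd.concat([base, fake], ignore_index=True)
            df = df.sort_values("frame_index", kind="stable").reset_index(drop=True)
            df["view"] = df["view"].astype("category")
            df["label"] = df["label"].astype("category")
            return df
    return _frame_from_columns(cols)


def simulate_streams(
    scenario: SimScenario,
) -> tuple[GroundTruth, pd.DataFrame, pd.DataFrame]:
    """Full generator: ground truth plus the two corrupted streams."""
    truth = simulate_session(scenario)
    front, side = project_views(truth, scenario)
    front = corrupt_stream(front, scenario, substream(scenario.seed, "front_corrupt"))
    side = corrupt_stream(side, scenario, substream(scenario.seed, "side_corrupt"))
    return truth, front, side


# --- rendering -------------------------------------------------------------

_BG, _HOUSE_VAL, _WHEEL_VAL, _MOUSE_VAL = 8, 60, 105, 255


def render_reference_frame(
    scenario: SimScenario, view: str, frame_size: Sequence[int] | None = None
) -> np.ndarray:
    """Background frame with the static region markers and no mouse:
    dim rectangles for house and wheel on a dark floor."""
    w, h = frame_size or scenario.frame_size
    if w <= 0 or h <= 0:
        raise InputError("frame size must be positive")
    img = np.full((h, w), _BG, dtype=np.uint8)
    statics = _static_boxes_px(scenario, (w, h))
    for label, val in (("house", _HOUSE_VAL), ("wheel", _WHEEL_VAL)):
        bx, by, bw, bh = statics[label][view]
        x0 = max(int(round(bx - bw / 2)), 0)
        x1 = min(int(round(bx + bw / 2)), w)
        y0 = max(int(round(by - bh / 2)), 0)
        y1 = min(int(round(by + bh / 2)), h)
        img[y0:y1, x0:x1] = val
    return img


def _ellipse_mask(a_px: float, b_px: float) -> tuple[np.ndarray, np.ndarray]:
    a = max(a_px, 1.0)
    b = max(b_px, 1.0)
    dx = np.arange(-int(np.ceil(a)), int(np.ceil(a)) + 1)
    dy = np.arange(-int(np.ceil(b)), int(np.ceil(b)) + 1)
    DX, DY = np.meshgrid(dx, dy)
    inside = (DX / a) ** 2 + (DY / b) ** 2 <= 1.0
    return DX[inside], DY[inside]


def render_frames(
    truth: GroundTruth,
    scenario: SimScenario | None = None,
    frame_size: Sequence[int] | None = None,
    indices: Sequence[int] | None = None,
) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    """Yield ``(frame_index, front_image, side_image)`` grayscale frames.

    The mouse is a bright ellipse centred on its projected midpoint with
    axes matching its configured body size; house and wheel are static dim
    rectangles.  A body partially outside the frame is clipped.
    Deterministic: rendering draws no randomness.
    """
    scenario = scenario or truth.scenario
    size = tuple(frame_size or scenario.frame_size)
    cal = scenario.calibration_for(size)
    templates = {v: render_reference_frame(scenario, v, size) for v in ("front", "side")}
    ml, md, mh = scenario.mouse_size_mm
    masks = {
        "front": _ellipse_mask(0.5 * ml / cal.scale_x, 0.5 * mh / cal.scale_z),
        "side": _ellipse_mask(0.5 * md / cal.scale_y, 0.5 * mh / cal.scale_z),
    }
    X, Y, Z = truth.positions_mm[:, 0], truth.positions_mm[:, 1], truth.positions_mm[:, 2]
    w, h = size
    idx = range(len(truth.timestamps_s)) if indices is None else indices
    for i in idx:
        imgs = {}
        for view in ("front", "side"):
            img = templates[view].copy()
            if view == "front":
                cx, cy = X[i] / cal.scale_x, Z[i] / cal.scale_z
            else:
                cx, cy = Y[i] / cal.scale_y, Z[i] / cal.scale_z
            dx, dy = masks[view]
            px = np.round(cx + dx).astype(int)
            py = np.round(cy + dy).astype(int)
            ok = (px >= 0) & (px < w) & (py >= 0) & (py < h)
            img[py[ok], px[ok]] = _MOUSE_VAL
            imgs[view] = img
        yield i, imgs["front"], imgs["side"]


def write_session(
    scenario: SimScenario,
    out_dir: str | Path,
    render: bool = False,
    render_size: Sequence[int] | None = None,
) -> GroundTruth:
    """Materialise a session on disk: detection CSVs, revolutions CSV,
    ground-truth JSON (+ optional PNG frames)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, front, side = simulate_streams(scenario)
    front.to_csv(out / "front.csv", index=False, columns=list(STREAM_COLUMNS))
    side.to_csv(out / "side.csv", index=False, columns=list(STREAM_COLUMNS))
    truth.hourly[["hour_index", "hour_start_clock", "revolutions"]].to_csv(
        out / "revolutions.csv", index=False
    )
    gt = {
        "dwell_seconds": truth.dwell_seconds,
        "outside_activity_m": truth.outside_activity_m(),
        "hourly_wheel_seconds": truth.hourly["wheel_seconds"].tolist(),
        "hourly_revolutions": truth.hourly["revolutions"].tolist(),
        "duration_s": scenario.duration_s,
        "fps": scenario.fps,
        "session_start_clock": scenario.session_start_clock,
    }
    import json

    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2))
    if render:
        frames_dir = out / "frames"
        for view in ("front", "side"):
            (frames_dir / view).mkdir(parents=True, exist_ok=True)
        for i, f_img, s_img in render_frames(truth, scenario, frame_size=render_size):
            iio.imwrite(frames_dir / "front" / f"{i:06d}.png", f_img)
            iio.imwrite(frames_dir / "side" / f"{i:06d}.png", s_img)
        for view in ("front", "side"):
            iio.imwrite(
                frames_dir / f"reference_{view}.png",
                render_reference_frame(scenario, view, render_size),
            )
    return truth
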