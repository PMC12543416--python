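"""Dual-view geometric core.

Two orthogonal cameras watch a home cage: the *front* view contributes the
cage-width (x) and height axes, the *side* view the cage-depth (y) and
height axes.  Every detection is a midpoint-based bounding box
``(x, y, w, h)`` in image pixels, origin top-left, y increasing downward.

This module holds the pure functions the rest of the pipeline is built on:

* midpoint-in-box containment (one view, and the two-view conjunction that
  decides region occupancy),
* fusion of the two 2D midpoints into a 3D cage position
  ``P = (F_x, S_x, (F_y + S_y)/2)``,
* frame-to-frame step and cumulative path distances.

All functions have vectorised array counterparts used by the frame-level
pipeline; the scalar forms exist for clarity and for record-level callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError

__all__ = [
    "View",
    "BoundingBox",
    "ViewPoint2D",
    "Position3D",
    "Calibration",
    "point_in_box",
    "points_in_box",
    "in_region_both_views",
    "fuse_views",
    "fuse_views_arrays",
    "step_distance",
    "path_distance",
]


class View(str, Enum):
    """Camera perspective."""

    FRONT = "front"
    SIDE = "side"


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise InputError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class BoundingBox:
    """Midpoint-based box: ``(x, y)`` is the centre, ``w``/``h`` the full
    extents, all in pixels of one camera view."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        _require_finite("BoundingBox coordinates", self.x, self.y, self.w, self.h)
        if self.w <= 0 or self.h <= 0:
            raise InputError(f"box extents must be positive, got w={self.w}, h={self.h}")

    @property
    def x_min(self) -> float:
        return self.x - 0.5 * self.w

    @property
    def x_max(self) -> float:
        return self.x + 0.5 * self.w

    @property
    def y_min(self) -> float:
        return self.y - 0.5 * self.h

    @property
    def y_max(self) -> float:
        return self.y + 0.5 * self.h

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class ViewPoint2D:
    """A pixel point in one camera view (typically an object midpoint)."""

    x: float
    y: float
    view: View

    def __post_init__(self) -> None:
        _require_finite("ViewPoint2D coordinates", self.x, self.y)
        object.__setattr__(self, "view", View(self.view))


@dataclass(frozen=True)
class Position3D:
    """Fused cage coordinate.

    ``x`` runs along the cage width (front-view horizontal), ``y`` along
    the cage depth (side-view horizontal), ``z`` along the height, in the
    image convention: z grows downward, so larger z means lower in the
    cage.  ``unit`` is ``"px"`` before calibration, ``"mm"`` after.
    """

    x: float
    y: float
    z: float
    unit: str = "px"

    def __post_init__(self) -> None:
        _require_finite("Position3D coordinates", self.x, self.y, self.z)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class Calibration:
    """Per-axis linear pixel-to-millimetre scales on the fused axes.

    Computed from the known interior cage dimensions and the pixel extent
    the cage spans in each view; the default (identity) leaves everything
    in pixels.  The z scale is shared by both views, which assumes the two
    cameras resolve height equally — adequate for cameras at comparable
    distances from a small cage.
    """

    scale_x: float = 1.0
    scale_y: float = 1.0
    scale_z: float = 1.0
    cage_dims: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0 or self.scale_z <= 0:
            raise InputError("calibration scales must be positive")

    @classmethod
    def from_cage_extents(
        cls,
        cage_dims_mm: tuple[float, float, float],
        front_extent_px: tuple[float, float],
        side_extent_px: tuple[float, float],
    ) -> "Calibration":
        """Scales from the cage's (width, depth, height) in mm and the
        pixel span of the cage in each view ((width_px, height_px) front,
        (depth_px, height_px) side).  The height scale averages the two
        views' height spans."""
        w_mm, d_mm, h_mm = cage_dims_mm
        fz = h_mm / front_extent_px[1]
        sz = h_mm / side_extent_px[1]
        return cls(
            scale_x=w_mm / front_extent_px[0],
            scale_y=d_mm / side_extent_px[0],
            scale_z=0.5 * (fz + sz),
            cage_dims=(w_mm, d_mm, h_mm),
        )

    def to_mm(self, p: Position3D) -> Position3D:
        if p.unit == "mm":
            return p
        return Position3D(p.x * self.scale_x, p.y * self.scale_y, p.z * self.scale_z, unit="mm")

    def arrays_to_mm(
        self, x: np.ndarray, y: np.ndarray, z: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return x * self.scale_x, y * self.scale_y, z * self.scale_z


def point_in_box(p: ViewPoint2D, box: BoundingBox) -> bool:
    """Strict interval containment of a midpoint in a box.

    Boundary points count as outside.  Containment uses the midpoint only,
    not box overlap: region membership is decided by where the animal's
    centre sits.
    """
    _require_finite("point", p.x, p.y)
    return (box.x_min < p.x < box.x_max) and (box.y_min < p.y < box.y_max)


def points_in_box(
    xs: np.ndarray,
    ys: np.ndarray,
    box_x: np.ndarray | float,
    box_y: np.ndarray | float,
    box_w: np.ndarray | float,
    box_h: np.ndarray | float,
) -> np.ndarray:
    """Vectorised :func:`point_in_box`; box parameters may be scalars or
    per-frame arrays.  NaN coordinates yield ``False``."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    with np.errstate(invalid="ignore"):
        inside = (
            (np.abs(xs - box_x) < 0.5 * np.asarray(box_w))
            & (np.abs(ys - box_y) < 0.5 * np.asarray(box_h))
        )
    return inside & np.isfinite(xs) & np.isfinite(ys)


def _check_views(front: ViewPoint2D, side: ViewPoint2D) -> None:
    if front.view is not View.FRONT or side.view is not View.SIDE:
        raise InputError(
            f"expected (front, side) points, got ({front.view.value}, {side.view.value})"
        )


def in_region_both_views(
    rodent_front: ViewPoint2D,
    rodent_side: ViewPoint2D,
    region_front: BoundingBox,
    region_side: BoundingBox,
) -> bool:
    """Two-view region test: the animal occupies a region only when its
    midpoint lies inside the region's box in the front view *and* in the
    side view."""
    _check_views(rodent_front, rodent_side)
    return point_in_box(rodent_front, region_front) and point_in_box(rodent_side, region_side)


def fuse_views(f: ViewPoint2D, s: ViewPoint2D) -> Position3D:
    """Combine front and side midpoints into a 3D cage position:
    ``x`` from the front horizontal, ``y`` from the side horizontal, ``z``
    the mean of the two vertical coordinates."""
    _check_views(f, s)
    return Position3D(f.x, s.x, 0.5 * (f.y + s.y), unit="px")


def fuse_views_arrays(
    fx: np.ndarray, fy: np.ndarray, sx: np.ndarray, sy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised :func:`fuse_views` on per-frame coordinate arrays."""
    fx = np.asarray(fx, dtype=float)
    sy = np.asarray(sy, dtype=float)
    return fx, np.asarray(sx, dtype=float), 0.5 * (np.asarray(fy, dtype=float) + sy)


_MODES = ("euclidean", "squared")


def _as_xyz(p: Position3D | Sequence[float]) -> tuple[float, float, float, str]:
    if isinstance(p, Position3D):
        return p.x, p.y, p.z, p.unit
    x, y, z = p
    return float(x), float(y), float(z), "px"


def step_distance(
    p_prev: Position3D | Sequence[float],
    p_curr: Position3D | Sequence[float],
    mode: str = "euclidean",
) -> float:
    """Displacement between two consecutive fused positions.

    ``euclidean`` is the usual L2 norm and the default, since travelled
    distance is ultimately reported in metres.  ``squared`` returns
    the plain sum of squared per-axis differences (no square root), kept
    — the squared-sum form some wheel-rig loggers record.
    """
    if mode not in _MODES:
        raise InputError(f"unknown distance mode {mode!r}; expected one of {_MODES}")
    x0, y0, z0, u0 = _as_xyz(p_prev)
    x1, y1, z1, u1 = _as_xyz(p_curr)
    if u0 != u1:
        raise InputError(f"unit mismatch: {u0!r} vs {u1!r}")
    sq = (x1 - x0) ** 2 + (y1 - y0) ** 2 + (z1 - z0) ** 2
    return sq if mode == "squared" else math.sqrt(sq)


def path_distance(
    trajectory: Iterable[Position3D] | np.ndarray, mode: str = "euclidean"
) -> float:
    """Cumulative distance over consecutive pairs of a trajectory.

    Accepts a sequence of :class:`Position3D` or an ``(n, 3)`` array; a
    single-point trajectory has zero length, an empty one is an error.
    """
    if mode not in _MODES:
        raise InputError(f"unknown distance mode {mode!r}; expected one of {_MODES}")
    if isinstance(trajectory, np.ndarray):
        pts = np.asarray(trajectory, dtype=float)
    else:
        traj = list(trajectory)
        if traj and isinstance(traj[0], Position3D):
            units = {p.unit for p in traj}
            if len(units) > 1:
                raise InputError(f"mixed units in trajectory: {sorted(units)}")
            pts = np.array([[p.x, p.y, p.z] for p in traj], dtype=float)
        else:
            pts = np.asarray(traj, dtype=float)
    if pts.size == 0:
        raise InputError("empty trajectory")
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"trajectory must be (n, 3), got shape {pts.shape}")
    if len(pts) == 1:
        return 0.0
    sq = np.sum(np.diff(pts, axis=0) ** 2, axis=1)
    return float(np.sum(sq if mode == "squared" else np.sqrt(sq)))
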