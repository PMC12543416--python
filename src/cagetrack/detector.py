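"""Threshold-and-connected-components blob detector.

A deliberately simple stand-in for the learned object detector a real rig
would run: it finds the mouse in a grayscale frame by intensity
thresholding, 4-connected component labelling, an area filter, and taking
the largest surviving component's bounding box.  On simulator-rendered
frames (bright mouse body on a dark floor with dim region markers) this
recovers midpoints to within a pixel or two, which is all the downstream
geometry needs — it makes no attempt at the accuracy of a trained network
on real infrared video.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import ConfigError, InputError
from .geometry import BoundingBox, View
from .streams import STREAM_COLUMNS, DetectionRecord

__all__ = ["DetectorConfig", "detect_mouse", "detect_static_regions", "detect_session"]


@dataclass(frozen=True)
class DetectorConfig:
    """Blob-detector knobs.

    ``threshold`` is a fixed intensity cut in [0, 255] or ``"otsu"``;
    a fixed cut above the region-marker intensities (e.g. 180) is the
    reproducible choice on rendered frames, where Otsu may settle between
    the floor and the markers instead of isolating the bright body.
    ``house_band``/``wheel_band`` are the marker intensity ranges used by
    :func:`detect_static_regions`.
    """

    threshold: float | str = "otsu"
    min_area: int = 20
    max_components: int = 10
    house_band: tuple[float, float] = (40.0, 80.0)
    wheel_band: tuple[float, float] = (85.0, 125.0)

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ConfigError("min_area must be >= 1")
        if not isinstance(self.threshold, str):
            if not 0 <= float(self.threshold) <= 255:
                raise ConfigError("fixed threshold must lie in [0, 255]")
        elif self.threshold != "otsu":
            raise ConfigError(f"unknown threshold {self.threshold!r}")


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise InputError(f"expected a non-empty 2D grayscale frame, got shape {frame.shape}")
    return frame


def _largest_component(mask: np.ndarray, config: DetectorConfig):
    labels = cc_label(mask, connectivity=1)
    props = regionprops(labels)
    props = [p for p in props if p.area >= config.min_area]
    if not props:
        return None
    props.sort(key=lambda p: p.area, reverse=True)
    return props[0] if props[:config.max_components] else None


def _box_of(prop) -> BoundingBox:
    y0, x0, y1, x1 = prop.bbox
    return BoundingBox(x=(x0 + x1) / 2.0, y=(y0 + y1) / 2.0, w=float(x1 - x0), h=float(y1 - y0))


def detect_mouse(
    frame: np.ndarray,
    config: DetectorConfig = DetectorConfig(),
    frame_index: int = 0,
    timestamp: float = 0.0,
    view: View | str = View.FRONT,
) -> DetectionRecord | None:
    """Detect the mouse blob in one frame, or ``None`` if nothing bright
    and large enough is present.

    Confidence is the mean intensity of the winning component over 255 — a
    crude proxy that still ranks a bright body above dim spurious blobs.
    """
    frame = _check_frame(frame)
    if isinstance(config.threshold, str):
        if frame.max() == frame.min():
            return None
        thr = threshold_otsu(frame)
    else:
        thr = float(config.threshold)
    mask = frame > thr
    if not mask.any():
        return None
    prop = _largest_component(mask, config)
    if prop is None:
        return None
    ys, xs = prop.coords[:, 0], prop.coords[:, 1]
    confidence = float(np.clip(frame[ys, xs].mean() / 255.0, 0.0, 1.0))
    return DetectionRecord(
        frame_index=frame_index,
        timestamp=timestamp,
        label="mouse",
        box=_box_of(prop),
        confidence=confidence,
        view=View(view),
    )


def detect_static_regions(
    reference_frame: np.ndarray, config: DetectorConfig = DetectorConfig()
) -> dict[str, BoundingBox]:
    """Locate the house and wheel markers in a mouse-free reference frame
    by their intensity bands; raises if either marker is missing."""
    frame = _check_frame(reference_frame)
    out: dict[str, BoundingBox] = {}
    for name, (lo, hi) in (("house", config.house_band), ("wheel", config.wheel_band)):
        mask = (frame >= lo) & (frame <= hi)
        prop = _largest_component(mask, config)
        if prop is None:
            raise ConfigError(f"static region {name!r} not found in reference frame")
        out[name] = _box_of(prop)
    return out


def detect_session(
    frames: Iterable[tuple[int, float, np.ndarray]],
    view: View | str,
    static_boxes: Mapping[str, BoundingBox],
    config: DetectorConfig = DetectorConfig(),
) -> pd.DataFrame:
    """Run the detector over a frame sequence and emit a detection stream.

    ``frames`` yields ``(frame_index, timestamp_s, image)``.  Static house
    and wheel boxes (from :func:`detect_static_regions` on a reference
    frame) are attached to every frame, mirroring a detector that reports
    all three objects.
    """
    view = View(view)
    rows = []
    for frame_index, ts, img in frames:
        rec = detect_mouse(img, config, frame_index=frame_index, timestamp=ts, view=view)
        if rec is not None:
            rows.append(
                (frame_index, ts, view.value, "mouse", rec.box.x, rec.box.y, rec.box.w, rec.box.h, rec.confidence)
            )
        for label in ("house", "wheel"):
            b = static_boxes[label]
            rows.append((frame_index, ts, view.value, label, b.x, b.y, b.w, b.h, 0.97))
    return pd.DataFrame(rows, columns=list(STREAM_COLUMNS))
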