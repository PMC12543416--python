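"""Cross-modality agreement and parameter-recovery statistics.

Two independent instruments can watch the same wheel: the camera pipeline
books *wheel time* (seconds of occupancy) while a magnetic counter books
*revolutions*.  If both work, their hourly series must co-vary strongly;
the Pearson product-moment correlation of the paired hourly values is the
agreement statistic.  Against simulated sessions, where ground truth is
known, :func:`recovery_report` quantifies how faithfully the pipeline
recovers region times and travel distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .metrics import MetricsReport, hourly_region_seconds
from .simulate import GroundTruth

__all__ = ["HourlyActivityPair", "pearson_r", "recovery_report"]


@dataclass(frozen=True)
class HourlyActivityPair:
    """One hour's wheel occupancy (camera) and revolutions (counter)."""

    hour_index: int
    wheel_time_s: float
    revolutions: float

    def __post_init__(self) -> None:
        if self.wheel_time_s < 0 or self.revolutions < 0:
            raise InputError("wheel time and revolutions must be non-negative")


def pearson_r(
    pairs: Sequence[HourlyActivityPair] | tuple[np.ndarray, np.ndarray],
) -> tuple[float, float]:
    """Pearson correlation of hourly wheel time against revolutions, with
    the two-sided p-value from the t transform on n - 2 degrees of
    freedom.  Requires at least three pairs and nonzero variance in both
    series."""
    if isinstance(pairs, tuple) and len(pairs) == 2 and not isinstance(pairs[0], HourlyActivityPair):
        x = np.asarray(pairs[0], dtype=float)
        y = np.asarray(pairs[1], dtype=float)
    else:
        x = np.array([p.wheel_time_s for p in pairs], dtype=float)
        y = np.array([p.revolutions for p in pairs], dtype=float)
    if len(x) != len(y):
        raise InputError("paired series must have equal length")
    if len(x) < 3:
        raise InputError(f"need at least 3 pairs, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("correlation undefined: a series has zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def recovery_report(
    truth: GroundTruth,
    report: MetricsReport,
    regions: np.ndarray | None = None,
    timestamps_s: np.ndarray | None = None,
) -> pd.DataFrame:
    """Absolute and relative errors of the pipeline against ground truth.

    Compares session-level house/wheel/outside times and outside activity,
    plus (when per-frame classifications are supplied) the per-hour wheel
    time series.  Relative error is against the frame-quantised truth; a
    zero-truth metric reports NaN relative error.
    """
    n_truth = len(truth.timestamps_s)
    if abs(report.session.n_frames - n_truth) > 0.05 * n_truth:
        raise InputError(
            f"session length mismatch: truth has {n_truth} frames, report {report.session.n_frames}"
        )
    rows = []
    true_dwell = truth.dwell_seconds
    est = {
        "t_house_s": report.session.t_house,
        "t_wheel_s": report.session.t_wheel,
        "t_outside_s": report.session.t_outside,
    }
    for region in ("house", "wheel", "outside"):
        tv = true_dwell[region]
        ev = est[f"t_{region}_s"]
        rows.append(("t_%s_s" % region, tv, ev))
    unit = report.distance_unit
    true_act = truth.outside_activity_m()
    if unit == "m":
        rows.append(("outside_activity_m", true_act, report.session.outside_activity))
    out = pd.DataFrame(rows, columns=["metric", "truth", "estimate"])
    out["abs_error"] = (out["estimate"] - out["truth"]).abs()
    out["rel_error"] = out["abs_error"] / out["truth"].where(out["truth"] > 0)

    if regions is not None and timestamps_s is not None:
        rec = hourly_region_seconds(regions, timestamps_s, report.fps)
        true_hw = truth.hourly_wheel_seconds()
        est_hw = np.zeros(len(true_hw))
        got = rec.set_index("hour_index")["wheel_s"]
        for h in got.index:
            if 0 <= h < len(est_hw):
                est_hw[h] = got.loc[h]
        err = float(np.abs(est_hw - true_hw).mean())
        denom = float(true_hw.mean()) if true_hw.mean() > 0 else np.nan
        extra = pd.DataFrame(
            [
                {
                    "metric": "hourly_wheel_time_mae_s",
                    "truth": 0.0,
                    "estimate": err,
                    "abs_error": err,
                    "rel_error": err / denom if denom == denom else np.nan,
                }
            ]
        )
        out = pd.concat([out, extra], ignore_index=True)
    return out
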