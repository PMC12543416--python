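"""Region classification, time accumulation, phases, report aggregation."""

import numpy as np
import pandas as pd
import pytest

from cagetrack.errors import ConfigError, InputError
from cagetrack.geometry import BoundingBox, Calibration, View, ViewPoint2D
from cagetrack.metrics import (
    PERIOD_SCHEDULE,
    PHASE_SCHEDULE,
    PhaseWindow,
    accumulate_times,
    aggregate_report,
    classify_frame,
    classify_frames,
    hourly_region_seconds,
    outside_activity,
    read_revolutions,
    region_counts,
    running_speed,
    segment_phases,
)

HOUSE_F = BoundingBox(50, 80, 40, 30)
HOUSE_S = BoundingBox(30, 80, 30, 30)
WHEEL_F = BoundingBox(150, 40, 50, 50)
WHEEL_S = BoundingBox(120, 40, 30, 50)


def _pt(x, y, view):
    return ViewPoint2D(x, y, View(view))


class TestClassifyFrame:
    def test_inside_wheel_both_views(self):
        fc = classify_frame(0, _pt(150, 40, "front"), _pt(120, 40, "side"), (HOUSE_F, HOUSE_S), (WHEEL_F, WHEEL_S))
        assert fc.region == "wheel"
        assert fc.position is not None

    def test_inside_house_front_only_is_outside(self):
        fc = classify_frame(0, _pt(50, 80, "front"), _pt(120, 40, "side"), (HOUSE_F, HOUSE_S), (WHEEL_F, WHEEL_S))
        assert fc.region == "outside"

    def test_overlapping_projections_prefer_wheel(self):
        house_f = BoundingBox(150, 40, 60, 60)  # overlaps the wheel's image
        house_s = BoundingBox(120, 40, 40, 60)
        fc = classify_frame(0, _pt(150, 40, "front"), _pt(120, 40, "side"), (house_f, house_s), (WHEEL_F, WHEEL_S))
        assert fc.region == "wheel"
        fc2 = classify_frame(
            0,
            _pt(150, 40, "front"),
            _pt(120, 40, "side"),
            (house_f, house_s),
            (WHEEL_F, WHEEL_S),
            precedence=("house", "wheel"),
        )
        assert fc2.region == "house"

    def test_missing_position_is_unknown(self):
        fc = classify_frame(3, None, _pt(1, 1, "side"), (HOUSE_F, HOUSE_S), (WHEEL_F, WHEEL_S))
        assert fc.region == "unknown" and fc.position is None

    def test_independent_of_mouse_box_size(self, rng):
        """Classification uses midpoints only, never the mouse box extent:
        the vectorised path takes bare coordinates."""
        fxy = rng.uniform(0, 200, size=(50, 2))
        sxy = rng.uniform(0, 200, size=(50, 2))
        r1, _ = classify_frames(fxy, sxy, (HOUSE_F, HOUSE_S), (WHEEL_F, WHEEL_S))
        scalar = [
            classify_frame(i, _pt(*fxy[i], "front"), _pt(*sxy[i], "side"), (HOUSE_F, HOUSE_S), (WHEEL_F, WHEEL_S)).region
            for i in range(50)
        ]
        assert r1.tolist() == scalar


class TestAccumulateTimes:
    def test_counts_over_fps(self):
        regions = np.array(["house"] * 15)
        assert accumulate_times(regions, 15.0)["house"] == pytest.approx(1.0)
        assert accumulate_times(regions, 15.0)["wheel"] == 0.0

    def test_conservation_of_counts(self):
        regions = np.array(["house"] * 10 + ["wheel"] * 10 + ["outside"] * 10)
        counts = region_counts(regions)
        assert sum(counts.values()) == 30
        times = accumulate_times(regions, 15.0)
        assert times["house"] == times["wheel"] == times["outside"] == pytest.approx(10 / 15)

    def test_bad_fps(self):
        with pytest.raises(ConfigError):
            accumulate_times(np.array(["house"]), 0.0)


class TestOutsideActivity:
    def test_all_house_is_zero(self):
        regions = np.array(["house"] * 10)
        pts = np.random.default_rng(0).uniform(0, 10, (10, 3))
        assert outside_activity(regions, pts) == 0.0

    def test_simple_pair(self):
        regions = np.array(["outside", "outside"])
        pts = np.array([[0.0, 0, 0], [3.0, 4, 0]])
        assert outside_activity(regions, pts) == pytest.approx(5.0)

    def test_interruption_not_counted(self):
        regions = np.array(["outside", "wheel", "outside"])
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0], [0.0, 3, 4]])
        assert outside_activity(regions, pts) == 0.0

    def test_calibrated_to_meters(self):
        cal = Calibration(scale_x=2.0, scale_y=2.0, scale_z=2.0)
        regions = np.array(["outside", "outside"])
        pts = np.array([[0.0, 0, 0], [300.0, 400.0, 0]])  # 500 px -> 1000 mm
        assert outside_activity(regions, pts, cal) == pytest.approx(1.0)

    def test_monotone_in_appended_frames(self, rng):
        pts = rng.uniform(0, 100, (50, 3))
        regions = np.array(rng.choice(["outside", "house"], 50))
        vals = [outside_activity(regions[:k], pts[:k]) for k in range(2, 51)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestRunningSpeed:
    def test_rev_per_second(self):
        assert running_speed(450, 900).rev_per_s == pytest.approx(0.5)

    def test_meters_per_second_from_circumference(self):
        # 0.5 rev/s on an 11.5 cm wheel: 0.5 * pi * 0.115 = 0.180642 m/s
        res = running_speed(450, 900, wheel_diameter_m=0.115)
        assert res.m_per_s == pytest.approx(0.180642, abs=1e-6)

    def test_degenerate_and_undefined(self):
        assert running_speed(0, 0).rev_per_s == 0.0
        assert running_speed(0, 0).undefined is False
        assert running_speed(10, 0).undefined is True

    def test_scale_equivariance(self):
        v1 = running_speed(100, 250).rev_per_s
        v2 = running_speed(200, 250).rev_per_s
        assert v2 == pytest.approx(2 * v1)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InputError):
            running_speed(-1, 10)
        with pytest.raises(InputError):
            running_speed(1, -10)


class TestSegmentPhases:
    def test_feeding_window_excluded_under_periods(self):
        # session starting 09:00; probe 4.5 h in = 13:30 local
        t = np.array([4.5 * 3600])
        out = segment_phases(t, "periods", "09:00")
        assert out[0] == "excluded"

    def test_midnight_spanning_window(self):
        # session starting 15:00; probe 11 h in = 02:00 local -> night activity
        out = segment_phases(np.array([11 * 3600.0]), "periods", "15:00")
        assert out[0] == "NA"
        out = segment_phases(np.array([11 * 3600.0]), "phases", "15:00")
        assert out[0] == "dark"

    def test_morning_probe_in_faa(self):
        out = segment_phases(np.array([0.0]), "periods", "10:30")
        assert out[0] == "FAA"

    def test_uncovered_clock_is_unassigned(self):
        # 14:00 under the light/dark preset falls between light2 and light1
        out = segment_phases(np.array([0.0]), "phases", "14:00")
        assert out[0] == "unassigned"

    def test_overlapping_windows_rejected(self):
        bad = [PhaseWindow("a", "09:00", "13:00"), PhaseWindow("b", "12:00", "15:00")]
        with pytest.raises(ConfigError):
            segment_phases(np.array([0.0]), bad, "09:00")


class TestAggregateReport:
    def test_uniform_outside_hour(self):
        n = 15 * 3600
        regions = np.array(["outside"] * n)
        pts = np.zeros((n, 3))
        t = np.arange(n) / 15.0
        rep = aggregate_report(regions, pts, t, fps=15.0, schedule="phases", session_start_clock="15:00")
        assert rep.phases["light1"].t_outside == pytest.approx(3600.0)
        assert rep.phases["light1"].t_house == 0.0
        assert rep.session.t_outside == pytest.approx(3600.0)

    def test_conservation_per_phase(self, rng):
        n = 20000
        regions = np.array(rng.choice(["house", "wheel", "outside", "unknown"], n))
        pts = rng.uniform(0, 100, (n, 3))
        pts[regions == "unknown"] = np.nan
        t = np.arange(n) / 15.0
        rep = aggregate_report(regions, pts, t, fps=15.0, schedule="periods", session_start_clock="08:00")
        for pm in [rep.session, *rep.phases.values()]:
            assert sum(pm.counts.values()) == pm.n_frames

    def test_revolutions_mapped_to_phase_by_hour_start(self):
        n = 15 * 7200  # two hours from 09:00: FAA hours
        regions = np.array(["wheel"] * n)
        pts = np.zeros((n, 3))
        t = np.arange(n) / 15.0
        revs = pd.DataFrame({"hour_start_clock": ["09:00", "10:00"], "revolutions": [600, 400]})
        rep = aggregate_report(
            regions, pts, t, fps=15.0, schedule="periods", session_start_clock="09:00", revolutions=revs
        )
        assert rep.phases["FAA"].revolutions == 1000
        assert rep.phases["FAA"].speed_rev_s == pytest.approx(1000 / 7200.0)
        assert rep.session.revolutions == 1000

    def test_tidy_frame_and_json_round_trip(self, tmp_path):
        regions = np.array(["house"] * 10)
        pts = np.zeros((10, 3))
        t = np.arange(10) / 15.0
        rep = aggregate_report(regions, pts, t, fps=15.0)
        tidy = rep.to_tidy_frame()
        assert {"phase", "metric", "value"} == set(tidy.columns)
        import json

        path = tmp_path / "report.json"
        rep.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["session"]["t_house_s"] == pytest.approx(10 / 15)


def test_hourly_region_seconds_bins_by_session_hour():
    regions = np.array(["wheel"] * 7200 + ["house"] * 3600)
    t = np.arange(len(regions)) / 1.0  # 1 FPS for easy arithmetic
    df = hourly_region_seconds(regions, t, fps=1.0)
    assert df.loc[df.hour_index == 0, "wheel_s"].item() == 3600
    assert df.loc[df.hour_index == 1, "wheel_s"].item() == 3600
    assert df.loc[df.hour_index == 2, "house_s"].item() == 3600


def test_read_revolutions_validates(tmp_path):
    good = tmp_path / "revs.csv"
    good.write_text("hour_start_clock,revolutions\n09:00,120\n10:00,80\n")
    df = read_revolutions(good)
    assert df["revolutions"].tolist() == [120, 80]
    bad = tmp_path / "bad.csv"
    bad.write_text("hour_start_clock,revolutions\n09:00,-5\n")
    from cagetrack.errors import SchemaError

    with pytest.raises(SchemaError):
        read_revolutions(bad)
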