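"""Detection-stream I/O, best-box selection, frame pairing, gap filling."""

import numpy as np
import pandas as pd
import pytest

from cagetrack.errors import ConfigError, InputError, SchemaError
from cagetrack.geometry import BoundingBox, View, ViewPoint2D
from cagetrack.streams import (
    DetectionRecord,
    fill_gaps,
    frame_to_records,
    pair_frames,
    read_stream,
    records_to_frame,
    select_best,
    select_best_stream,
    write_stream,
)


def _record(frame=0, conf=0.9, x=10.0, w=4.0, h=4.0, label="mouse", view="front", ts=0.0):
    return DetectionRecord(
        frame_index=frame,
        timestamp=ts,
        label=label,
        box=BoundingBox(x, 20.0, w, h),
        confidence=conf,
        view=View(view),
    )


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path):
        records = [
            _record(frame=0, ts=0.0, label="mouse"),
            _record(frame=0, ts=0.0, label="house", x=50.0, w=30.0, h=20.0),
            _record(frame=1, ts=1 / 15, label="mouse", x=11.5),
        ]
        df = records_to_frame(records)
        path = tmp_path / "stream.csv"
        write_stream(df, path)
        back = read_stream(path)
        assert frame_to_records(back) == records

    def test_malformed_row_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "frame_index,timestamp_s,view,label,x,y,w,h,confidence\n"
            "0,0.0,front,mouse,10,20,4,4,0.9\n"
            "1,0.07,front,mouse,10,20,-4,4,0.9\n"  # negative width: line 3
            "2,0.13,front,mouse,10,20,4,4,0.9\n"
        )
        with pytest.warns(UserWarning, match=r"line\(s\) \[3\]"):
            df = read_stream(path)
        assert df["frame_index"].tolist() == [0, 2]

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "noconf.csv"
        path.write_text("frame_index,timestamp_s,view,label,x,y,w,h\n0,0.0,front,mouse,1,2,3,4\n")
        with pytest.raises(SchemaError, match="confidence"):
            read_stream(path)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("frame_index,timestamp_s,view,label,x,y,w,h,confidence\n")
        with pytest.warns(UserWarning, match="empty"):
            df = read_stream(path)
        assert len(df) == 0

    def test_json_lines_dialect(self, tmp_path):
        path = tmp_path / "stream.jsonl"
        rows = [
            '{"frame_index": 0, "timestamp_s": 0.0, "view": "side", "label": "mouse", "x": 5, "y": 6, "w": 2, "h": 2, "confidence": 0.8}',
            '{"frame_index": 1, "timestamp_s": 0.066, "view": "side", "label": "mouse", "x": 6, "y": 6, "w": 2, "h": 2, "confidence": 0.85}',
        ]
        path.write_text("\n".join(rows) + "\n")
        df = read_stream(path, view="side")
        assert len(df) == 2 and df["x"].tolist() == [5.0, 6.0]

    def test_nonmonotone_timestamps_warn_and_sort_by_frame(self, tmp_path):
        path = tmp_path / "shuffled.csv"
        path.write_text(
            "frame_index,timestamp_s,view,label,x,y,w,h,confidence\n"
            "1,0.07,front,mouse,10,20,4,4,0.9\n"
            "0,0.0,front,mouse,9,20,4,4,0.9\n"
        )
        with pytest.warns(UserWarning, match="non-monotone"):
            df = read_stream(path)
        assert df["frame_index"].tolist() == [0, 1]


class TestSelectBest:
    def test_highest_confidence_wins(self):
        best = select_best([_record(conf=0.9), _record(conf=0.5, x=99.0)])
        assert best.confidence == 0.9

    def test_tie_broken_by_area_then_x(self):
        best = select_best([_record(conf=0.8, w=10.0, h=10.0, x=50.0), _record(conf=0.8, w=20.0, h=10.0, x=60.0)])
        assert best.box.area == 200.0
        best = select_best([_record(conf=0.8, x=30.0), _record(conf=0.8, x=10.0)])
        assert best.box.x == 10.0

    def test_empty_input_absent(self):
        assert select_best([]) is None

    def test_mixed_groups_rejected(self):
        with pytest.raises(InputError):
            select_best([_record(frame=0), _record(frame=1)])

    def test_stream_reduction_matches_record_level_oracle(self, rng):
        rows = []
        for frame in range(30):
            for _ in range(rng.integers(1, 4)):
                rows.append(
                    _record(
                        frame=frame,
                        ts=frame / 15,
                        conf=float(rng.choice([0.5, 0.8, 0.8, 0.9])),
                        x=float(rng.uniform(0, 100)),
                        w=float(rng.uniform(1, 20)),
                        h=float(rng.uniform(1, 20)),
                    )
                )
        df = records_to_frame(rows)
        reduced = select_best_stream(df)
        by_frame = {}
        for r in rows:
            by_frame.setdefault(r.frame_index, []).append(r)
        expected = [select_best(group) for _, group in sorted(by_frame.items())]
        assert frame_to_records(reduced) == expected


class TestPairFrames:
    def test_identical_grids_pair_one_to_one(self):
        t = np.arange(100) / 15.0
        fi, si, uf, us = pair_frames(t, t, 0.3)
        assert len(fi) == 100 and uf == 0 and us == 0
        assert (fi == si).all()

    def test_latency_within_tolerance_fully_paired(self):
        t = np.arange(100) / 15.0
        fi, si, uf, us = pair_frames(t, t + 0.2, 0.3)
        # 0.2 s at 15 FPS is three frames of offset: the greedy nearest
        # match pairs across the shift, dropping only edge frames
        assert len(fi) >= 97
        assert np.all(np.abs(t[fi] - (t + 0.2)[si]) <= 0.3)

    def test_offset_beyond_tolerance_pairs_nothing(self):
        t = np.arange(50) / 15.0
        fi, si, uf, us = pair_frames(t, t + 1000.0, 0.3)
        assert len(fi) == 0 and uf == 50 and us == 50

    def test_each_frame_used_at_most_once(self, rng):
        tf = np.sort(rng.uniform(0, 10, 80))
        ts = np.sort(rng.uniform(0, 10, 60))
        fi, si, uf, us = pair_frames(tf, ts, 0.15)
        assert len(set(fi.tolist())) == len(fi)
        assert len(set(si.tolist())) == len(si)
        assert len(fi) <= min(len(tf), len(ts))
        assert np.all(np.abs(tf[fi] - ts[si]) <= 0.15)
        assert uf == len(tf) - len(fi) and us == len(ts) - len(si)

    def test_nonpositive_tolerance_is_config_error(self):
        with pytest.raises(ConfigError):
            pair_frames(np.arange(3.0), np.arange(3.0), 0.0)

    def test_unsorted_input_rejected(self):
        with pytest.raises(InputError):
            pair_frames(np.array([1.0, 0.5]), np.array([0.0, 1.0]), 0.3)


def _track(*entries):
    out = []
    for frame, xy in entries:
        out.append((frame, None if xy is None else ViewPoint2D(xy[0], xy[1], View.FRONT)))
    return out


class TestFillGaps:
    def test_hold_last_fills_with_last_known(self):
        xy, known, report = fill_gaps(
            _track((0, (1.0, 2.0)), (1, None), (2, (5.0, 6.0))), "hold_last", 30
        )
        assert xy[1].tolist() == [1.0, 2.0]
        assert known.all()
        assert report.n_interpolated == 1 and report.n_unknown == 0

    def test_linear_fills_midpoint(self):
        xy, known, _ = fill_gaps(_track((0, (0.0, 0.0)), (1, None), (2, (2.0, 2.0))), "linear", 30)
        assert xy[1].tolist() == [1.0, 1.0]

    def test_long_gap_booked_unknown_in_full(self):
        entries = [(0, (1.0, 1.0))] + [(i, None) for i in range(1, 41)] + [(41, (2.0, 2.0))]
        xy, known, report = fill_gaps(_track(*entries), "hold_last", 30)
        assert report.n_unknown == 40 and report.n_interpolated == 0
        assert np.isnan(xy[1:41]).all()
        assert not known[1:41].any()

    def test_observed_frames_never_altered(self, rng):
        frames = np.arange(200)
        xy = rng.uniform(0, 50, size=(200, 2))
        missing = rng.random(200) < 0.3
        missing[0] = False
        obs = xy.copy()
        obs[missing] = np.nan
        filled, known, _ = fill_gaps((frames, obs), "hold_last", 10)
        assert np.array_equal(filled[~missing], xy[~missing])

    def test_hold_last_outputs_subset_of_observed(self, rng):
        frames = np.arange(100)
        xy = rng.uniform(0, 50, size=(100, 2))
        missing = rng.random(100) < 0.4
        obs = xy.copy()
        obs[missing] = np.nan
        if np.isnan(obs).all():
            obs[0] = xy[0]
        filled, known, _ = fill_gaps((frames, obs), "hold_last", 100)
        observed = {tuple(r) for r in xy[~np.isnan(obs).any(axis=1)]}
        for row in filled[known]:
            assert tuple(row) in observed

    def test_leading_gap_backfilled(self):
        xy, known, report = fill_gaps(_track((0, None), (1, None), (2, (7.0, 8.0))), "hold_last", 30)
        assert xy[0].tolist() == [7.0, 8.0] and xy[1].tolist() == [7.0, 8.0]
        assert report.n_interpolated == 2

    def test_all_absent_is_error(self):
        with pytest.raises(InputError):
            fill_gaps(_track((0, None), (1, None)), "hold_last", 30)

    def test_unknown_policy_is_config_error(self):
        with pytest.raises(ConfigError):
            fill_gaps(_track((0, (0.0, 0.0))), "cubic", 30)

    def test_gap_accounting_totals(self, rng):
        n = 500
        frames = np.arange(n)
        xy = rng.uniform(0, 50, size=(n, 2))
        obs = xy.copy()
        missing = rng.random(n) < 0.2
        missing[0] = missing[-1] = False
        obs[missing] = np.nan
        _, known, report = fill_gaps((frames, obs), "hold_last", 5)
        assert report.n_frames == n
        assert report.n_missing_mouse == int(missing.sum())
        assert report.n_interpolated + report.n_unknown == report.n_missing_mouse
        assert report.n_unknown == int((~known).sum())
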