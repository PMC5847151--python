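"""Trajectory table validation and the speed-series preprocessing chain."""

import numpy as np
import pandas as pd
import pytest

from shoalhmm import (
    MalformedInputError,
    ParameterError,
    UndefinedResultError,
    attach_nearest_neighbour,
    coarse_grain,
    compute_speeds,
    filter_full_frames,
    lag_autocorrelation,
    load_trajectories,
    smooth_positions,
    subset_series,
    write_trajectories,
)

from conftest import make_dataset, make_series


def grid_rows(n_frames, ids, pos=None, untracked=()):
    rows = []
    for f in range(n_frames):
        for k, ind in enumerate(ids):
            x, y = pos(f, k) if pos else (float(f + k), float(k))
            rows.append((f, ind, x, y, (f, ind) not in untracked))
    return rows


class TestLoadAndValidate:
    def test_round_trip(self, tmp_path):
        ds = make_dataset(grid_rows(3, ["a", "b"]))
        assert len(ds.records) == 6
        p = tmp_path / "t0.csv"
        write_trajectories(ds, p)
        back = load_trajectories(p, frame_rate=10.0, group_size=2)
        pd.testing.assert_frame_equal(back.records, ds.records)

    def test_duplicate_record_rejected(self):
        rows = grid_rows(3, ["a", "b"]) + [(0, "a", 9.0, 9.0, True)]
        with pytest.raises(MalformedInputError):
            make_dataset(rows)

    def test_non_numeric_tracked_coordinate_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("frame,id,x,y,tracked\n0,a,1.0,2.0,1\n0,b,oops,2.0,1\n")
        with pytest.raises(MalformedInputError):
            load_trajectories(p, frame_rate=10.0, group_size=2)

    def test_untracked_records_retained(self):
        ds = make_dataset(grid_rows(2, ["a", "b"], untracked={(1, "b")}))
        assert len(ds.records) == 4
        assert ds.records["tracked"].sum() == 3


class TestFilterFullFrames:
    def test_partial_frame_dropped(self):
        ds = make_dataset(grid_rows(3, ["a", "b"], untracked={(1, "b")}))
        out = filter_full_frames(ds)
        assert sorted(out.frames().tolist()) == [0, 2]

    def test_complete_dataset_unchanged(self):
        ds = make_dataset(grid_rows(3, ["a", "b"]))
        out = filter_full_frames(ds)
        assert len(out.records) == 6

    def test_no_complete_frame_yields_empty(self):
        ds = make_dataset(grid_rows(2, ["a", "b"],
                                    untracked={(0, "a"), (1, "b")}))
        out = filter_full_frames(ds)
        assert len(out.records) == 0

    def test_commutes_with_speed_computation(self):
        ds = make_dataset(grid_rows(6, ["a", "b"], untracked={(3, "b")}))
        direct = compute_speeds(filter_full_frames(ds))
        pre = filter_full_frames(ds)
        again = compute_speeds(filter_full_frames(pre))
        for ind in direct:
            for (t1, v1), (t2, v2) in zip(direct[ind], again[ind]):
                np.testing.assert_allclose(t1, t2)
                np.testing.assert_allclose(v1, v2)


class TestSmoothing:
    def test_constant_positions_preserved(self):
        rows = [(f, i, 5.0, 5.0, True) for f in range(5) for i in "ab"]
        out = smooth_positions(make_dataset(rows), window=3)
        sub = out.records[out.records["id"] == "a"]
        assert len(sub) == 3
        np.testing.assert_allclose(sub["x"], 5.0)

    @pytest.mark.parametrize("xs,expected", [([0, 3, 6], 3.0), ([0, 0, 3], 1.0)])
    def test_centre_window_mean(self, xs, expected):
        rows = [(f, "a", float(x), 0.0, True) for f, x in enumerate(xs)]
        rows += [(f, "b", 0.0, 1.0, True) for f in range(3)]
        out = smooth_positions(make_dataset(rows), window=3)
        sub = out.records[out.records["id"] == "a"]
        assert len(sub) == 1
        assert sub["x"].iloc[0] == pytest.approx(expected)

    def test_even_window_rejected(self):
        ds = make_dataset(grid_rows(4, ["a", "b"]))
        with pytest.raises(ParameterError):
            smooth_positions(ds, window=4)

    def test_short_runs_discarded(self):
        rows = grid_rows(2, ["a", "b"])  # runs of 2 < window 3
        out = smooth_positions(make_dataset(rows), window=3)
        assert len(out.records) == 0


class TestSpeeds:
    def test_stationary_fish_zero_speed(self):
        rows = [(f, i, 1.0, 2.0, True) for f in range(4) for i in "ab"]
        raw = compute_speeds(make_dataset(rows))
        np.testing.assert_allclose(raw["a"][0][1], 0.0)

    def test_unit_displacement_at_10fps(self):
        # 1 cm between consecutive 0.1 s frames -> 10 cm/s
        rows = [(f, "a", float(f), 0.0, True) for f in range(3)]
        rows += [(f, "b", 0.0, 5.0, True) for f in range(3)]
        raw = compute_speeds(make_dataset(rows, frame_rate=10.0))
        np.testing.assert_allclose(raw["a"][0][1], [10.0, 10.0])

    def test_pythagorean_displacement(self):
        rows = [(0, "a", 0.0, 0.0, True), (1, "a", 3.0, 4.0, True),
                (0, "b", 9.0, 9.0, True), (1, "b", 9.0, 9.0, True)]
        raw = compute_speeds(make_dataset(rows, frame_rate=10.0))
        np.testing.assert_allclose(raw["a"][0][1], [50.0])

    def test_single_frame_run_yields_empty(self):
        rows = [(0, "a", 1.0, 1.0, True), (0, "b", 2.0, 2.0, True)]
        raw = compute_speeds(make_dataset(rows))
        assert raw["a"] == []


class TestCoarseGrain:
    def test_sample_count_at_1s(self):
        # 25 frames at 10 fps -> 24 speeds; kept at frames 0, 10, 20
        rows = [(f, "a", 0.1 * f, 0.0, True) for f in range(25)]
        rows += [(f, "b", 0.0, 5.0, True) for f in range(25)]
        raw = compute_speeds(make_dataset(rows, frame_rate=10.0))
        series = coarse_grain(raw, step=1.0, frame_rate=10.0)
        s = next(x for x in series if x.individual_id == "a")
        assert len(s) == 3
        np.testing.assert_allclose(s.times, [0.0, 1.0, 2.0])
        assert s.segments == [(0, 3)]

    def test_gap_restarts_phase(self):
        frames = list(range(12)) + list(range(15, 27))
        rows = [(f, i, 0.1 * f, 0.0, True) for f in frames for i in "ab"]
        raw = compute_speeds(make_dataset(rows, frame_rate=10.0))
        series = coarse_grain(raw, step=1.0, frame_rate=10.0)
        s = series[0]
        assert len(s.segments) == 2
        np.testing.assert_allclose(s.times[s.segments[1][0]], 1.5)

    def test_half_second_step_keeps_every_5th_frame(self):
        rows = [(f, i, 0.1 * f, 0.0, True) for f in range(21) for i in "ab"]
        raw = compute_speeds(make_dataset(rows, frame_rate=10.0))
        series = coarse_grain(raw, step=0.5, frame_rate=10.0)
        np.testing.assert_allclose(series[0].times, [0.0, 0.5, 1.0, 1.5])

    def test_non_multiple_step_rejected(self):
        with pytest.raises(ParameterError):
            coarse_grain({}, step=0.15, frame_rate=10.0)

    def test_frame_interval_step_is_identity(self):
        rows = [(f, i, 0.1 * f, 0.0, True) for f in range(9) for i in "ab"]
        raw = compute_speeds(make_dataset(rows, frame_rate=10.0))
        series = coarse_grain(raw, step=0.1, frame_rate=10.0)
        s = series[0]
        assert s.segments == [(0, 8)]
        np.testing.assert_allclose(s.speeds, raw["a"][0][1])


class TestNearestNeighbour:
    def _series_for(self, ds):
        raw = compute_speeds(ds)
        return coarse_grain(raw, step=ds.frame_interval,
                            frame_rate=ds.frame_rate, trial_id=ds.trial_id)

    def test_two_individuals_mutual(self):
        rows = [(f, "a", float(f), 0.0, True) for f in range(4)]
        rows += [(f, "b", float(2 * f), 5.0, True) for f in range(4)]
        ds = make_dataset(rows, frame_rate=1.0)
        out = attach_nearest_neighbour(ds, self._series_for(ds))
        a = next(s for s in out if s.individual_id == "a")
        b = next(s for s in out if s.individual_id == "b")
        assert set(a.nn_ids) == {"b"} and set(b.nn_ids) == {"a"}
        np.testing.assert_allclose(a.nn_speeds, b.speeds)
        np.testing.assert_allclose(b.nn_speeds, a.speeds)

    def test_collinear_distance_comparison(self):
        xs = {"a": 0.0, "b": 1.0, "c": 5.0}
        rows = [(f, i, x + 0.1 * f, 0.0, True) for f in range(3)
                for i, x in xs.items()]
        ds = make_dataset(rows, frame_rate=1.0, group_size=3)
        out = attach_nearest_neighbour(ds, self._series_for(ds))
        nn = {s.individual_id: s.nn_ids[0] for s in out}
        assert nn == {"a": "b", "b": "a", "c": "b"}

    def test_equidistant_tie_lexicographic(self):
        xs = {"a": 0.0, "b": 1.0, "c": 2.0}
        rows = [(f, i, x + 0.1 * f, 0.0, True) for f in range(3)
                for i, x in xs.items()]
        ds = make_dataset(rows, frame_rate=1.0, group_size=3)
        out = attach_nearest_neighbour(ds, self._series_for(ds))
        b = next(s for s in out if s.individual_id == "b")
        assert b.nn_ids[0] == "a"


class TestLagAutocorrelation:
    def test_periodic_ramp_perfect_at_period(self):
        speeds = np.tile([1.0, 2.0, 3.0, 4.0], 6)
        s = make_series(speeds)
        assert lag_autocorrelation(s, 4.0) == pytest.approx(1.0)

    def test_white_noise_near_zero_and_matches_brute_force(self, rng):
        speeds = rng.gamma(2.0, 1.0, size=10_000)
        s = make_series(speeds, segments=[(0, 4000), (4000, 10_000)])
        r = lag_autocorrelation(s, 1.0)
        assert abs(r) < 0.05
        # brute force over all within-segment pairs
        xs, ys = [], []
        for a, b in s.segments:
            for i in range(a, b - 1):
                xs.append(speeds[i])
                ys.append(speeds[i + 1])
        expect = np.corrcoef(xs, ys)[0, 1]
        assert r == pytest.approx(expect, abs=1e-12)

    def test_constant_series_undefined(self):
        s = make_series(np.full(10, 2.0))
        with pytest.raises(UndefinedResultError):
            lag_autocorrelation(s, 1.0)

    def test_pairs_do_not_cross_segments(self):
        # lag spans a whole segment -> no valid within-segment pairs
        s = make_series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                        segments=[(0, 3), (3, 6)])
        with pytest.raises(UndefinedResultError):
            lag_autocorrelation(s, 3.0)


class TestSubsetSeries:
    def test_deletion_splits_segments(self):
        s = make_series(np.arange(6, dtype=float))
        keep = np.array([True, True, False, True, True, True])
        out = subset_series(s, keep)
        assert out.segments == [(0, 2), (2, 5)]
        np.testing.assert_allclose(out.speeds, [0, 1, 3, 4, 5])

    def test_single_point_fragments_retained(self):
        s = make_series(np.arange(5, dtype=float))
        out = subset_series(s, np.array([True, False, True, False, True]))
        assert out.segments == [(0, 1), (1, 2), (2, 3)]

    def test_empty_keep_returns_none(self):
        s = make_series(np.arange(3, dtype=float))
        assert subset_series(s, np.zeros(3, dtype=bool)) is None
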