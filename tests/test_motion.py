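"""Landmark step sizes, trajectory components and edge-distance classes."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from biofilm_kinetics import synthetic as syn
from biofilm_kinetics.edge import EdgeTrace
from biofilm_kinetics.io import PointTrack
from biofilm_kinetics.motion import (
    CLASS_CATCHING_UP,
    CLASS_FALLING_BEHIND,
    CLASS_KEEPING_PACE,
    distance_to_edge,
    normalise_trajectories,
    step_histogram,
    step_sizes,
    track_metrics,
    truncate_tracks,
    x_step_sizes,
    xy_components,
)


def linear_track(track_id, n, vx_px=1.0, vy_px=0.0, x0=0.0, y0=0.0):
    f = np.arange(n)
    return PointTrack(track_id, f, x0 + vx_px * f, y0 + vy_px * f)


def edge_trace(n, rate_um_min, dt_min=10.0, x0_um=100.0):
    t = np.arange(n) * dt_min
    return EdgeTrace(t, x0_um + rate_um_min * t, np.ones(n, bool))


class TestTruncateTracks:
    def test_all_cut_to_shortest(self):
        tracks = [linear_track("a", 11), linear_track("b", 9), linear_track("c", 15)]
        out = truncate_tracks(tracks)
        assert [len(t) for t in out] == [9, 9, 9]
        np.testing.assert_array_equal(out[2].frames, np.arange(9))

    def test_equal_lengths_unchanged(self):
        tracks = [linear_track("a", 6), linear_track("b", 6)]
        out = truncate_tracks(tracks)
        for a, b in zip(tracks, out):
            np.testing.assert_array_equal(a.x_px, b.x_px)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            truncate_tracks([])


class TestStepSizes:
    def test_3_4_5_triangle(self):
        track = PointTrack("a", [0, 1], [0.0, 3.0], [0.0, 4.0])
        assert step_sizes(track, 1.0) == pytest.approx([5.0])
        assert x_step_sizes(track, 1.0) == pytest.approx([3.0])

    def test_stationary_track_all_zero(self):
        track = PointTrack("a", np.arange(5), np.ones(5), np.ones(5))
        np.testing.assert_allclose(step_sizes(track, 2.0), 0.0)

    def test_drift_track_steps_match_truth(self):
        tracks, truth = syn.make_tracks(
            3, syn.StepModel.drift(0.87), 18.0, 12, seed=3, pixel_size_um=1.0
        )
        for t in tracks:
            np.testing.assert_allclose(
                step_sizes(t, 1.0), truth["mean_speed_um_min"] * 18.0, rtol=1e-12
            )

    @given(
        xs=st.lists(st.floats(-100, 100), min_size=3, max_size=12),
        ys=st.lists(st.floats(-100, 100), min_size=3, max_size=12),
    )
    def test_triangle_inequality(self, xs, ys):
        n = min(len(xs), len(ys))
        track = PointTrack("h", np.arange(n), xs[:n], ys[:n])
        steps = step_sizes(track, 1.0)
        net = np.hypot(xs[n - 1] - xs[0], ys[n - 1] - ys[0])
        assert steps.sum() >= net - 1e-9


class TestNormaliseTrajectories:
    def test_starts_at_origin(self):
        out = normalise_trajectories([linear_track("a", 5, x0=40, y0=7)], 0.869)
        _, x, y = out[0]
        assert x[0] == 0.0 and y[0] == 0.0

    def test_pure_x_drift_keeps_y_zero(self):
        _, x, y = normalise_trajectories([linear_track("a", 5, vx_px=2.0)], 1.0)[0]
        np.testing.assert_allclose(y, 0.0)
        np.testing.assert_allclose(x, 2.0 * np.arange(5))

    def test_idempotent(self):
        track = linear_track("a", 5, x0=10, y0=20)
        once = normalise_trajectories([track], 1.0)[0]
        again = normalise_trajectories(
            [PointTrack("a", track.frames, once[1], once[2])], 1.0
        )[0]
        np.testing.assert_allclose(once[1], again[1])
        np.testing.assert_allclose(once[2], again[2])


class TestXYComponents:
    def test_straight_x_drift(self):
        df = xy_components([linear_track("a", 5, vx_px=10.0)], 1.0)
        assert df.loc[0, "x_range_um"] == pytest.approx(40.0)
        assert df.loc[0, "y_range_um"] == pytest.approx(0.0)

    def test_circle_spans_diameter_in_both_axes(self):
        theta = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        r = 10.0
        track = PointTrack("c", np.arange(200), r * np.cos(theta), r * np.sin(theta))
        df = xy_components([track], 1.0)
        assert df.loc[0, "x_range_um"] == pytest.approx(2 * r, rel=1e-3)
        assert df.loc[0, "y_range_um"] == pytest.approx(2 * r, rel=1e-3)

    def test_range_bounded_by_step_sum(self):
        rng = np.random.default_rng(1)
        track = PointTrack(
            "r", np.arange(20), rng.normal(0, 5, 20), rng.normal(0, 5, 20)
        )
        df = xy_components([track], 1.0)
        assert df.loc[0, "x_range_um"] <= np.abs(np.diff(track.x_px)).sum() + 1e-9
        assert df.loc[0, "y_range_um"] <= np.abs(np.diff(track.y_px)).sum() + 1e-9


class TestDistanceToEdge:
    def test_landmark_at_edge_rate_keeps_pace(self):
        trace = edge_trace(10, rate_um_min=4.25)
        track = linear_track("a", 10, vx_px=42.5)  # pixel size 1 → 4.25 μm/min
        res = distance_to_edge(track, trace, 1.0)
        np.testing.assert_allclose(res.dist_change_um, 0.0, atol=1e-9)
        assert res.classification == CLASS_KEEPING_PACE

    def test_stationary_landmark_falls_behind(self):
        trace = edge_trace(10, rate_um_min=4.25)
        track = linear_track("a", 10, vx_px=0.0)
        res = distance_to_edge(track, trace, 1.0)
        assert res.slope_um_min == pytest.approx(4.25)
        assert res.classification == CLASS_FALLING_BEHIND
        assert res.dist_change_um[0] == 0.0

    def test_fast_landmark_catches_up(self):
        trace = edge_trace(10, rate_um_min=1.0)
        track = linear_track("a", 10, vx_px=30.0)  # 3 μm/min
        res = distance_to_edge(track, trace, 1.0)
        assert res.slope_um_min == pytest.approx(-2.0)
        assert res.classification == CLASS_CATCHING_UP

    def test_classification_antisymmetric(self):
        a, b = 1.0, 3.0
        trace_ab = edge_trace(10, rate_um_min=b)
        res_ab = distance_to_edge(linear_track("x", 10, vx_px=10 * a), trace_ab, 1.0)
        trace_ba = edge_trace(10, rate_um_min=a)
        res_ba = distance_to_edge(linear_track("x", 10, vx_px=10 * b), trace_ba, 1.0)
        assert res_ab.slope_um_min == pytest.approx(-res_ba.slope_um_min)
        assert {res_ab.classification, res_ba.classification} == {
            CLASS_FALLING_BEHIND,
            CLASS_CATCHING_UP,
        }

    def test_track_outside_valid_frames_rejected(self):
        trace = edge_trace(5, 1.0)
        trace.valid[3:] = False
        with pytest.raises(ValueError, match="valid edge frames"):
            distance_to_edge(linear_track("a", 5), trace, 1.0)


class TestStepHistogram:
    def test_equal_steps_single_bin(self):
        df = step_histogram(np.full(30, 5.3), bin_width_um=2.0)
        assert (df["count"] > 0).sum() == 1
        row = df[df["count"] > 0].iloc[0]
        assert row["bin_lo_um"] <= 5.3 < row["bin_hi_um"]
        assert row["count"] == 30

    def test_mixture_gives_three_occupied_regions(self):
        model = syn.StepModel.mixture(
            [syn.StepModel.gaussian(6.0, 0.2),
             syn.StepModel.gaussian(24.0, 0.2),
             syn.StepModel.gaussian(50.0, 0.2)],
            [1, 1, 1],
        )
        tracks, _ = syn.make_tracks(45, model, 10.0, 20, seed=8, pixel_size_um=1.0)
        steps = np.concatenate([step_sizes(t, 1.0) for t in tracks])
        df = step_histogram(steps, 2.0)
        occupied = df.loc[df["count"] > 0, "bin_lo_um"].to_numpy()
        for mode in (6.0, 24.0, 50.0):
            assert np.min(np.abs(occupied - mode)) <= 2.0
        assert not df[(df.bin_lo_um > 10) & (df.bin_hi_um < 20)]["count"].any()

    def test_broad_distribution_reaches_its_maximum(self):
        rng = np.random.default_rng(2)
        steps = rng.uniform(0, 60.0, 500)
        df = step_histogram(steps, 2.0)
        assert df["bin_hi_um"].iloc[-1] >= steps.max()
        assert df["count"].sum() == 500


class TestTrackMetrics:
    def test_tidy_table_with_edge_classes(self):
        trace = edge_trace(8, rate_um_min=2.0)
        tracks = [linear_track("fast", 8, vx_px=30.0), linear_track("slow", 8, vx_px=1.0)]
        df = track_metrics(tracks, 1.0, 10.0, trace)
        assert set(df["edge_class"]) == {CLASS_CATCHING_UP, CLASS_FALLING_BEHIND}
        assert df.loc[df.track_id == "fast", "mean_speed_um_min"].iloc[0] == pytest.approx(3.0)
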