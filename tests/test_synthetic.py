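"""Generator determinism, geometry oracles and ground-truth contracts."""

import numpy as np
import pytest

from biofilm_kinetics import synthetic as syn
from biofilm_kinetics.io import ROOT_ID


class TestFrontStack:
    def test_zero_rate_zero_noise_frames_identical(self):
        stack, _ = syn.make_front_stack(
            syn.FrontSpec(rate_um_min=0.0, n_frames=5, width_px=50, height_px=8)
        )
        for t in range(1, 5):
            np.testing.assert_array_equal(stack.data[t], stack.data[0])

    def test_edge_advances_at_default_calibration(self):
        # 4.25 μm/min × 10 min = 42.5 μm ≈ 48.9 px per frame at 890/1024 μm/px
        stack, truth = syn.make_front_stack(
            syn.FrontSpec(rate_um_min=4.25, n_frames=10, width_px=600, height_px=8)
        )
        edge_um = np.array(truth["edge_um"])
        np.testing.assert_allclose(np.diff(edge_um), 42.5)
        steps_px = np.diff(truth["edge_px"])
        assert set(steps_px) <= {48, 49}
        assert np.mean(steps_px) == pytest.approx(42.5 / syn.DEFAULT_PIXEL_SIZE_UM, abs=0.12)

    def test_seed_determinism(self):
        spec = syn.FrontSpec(rate_um_min=2.0, noise_sd=5.0, seed=42,
                             n_frames=4, width_px=64, height_px=16)
        a, _ = syn.make_front_stack(spec)
        b, _ = syn.make_front_stack(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_hard_step_geometry_matches_truth(self):
        spec = syn.FrontSpec(rate_um_min=1.0, x0_um=10.0, n_frames=3,
                             width_px=40, height_px=4, pixel_size_um=1.0)
        stack, truth = syn.make_front_stack(spec)
        for t in range(3):
            fg_cols = np.flatnonzero(stack.data[t, 0] > 50)
            assert fg_cols[-1] == truth["edge_px"][t]

    def test_fg_must_exceed_bg(self):
        with pytest.raises(ValueError, match="fg_level"):
            syn.FrontSpec(rate_um_min=1.0, fg_level=10.0, bg_level=10.0)


class TestGrowthCurve:
    def test_single_frame_gives_i0(self):
        spec = syn.GrowthCurveSpec(doubling_time_min=100.0, i0=2.0, n_frames=1)
        _, curve = syn.logistic_curve(spec)
        assert curve == pytest.approx([2.0])

    def test_early_time_limit_is_exponential(self):
        # for i0 ≪ capacity the logistic reduces to i0·2^(t/T)
        spec = syn.GrowthCurveSpec(doubling_time_min=258.0, carrying_capacity=1000.0,
                                   i0=1.0, n_frames=120)
        t, curve = syn.logistic_curve(spec)
        n_early = 12
        expected = spec.i0 * 2.0 ** (t[:n_early] / 258.0)
        np.testing.assert_allclose(curve[:n_early], expected, rtol=5e-3)
        slope = np.polyfit(t[:n_early], np.log2(curve[:n_early]), 1)[0]
        assert slope == pytest.approx(1 / 258.0, rel=5e-3)

    def test_midpoint_at_closed_form_time(self):
        spec = syn.GrowthCurveSpec(doubling_time_min=258.0, carrying_capacity=1000.0,
                                   i0=1.0, n_frames=400)
        _, _, _, truth = syn.make_growth_curve(spec)
        t_half = truth["t_half_min"]
        t = np.array(truth["t_min"])
        i = np.array(truth["intensity"])
        assert np.interp(t_half, t, i) == pytest.approx(500.0, rel=1e-3)

    def test_rendered_stack_roi_mean_equals_curve(self):
        spec = syn.GrowthCurveSpec(doubling_time_min=100.0, n_frames=20)
        curve, stack, roi, truth = syn.make_growth_curve(spec)
        ys, xs = roi.slices()
        np.testing.assert_allclose(
            stack.data[:, ys, xs].mean(axis=(1, 2)), truth["intensity"], rtol=1e-6
        )


class TestPedigree:
    def test_deterministic_intervals_give_exact_frame_gaps(self):
        table, _ = syn.make_pedigree(
            syn.PedigreeSpec(mean_interval_min=50.0, sd_interval_min=0.0,
                             n_generations=3, n_roots=2)
        )
        rows = table.rows.set_index("roi_id")
        for r in table.rows.itertuples():
            if r.parent_id != ROOT_ID:
                assert r.frame - rows.loc[r.parent_id, "frame"] == 5

    def test_empirical_mean_approaches_truth(self):
        table, truth = syn.make_pedigree(
            syn.PedigreeSpec(mean_interval_min=54.0, sd_interval_min=11.0,
                             n_generations=5, n_roots=10, seed=3)
        )
        iv = np.array(truth["sampled_intervals_min"])
        assert truth["n_edges"] == 10 * (2**5 - 2)
        assert iv.mean() == pytest.approx(54.0, abs=3 * 11.0 / np.sqrt(len(iv)))

    def test_single_generation_has_no_links(self):
        table, truth = syn.make_pedigree(
            syn.PedigreeSpec(mean_interval_min=50.0, n_generations=1, n_roots=4)
        )
        assert truth["n_edges"] == 0
        assert (table.rows["parent_id"] == ROOT_ID).all()
        assert len(table) == 4

    def test_intervals_truncated_at_sampling_interval(self):
        _, truth = syn.make_pedigree(
            syn.PedigreeSpec(mean_interval_min=12.0, sd_interval_min=20.0,
                             n_generations=4, n_roots=4, seed=0)
        )
        assert min(truth["sampled_intervals_min"]) >= 10.0


class TestVolumeStack:
    def test_flat_height_top_index(self):
        # 10 μm at z-step 3.87 μm fills z indices 0..2 (floor(10/3.87) = 2)
        stack, truth = syn.make_volume_stack(
            syn.SurfaceSpec(height_map_um=np.full((6, 6), 10.0), z_step_um=3.87)
        )
        fg = stack.data[0] > 50
        for z in range(stack.data.shape[1]):
            expected = z <= 2
            assert fg[z].all() == expected and fg[z].any() == expected
        assert np.all(np.array(truth["top_index"]) == 2)

    def test_zero_height_leaves_only_base_plane(self):
        stack, _ = syn.make_volume_stack(
            syn.SurfaceSpec(height_map_um=np.zeros((4, 4)), z_step_um=2.0)
        )
        fg = stack.data[0] > 50
        assert fg[0].all()
        assert not fg[1:].any()

    def test_volume_linearity_under_height_scaling(self):
        h = np.linspace(5, 40, 64).reshape(8, 8)
        _, t1 = syn.make_volume_stack(syn.SurfaceSpec(height_map_um=h, z_step_um=1.0))
        _, t2 = syn.make_volume_stack(syn.SurfaceSpec(height_map_um=2 * h, z_step_um=1.0))
        assert t2["true_volume_um3"] / t1["true_volume_um3"] == pytest.approx(2.0, rel=0.05)

    def test_height_exceeding_extent_rejected(self):
        with pytest.raises(ValueError, match="z-extent"):
            syn.SurfaceSpec(height_map_um=np.full((4, 4), 50.0), z_step_um=1.0, n_z=10)


class TestTracks:
    def test_zero_displacement_model_is_stationary(self):
        tracks, truth = syn.make_tracks(3, syn.StepModel.drift(0.0), 10.0, 8, seed=1)
        for t in tracks:
            assert np.ptp(t.x_px) == 0 and np.ptp(t.y_px) == 0
        assert truth["mean_speed_um_min"] == 0.0

    def test_constant_drift_step_is_rate_times_interval(self):
        # 0.87 μm/min over an 18-min interval → 15.66 μm per step
        tracks, truth = syn.make_tracks(
            2, syn.StepModel.drift(0.87), 18.0, 10, seed=2, pixel_size_um=1.0
        )
        for t in tracks:
            np.testing.assert_allclose(np.diff(t.x_px), 15.66, rtol=1e-12)
        assert truth["mean_speed_um_min"] == pytest.approx(0.87)

    def test_mixture_produces_multimodal_steps(self):
        model = syn.StepModel.mixture(
            [syn.StepModel.gaussian(5.0, 0.3),
             syn.StepModel.gaussian(20.0, 0.3),
             syn.StepModel.gaussian(40.0, 0.3)],
            [1 / 3] * 3,
        )
        tracks, truth = syn.make_tracks(60, model, 10.0, 30, seed=4, pixel_size_um=1.0)
        steps = np.concatenate(
            [np.hypot(np.diff(t.x_px), np.diff(t.y_px)) for t in tracks]
        )
        counts, edges = np.histogram(steps, bins=np.arange(0, 46, 2.0))
        centres = (edges[:-1] + edges[1:]) / 2
        occupied = centres[counts > 0]
        for mode in (5.0, 20.0, 40.0):
            assert np.min(np.abs(occupied - mode)) < 2.0
        # the gaps between modes stay empty
        assert counts[np.abs(centres - 12.5) < 2].sum() == 0

    def test_seed_determinism(self):
        model = syn.StepModel.gaussian(3.0, 1.0)
        a, _ = syn.make_tracks(4, model, 10.0, 6, seed=9)
        b, _ = syn.make_tracks(4, model, 10.0, 6, seed=9)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x_px, tb.x_px)
            np.testing.assert_array_equal(ta.y_px, tb.y_px)


class TestColonyImage:
    def test_disk_pixel_count_matches_truth(self):
        image, truth = syn.make_colony_image(radius_px=20, size_px=64)
        assert (image > 50).sum() == truth["n_fg_px"]
        assert truth["n_fg_px"] == pytest.approx(np.pi * 20**2, rel=0.02)
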