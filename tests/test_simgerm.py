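"""Synthetic germination-scene generator: distributions, geometry, rendering."""

import math

import numpy as np
import pytest
from scipy.interpolate import CubicSpline
from scipy.stats import spearmanr

from radiclen import simgerm
from radiclen.simgerm import (Centerline3D, GeneratorConfig, LengthLaw,
                              RadicleSpec, arc_length, build_centerline,
                              count_deviation_points, generate_scene,
                              projected_length, sample_radicle_spec,
                              sample_radicle_specs)


@pytest.fixture(scope="module")
def default_specs():
    cfg = GeneratorConfig()
    rng = np.random.default_rng(42)
    return sample_radicle_specs(cfg, 10_000, rng)


class TestSpecSampling:
    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(category_weights=(0.5, 0.5, 0.2, -0.2))
        with pytest.raises(ValueError):
            GeneratorConfig(category_weights=(0.3, 0.3, 0.3, 0.3))

    def test_degenerate_point_mass_length(self):
        cfg = GeneratorConfig(length_law=LengthLaw(mu=math.log(25.0), sigma=0.0))
        rng = np.random.default_rng(0)
        specs = sample_radicle_specs(cfg, 50, rng)
        assert all(s.length_mm == pytest.approx(25.0) for s in specs)

    def test_category_marginals_match_weights(self, default_specs):
        d = np.array([s.n_dev for s in default_specs])
        # binomial 4-sigma bands at n=10,000
        for frac, p in [((d == 1).mean(), 0.545), ((d == 2).mean(), 0.288),
                        ((d == 0).mean(), 0.089), ((d > 2).mean(), 0.078)]:
            band = 4 * math.sqrt(p * (1 - p) / 10_000)
            assert abs(frac - p) < band

    def test_length_statistics(self, default_specs):
        lengths = np.array([s.length_mm for s in default_specs])
        assert np.median(lengths) == pytest.approx(28.0, abs=0.5)
        assert lengths.mean() == pytest.approx(30.0, abs=0.5)
        assert lengths.min() >= 10.0 and lengths.max() <= 80.0
        # right skew: mean above median
        assert lengths.mean() > np.median(lengths)

    def test_length_curvature_rank_coupling(self):
        cfg = GeneratorConfig()
        specs = sample_radicle_specs(cfg, 1000, np.random.default_rng(7))
        lengths = [s.length_mm for s in specs]
        ndev = [s.n_dev for s in specs]
        assert spearmanr(lengths, ndev).statistic >= 0.7


class TestCenterline:
    def test_planar_when_no_deviation(self):
        spec = RadicleSpec(25.0, 0, (0.0, 0.0), 0.3)
        cl = build_centerline(spec, np.random.default_rng(1))
        assert np.all(cl.points(513)[:, 2] == 0.0)
        assert count_deviation_points(cl) == 0

    @pytest.mark.parametrize("n_dev", [1, 2, 3])
    def test_deviation_count_by_construction(self, n_dev):
        spec = RadicleSpec(40.0, n_dev, (2.0, -3.0), 1.0)
        cl = build_centerline(spec, np.random.default_rng(n_dev))
        assert count_deviation_points(cl) == n_dev

    def test_arc_length_matches_target_within_half_percent(self):
        rng = np.random.default_rng(5)
        cfg = GeneratorConfig()
        for spec in sample_radicle_specs(cfg, 15, rng):
            cl = build_centerline(spec, rng)
            assert arc_length(cl) == pytest.approx(spec.length_mm, rel=5e-3)

    def test_arc_length_straight_segment(self):
        t = np.linspace(0, 1, 9)
        cl = Centerline3D(CubicSpline(t, 30.0 * t), CubicSpline(t, 0 * t),
                          CubicSpline(t, 0 * t), 30.0,
                          np.empty(0), np.empty(0), np.empty(0))
        assert arc_length(cl) == pytest.approx(30.0, rel=1e-6)

    def test_arc_length_semicircle(self):
        t = np.linspace(0, 1, 257)
        cl = Centerline3D(
            CubicSpline(t, 10.0 * np.cos(np.pi * t)),
            CubicSpline(t, 10.0 * np.sin(np.pi * t)),
            CubicSpline(t, 0 * t), 10 * np.pi,
            np.empty(0), np.empty(0), np.empty(0))
        assert arc_length(cl) == pytest.approx(10 * np.pi, rel=1e-4)

    def test_arc_length_agrees_with_dense_polyline_oracle(self):
        rng = np.random.default_rng(11)
        spec = RadicleSpec(45.0, 2, (0.0, 5.0), 2.0)
        cl = build_centerline(spec, rng)
        pts = cl.points(100_001)
        oracle = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        assert arc_length(cl) == pytest.approx(oracle, rel=1e-3)

    def test_nonfinite_centerline_rejected(self):
        t = np.linspace(0, 1, 9)
        cl = Centerline3D(CubicSpline(t, t), CubicSpline(t, t),
                          CubicSpline(t, 0 * t), 1.0,
                          np.empty(0), np.empty(0), np.empty(0))
        cl.spline_x.c[:] = np.nan
        with pytest.raises(ValueError):
            arc_length(cl)

    def test_three_sinusoidal_maxima_counted(self):
        # lift with three above-threshold maxima, enumerated numerically
        t = np.linspace(0, 1, 513)
        z = 2.0 * np.sin(3 * np.pi * t) ** 2
        cl = Centerline3D(CubicSpline(t, 30 * t), CubicSpline(t, 0 * t),
                          CubicSpline(t, z), 30.0,
                          np.empty(0), np.empty(0), np.empty(0))
        assert count_deviation_points(cl) == 3

    def test_projection_shortens_iff_lifted(self):
        rng = np.random.default_rng(9)
        flat = build_centerline(RadicleSpec(30.0, 0, (0, 0), 0.1), rng)
        assert projected_length(flat) == pytest.approx(arc_length(flat), rel=1e-6)
        lifted = build_centerline(RadicleSpec(30.0, 2, (0, 0), 0.1), rng)
        assert projected_length(lifted) < arc_length(lifted) - 0.5


class TestRendering:
    def test_single_instance_mask_and_tight_box(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(2)
        spec = sample_radicle_spec(cfg, rng)
        scene = simgerm.render_scene([spec], cfg, rng)
        assert len(scene.masks) == 1
        mask = scene.masks[0]
        assert mask.any()
        ys, xs = np.nonzero(mask)
        np.testing.assert_array_equal(
            scene.boxes[0],
            [xs.min(), ys.min(), xs.max() + 1, ys.max() + 1])

    def test_grid_pitch_by_construction(self):
        cfg = GeneratorConfig(px_per_mm=8.0, grid_mm=10.0)
        rng = np.random.default_rng(3)
        scene = simgerm.render_scene(
            sample_radicle_specs(cfg, 2, rng), cfg, rng)
        assert scene.grid_pitch_px == pytest.approx(80.0, abs=0.5)
        # drawn grid lines really are 80 px apart
        img = scene.image.astype(float).mean(axis=2)
        col_profile = img[:40].mean(axis=0)  # top strip avoids the dish
        line_cols = np.nonzero(
            col_profile > col_profile.mean() + 2 * col_profile.std()
        )[0]
        gaps = np.diff(line_cols)
        assert np.all(np.isin(gaps[gaps > 1], [80]))

    def test_eq1_consistency_for_every_instance(self):
        cfg = GeneratorConfig()
        scene = generate_scene(cfg, seed=4)
        ratio = scene.lengths_px / scene.lengths_mm
        np.testing.assert_allclose(
            ratio, scene.grid_pitch_px / cfg.grid_mm, rtol=1e-12)

    def test_masks_nonoverlapping_within_tolerance(self):
        scene = generate_scene(GeneratorConfig(), seed=6)
        for i in range(len(scene.masks)):
            for j in range(i + 1, len(scene.masks)):
                inter = np.logical_and(scene.masks[i], scene.masks[j]).sum()
                smaller = min(scene.masks[i].sum(), scene.masks[j].sum())
                assert inter / smaller < 0.25

    @pytest.mark.parametrize("style", ["black", "white", "wood"])
    def test_background_styles_render_valid_scenes(self, style):
        cfg = simgerm.GeneratorConfig.tiny(background_style=style)
        scene = generate_scene(cfg, seed=8, n_instances=2)
        assert scene.image.dtype == np.uint8
        assert len(scene.masks) == 2 and all(m.any() for m in scene.masks)

    def test_unknown_background_rejected(self):
        with pytest.raises(ValueError):
            simgerm.GeneratorConfig(background_style="plaid")

    def test_scene_determinism_bit_identical(self):
        a = generate_scene(GeneratorConfig(), seed=5)
        b = generate_scene(GeneratorConfig(), seed=5)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.boxes, b.boxes)
        assert all(np.array_equal(x, y) for x, y in zip(a.masks, b.masks))
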