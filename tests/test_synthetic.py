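"""Scene generator: determinism, nesting, signal calibration, plot inversion."""

import numpy as np
import pytest

from carbonscape import (SceneConfig, compute_vi, default_registry,
                         generate_plots, generate_scene, plot_carbon_density)
from carbonscape.raster import block_reduce_mean
from carbonscape.synthetic import CLASS_CODES, CLASS_LABELS


def shrub_only_config(**kw):
    fracs = {c: 0.0 for c in CLASS_LABELS}
    fracs["shrub"] = 1.0
    return SceneConfig(extent_pixels_10m=(60, 60), seed=2,
                       species_fractions=fracs, **kw)


class TestConfigValidation:
    def test_extent_must_nest(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            SceneConfig(extent_pixels_10m=(100, 99))

    def test_fractions_must_sum_to_one(self):
        fracs = {c: 0.25 for c in CLASS_LABELS}
        with pytest.raises(ValueError, match="sum to 1"):
            SceneConfig(species_fractions=fracs)

    def test_density_ranges_positive(self):
        params = {c: (10.0, 1.0, 20.0) for c in CLASS_LABELS}
        params["shrub"] = (5.0, -1.0, 10.0)
        with pytest.raises(ValueError):
            SceneConfig(density_params=params)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SceneConfig(extent_pixels_10m=(90, 90), seed=9, vi_signal_r=0.6)
        cfg.to_yaml(tmp_path / "scene.yaml")
        back = SceneConfig.from_yaml(tmp_path / "scene.yaml")
        assert back == cfg


class TestGenerateScene:
    def test_bit_identical_under_fixed_seed(self):
        cfg = SceneConfig(extent_pixels_10m=(60, 60), seed=4)
        s1, s2 = generate_scene(cfg), generate_scene(cfg)
        np.testing.assert_array_equal(s1.true_density_10m.data,
                                      s2.true_density_10m.data)
        for b in s1.stack_10m.bands:
            np.testing.assert_array_equal(s1.stack_10m.bands[b],
                                          s2.stack_10m.bands[b])
        for b in s1.stack_30m.bands:
            np.testing.assert_array_equal(s1.stack_30m.bands[b],
                                          s2.stack_30m.bands[b])
        np.testing.assert_array_equal(s1.landuse_truth_30m.data,
                                      s2.landuse_truth_30m.data)

    def test_different_seeds_differ(self):
        a = generate_scene(SceneConfig(extent_pixels_10m=(60, 60), seed=1))
        b = generate_scene(SceneConfig(extent_pixels_10m=(60, 60), seed=2))
        assert not np.array_equal(a.true_density_10m.data, b.true_density_10m.data)

    def test_reflectance_bounded(self, small_scene):
        for stack in (small_scene.stack_10m, small_scene.stack_30m):
            for arr in stack.bands.values():
                assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_30m_is_block_mean_before_sensor_noise(self, small_scene):
        for l8, s2 in [("b3", "b3"), ("b4", "b4"), ("b5", "b8")]:
            np.testing.assert_allclose(
                small_scene.clean_stack_30m.bands[l8],
                block_reduce_mean(small_scene.clean_stack_10m.bands[s2], 3),
                atol=1e-9)

    def test_species_mask_partitions_forest(self, small_scene):
        mask = small_scene.species_mask_10m.data
        forest = small_scene.forest_mask_10m
        assert set(np.unique(mask[forest])) <= set(CLASS_CODES.values())
        assert np.all(mask[~forest] == 0)
        covered = np.zeros_like(forest)
        for label in CLASS_LABELS:
            cls = small_scene.class_mask(label)
            assert not np.any(covered & cls)  # disjoint
            covered |= cls
        np.testing.assert_array_equal(covered, forest)  # exhaustive

    def test_class_fractions_respected(self, small_scene):
        forest_n = small_scene.forest_mask_10m.sum()
        for label in CLASS_LABELS:
            want = small_scene.config.species_fractions[label]
            got = small_scene.class_mask(label).sum() / forest_n
            assert got == pytest.approx(want, abs=2.0 / forest_n + 1e-9)

    def test_density_within_class_ranges(self, small_scene):
        d = small_scene.true_density_10m.data
        for label in CLASS_LABELS:
            sel = small_scene.class_mask(label)
            mean, lo, hi = small_scene.config.density_params[label]
            assert d[sel].min() >= lo - 1e-9
            assert d[sel].max() <= hi + 1e-9
            assert d[sel].mean() == pytest.approx(mean, rel=0.02)

    def test_noiseless_high_signal_correlation(self):
        cfg = SceneConfig(extent_pixels_10m=(120, 120), seed=3,
                          vi_signal_r=0.99, sensor_noise_sd=0.0)
        scene = generate_scene(cfg)
        ndvi = compute_vi(scene.stack_10m, "NDVI", sensor="s2a")
        f = scene.forest_mask_10m
        r = np.corrcoef(ndvi.data[f], scene.true_density_10m.data[f])[0, 1]
        assert r >= 0.95

    def test_calibration_hits_requested_signal(self, small_scene):
        ndvi = compute_vi(small_scene.stack_10m, "NDVI", sensor="s2a")
        f = small_scene.forest_mask_10m
        r = np.corrcoef(ndvi.data[f], small_scene.true_density_10m.data[f])[0, 1]
        assert r == pytest.approx(small_scene.config.vi_signal_r, abs=0.05)

    def test_degenerate_single_class_mixture(self):
        scene = generate_scene(shrub_only_config())
        forest = scene.forest_mask_10m
        assert set(np.unique(scene.species_mask_10m.data[forest])) \
            == {CLASS_CODES["shrub"]}

    def test_landuse_truth_covers_six_classes(self, small_scene):
        assert set(np.unique(small_scene.landuse_truth_30m.data)) \
            <= set(range(1, 7))
        assert small_scene.landuse_truth_30m.shape \
            == tuple(s // 3 for s in small_scene.stack_10m.shape)


class TestGeneratePlots:
    def test_survey_layout_gives_96_plots(self, small_scene):
        plots = generate_plots(small_scene)
        assert len(plots) == 96
        by_class = {c: sum(p.class_label == c for p in plots)
                    for c in CLASS_LABELS}
        assert by_class == {"Populus": 20, "Salix": 18,
                            "Pinus tabuliformis": 20, "other": 18, "shrub": 20}

    def test_zero_noise_roundtrip_through_allometry(self):
        cfg = SceneConfig(extent_pixels_10m=(90, 90), seed=6, plot_noise_rel=0.0)
        scene = generate_scene(cfg)
        plots = generate_plots(scene)
        registry = default_registry()
        density = scene.true_density_10m
        for plot in plots:
            local = density.data[density.grid.xy_to_rowcol(
                plot.center["x"], plot.center["y"])]
            computed = plot_carbon_density(plot, registry).carbon_density
            assert computed == pytest.approx(float(local), rel=0.01)

    def test_plot_layers_match_class(self, small_scene):
        plots = generate_plots(small_scene)
        for p in plots:
            if p.class_label == "shrub":
                assert p.shrubs and not p.stems
                assert p.plot_area == 0.01
            else:
                assert p.stems and not p.shrubs
                assert p.plot_area == 0.04
            assert len(p.herb_quadrats) == 3

    def test_empty_class_mask_warns_and_skips(self):
        scene = generate_scene(shrub_only_config())
        with pytest.warns(UserWarning, match="empty mask"):
            plots = generate_plots(scene)
        assert all(p.class_label == "shrub" for p in plots)
        assert len(plots) == 20

    def test_deterministic_per_seed(self, small_scene):
        p1 = generate_plots(small_scene)
        p2 = generate_plots(small_scene)
        assert [(p.plot_id, p.center, p.stems, p.shrubs, p.herb_quadrats)
                for p in p1] == \
            [(p.plot_id, p.center, p.stems, p.shrubs, p.herb_quadrats)
             for p in p2]
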