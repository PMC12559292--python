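"""Mosaics, block aggregation, both estimation approaches and storage math."""

import numpy as np
import pandas as pd
import pytest

from carbonscape import (ModelSpec, aggregate_to_30m, apply_model_to_stack,
                         approach1, approach2, composition_and_change,
                         compute_vi, discrepancy_classify, mosaic_species,
                         pixel_area_ha, total_storage)
from carbonscape.raster import GridSpec, Raster, RasterStack

from conftest import make_raster


class TestMosaic:
    def _halves(self, value_left, value_right):
        shape = (6, 6)
        left = np.zeros(shape, bool)
        left[:, :3] = True
        right = ~left
        preds = {"A": make_raster(np.full(shape, value_left)),
                 "B": make_raster(np.full(shape, value_right))}
        return preds, {"A": left, "B": right}

    def test_two_disjoint_halves_merge(self):
        preds, masks = self._halves(10.0, 30.0)
        mosaic = mosaic_species(preds, masks)
        assert mosaic.merged.data[~mosaic.merged.mask].mean() == pytest.approx(20.0)

    def test_single_class_equals_its_prediction(self):
        shape = (4, 4)
        pred = make_raster(np.arange(16.0).reshape(shape))
        mosaic = mosaic_species({"A": pred}, {"A": np.ones(shape, bool)})
        np.testing.assert_array_equal(mosaic.merged.data, pred.data)

    def test_overlap_rejected_with_count(self):
        preds, masks = self._halves(1.0, 2.0)
        masks["B"][0, 0] = True  # overlaps A
        with pytest.raises(ValueError, match="1 pixel"):
            mosaic_species(preds, masks)


class TestAggregate:
    def test_uniform_children(self):
        ref = aggregate_to_30m(make_raster(np.full((3, 3), 7.0)))
        assert ref.density.data[0, 0] == pytest.approx(7.0)
        assert ref.forest_fraction[0, 0] == 1.0

    def test_mean_of_one_to_nine(self):
        ref = aggregate_to_30m(make_raster(np.arange(1.0, 10.0).reshape(3, 3)))
        assert ref.density.data[0, 0] == pytest.approx(5.0)

    def test_partial_forest_cell(self):
        mask = np.ones((3, 3), bool)
        mask[0, 0] = False  # one nodata child
        r = make_raster(np.full((3, 3), 4.0), mask=~mask * True)
        r.mask[0, 0] = True
        ref = aggregate_to_30m(r)
        assert ref.forest_fraction[0, 0] == pytest.approx(8 / 9)
        assert ref.density.data[0, 0] == pytest.approx(4.0)

    def test_cell_without_forest_children_is_nodata(self):
        r = make_raster(np.ones((6, 6)))
        r.mask[:3, :3] = True
        ref = aggregate_to_30m(r)
        assert ref.density.mask[0, 0]
        assert not ref.density.mask[1, 1]

    def test_conservation_of_total_carbon(self, small_scene):
        d = small_scene.true_density_10m
        ref = aggregate_to_30m(d)
        fine = total_storage(d)
        coarse = total_storage(ref.density, area_weights=ref.forest_fraction)
        assert coarse.total_t == pytest.approx(fine.total_t, rel=1e-9)

    def test_non_nesting_shape_rejected(self):
        with pytest.raises(ValueError, match="nest"):
            aggregate_to_30m(make_raster(np.ones((4, 6))))


def _linear_scene(seed=0, shape=(30, 30)):
    """A 30 m Landsat-like stack and a reference that is exactly linear in NDVI."""
    rng = np.random.default_rng(seed)
    grid = GridSpec(0.0, shape[0] * 30.0, 30.0)
    nir = rng.uniform(0.2, 0.6, shape)
    red = rng.uniform(0.05, 0.2, shape)
    green = rng.uniform(0.05, 0.15, shape)
    stack = RasterStack({"b3": green, "b4": red, "b5": nir}, grid)
    ndvi = (nir - red) / (nir + red)
    density = 5.0 + 30.0 * ndvi
    from carbonscape.crossres import ReferenceRaster30m
    ref = ReferenceRaster30m(density=Raster(density, grid),
                             forest_fraction=np.ones(shape))
    return stack, ref, density


class TestApproaches:
    def test_approach2_recovers_exact_linear_reference(self):
        stack, ref, density = _linear_scene()
        res = approach2(ref, stack, candidates=["NDVI"], sample_n=None,
                        threshold=0.3)
        np.testing.assert_allclose(res.density_map.data, density, atol=1e-6)

    def test_approach2_needs_enough_cells(self):
        stack, ref, _ = _linear_scene(shape=(3, 3))
        ref.density.mask[:, :] = True
        ref.density.mask[0, :] = False
        with pytest.raises(ValueError, match="eligible"):
            approach2(ref, stack)

    def test_approach2_model_reusable_on_second_date(self):
        stack, ref, _ = _linear_scene(seed=1)
        res = approach2(ref, stack, candidates=["NDVI"], sample_n=None,
                        threshold=0.3)
        stack2, _, _ = _linear_scene(seed=2)
        out, _ = apply_model_to_stack(res.model, stack2,
                                      np.ones(stack2.shape, bool))
        assert np.isfinite(out.data[~out.mask]).all()
        assert (~out.mask).sum() == out.data.size

    def test_approach1_deterministic_end_to_end(self, small_scene):
        from carbonscape import default_registry, generate_plots, plot_carbon_density
        plots = generate_plots(small_scene)
        reg = default_registry()
        df = pd.DataFrame([
            {"x": p.center["x"], "y": p.center["y"],
             "carbon_density": plot_carbon_density(p, reg).carbon_density}
            for p in plots])
        ref = aggregate_to_30m(small_scene.true_density_10m)
        mask30 = ref.forest_fraction > 0
        r1 = approach1(df, small_scene.stack_30m, mask30, threshold=0.3, top_k=3)
        r2 = approach1(df, small_scene.stack_30m, mask30, threshold=0.3, top_k=3)
        np.testing.assert_array_equal(r1.density_map.data[mask30],
                                      r2.density_map.data[mask30])

    def test_approach1_recovers_strong_signal(self):
        # plots sampled from an exactly NDVI-linear density surface
        stack, ref, density = _linear_scene(seed=3)
        rng = np.random.default_rng(4)
        rows = rng.integers(0, 30, 60)
        cols = rng.integers(0, 30, 60)
        x, y = ref.density.grid.rowcol_to_xy(rows, cols)
        df = pd.DataFrame({"x": x, "y": y,
                           "carbon_density": density[rows, cols]})
        res = approach1(df, stack, np.ones((30, 30), bool),
                        candidates=["NDVI", "gNDVI"], threshold=0.3)
        assert res.model.test_metrics.r2 >= 0.9

    def test_empty_forest_mask_yields_all_nodata(self):
        stack, ref, density = _linear_scene(seed=5)
        rng = np.random.default_rng(6)
        rows, cols = rng.integers(0, 30, 40), rng.integers(0, 30, 40)
        x, y = ref.density.grid.rowcol_to_xy(rows, cols)
        df = pd.DataFrame({"x": x, "y": y, "carbon_density": density[rows, cols]})
        res = approach1(df, stack, np.zeros((30, 30), bool), threshold=0.3)
        assert res.density_map.mask.all()


class TestDiscrepancy:
    def test_identical_maps_are_all_minor(self):
        est = make_raster(np.full((4, 4), 10.0))
        out = discrepancy_classify(est, make_raster(np.full((4, 4), 10.0)))
        assert out.fractions["minor"] == pytest.approx(100.0)

    @pytest.mark.parametrize("est,expected", [
        (11.0, "minor"),        # 10%
        (14.0, "moderate"),     # 40%
        (13.0, "moderate"),     # exactly 30% -> closed interval
        (16.0, "moderate"),     # exactly 60% -> closed interval
        (17.0, "substantial"),  # 70%
    ])
    def test_threshold_classes(self, est, expected):
        out = discrepancy_classify(make_raster(np.full((2, 2), est)),
                                   make_raster(np.full((2, 2), 10.0)))
        assert out.fractions[expected] == pytest.approx(100.0)

    def test_zero_reference_excluded_and_counted(self):
        ref = make_raster(np.array([[10.0, 0.0], [10.0, 10.0]]))
        out = discrepancy_classify(make_raster(np.full((2, 2), 10.0)), ref)
        assert out.n_excluded_zero_reference == 1
        assert out.n_compared == 3

    def test_fractions_sum_to_100(self, small_scene):
        d = small_scene.true_density_10m
        est = Raster(d.data * 1.4, d.grid, mask=d.mask)
        out = discrepancy_classify(est, d)
        assert sum(out.fractions.values()) == pytest.approx(100.0, abs=0.01)


class TestStorage:
    def test_uniform_density_total(self):
        r = make_raster(np.full((100, 100), 20.0), pixel_size=10.0)
        stats = total_storage(r)
        assert stats.total_t == pytest.approx(20.0 * 10_000 * 0.01)

    def test_pixel_areas(self):
        assert pixel_area_ha(10.0) == pytest.approx(0.01)
        assert pixel_area_ha(30.0) == pytest.approx(0.09)

    def test_all_nodata_warns_and_returns_zero(self):
        r = make_raster(np.ones((3, 3)), mask=np.ones((3, 3), bool))
        with pytest.warns(UserWarning):
            stats = total_storage(r)
        assert stats.total_t == 0.0

    def test_reported_class_totals_compose(self):
        # published regional per-class storage totals (t)
        totals = {"Populus": 4_506_024.85, "Salix": 1_197_381.53,
                  "Pinus tabuliformis": 825_591.21, "other": 2_150_570.97,
                  "shrub": 17_245_919.68}
        report = composition_and_change(totals)
        assert report.whole_forest_total == pytest.approx(25_925_488.23, abs=1.0)
        assert report.composition_pct["shrub"] == pytest.approx(66.52, abs=0.01)
        assert sum(report.composition_pct.values()) == pytest.approx(100.0, abs=0.01)

    def test_between_date_change(self):
        report = composition_and_change(
            {"whole": 25_925_488.23},
            date_totals={"2013": 13_715_729.12, "2023": 25_925_488.23})
        assert report.change_pct == pytest.approx(89.02, abs=0.01)
        assert report.change_t == pytest.approx(12_209_759.11, abs=1.0)

    def test_equal_dates_zero_change(self):
        report = composition_and_change({"a": 10.0},
                                        date_totals={"t0": 5.0, "t1": 5.0})
        assert report.change_t == 0.0 and report.change_pct == 0.0

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            composition_and_change({"a": -1.0})
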