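"""Cross-resolution carbon mapping: direct coarse modeling (Approach 1) and
fine-resolution reference transfer (Approach 2), plus discrepancy mapping
and storage accounting.

Approach 1 regresses plot-measured carbon density directly on coarse (30 m)
vegetation indices and maps the fit over the forest extent.

Approach 2 first maps density per dominant class at fine (10 m) resolution,
mosaics the per-class maps, block-aggregates the mosaic to the coarse grid
(each 30 m cell = mean over its 10 m forest children, with the forest
fraction recorded), and then regresses those reference cells on the coarse
vegetation indices.  The fitted coarse model is reusable on another date's
imagery — the mechanism that lets a long Landsat record inherit the quality
of a short high-resolution record.

Storage totals integrate density (t/ha) over pixel area; a 10 m pixel is
0.01 ha and a 30 m pixel 0.09 ha.  On the coarse grid the area of each cell
is weighted by its forest fraction so that block aggregation conserves
total carbon exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import screen_by_correlation, vif_filter
from .indices import compute_vi, extract_at_points
from .models import FittedCarbonModel, ModelSpec, fit, predict_density_map
from .raster import GridSpec, Raster, RasterStack, grids_nested

__all__ = [
    "SpeciesDensityMosaic", "ReferenceRaster30m", "DiscrepancySummary",
    "StorageStats", "StorageReport", "ApproachResult",
    "mosaic_species", "aggregate_to_30m", "approach1", "approach2",
    "discrepancy_classify", "total_storage", "composition_and_change",
    "pixel_area_ha",
]


@dataclass
class SpeciesDensityMosaic:
    """Per-class 10 m density maps merged into one whole-forest raster."""

    per_class: dict[str, Raster]
    masks: dict[str, np.ndarray]
    merged: Raster


@dataclass
class ReferenceRaster30m:
    """Coarse-grid reference density from the fine mosaic.

    ``density`` is the mean density of the 10 m forest children of each
    30 m cell (nodata where a cell has no forest child); ``forest_fraction``
    is the fraction of the cell's 9 children that are forest.
    """

    density: Raster
    forest_fraction: np.ndarray


@dataclass(frozen=True)
class DiscrepancySummary:
    class_map: Raster                 # 1 minor, 2 moderate, 3 substantial; 0 excluded
    fractions: dict[str, float]       # % of compared pixels, sums to 100
    n_compared: int
    n_excluded_zero_reference: int


@dataclass(frozen=True)
class StorageStats:
    total_t: float
    mean_density: float
    min_density: float
    max_density: float
    area_ha: float
    n_pixels: int


@dataclass(frozen=True)
class StorageReport:
    class_totals: dict[str, float]
    whole_forest_total: float
    composition_pct: dict[str, float]
    date_totals: dict = field(default_factory=dict)
    change_t: float | None = None
    change_pct: float | None = None


@dataclass
class ApproachResult:
    model: FittedCarbonModel
    density_map: Raster
    selected_indices: list[str]
    n_floored: int
    screen_report: object = None
    vif_report: object = None


def pixel_area_ha(resolution_m: float) -> float:
    """Pixel area in hectares from the resolution in metres."""
    return (resolution_m / 100.0) ** 2


def mosaic_species(predictions: dict[str, Raster],
                   masks: dict[str, np.ndarray]) -> SpeciesDensityMosaic:
    """Merge per-class density maps; each pixel comes from its class's map.

    Class masks must be pairwise disjoint; overlap is rejected with the
    offending pixel count.
    """
    if set(predictions) != set(masks):
        raise ValueError("predictions and masks must cover the same classes")
    first = next(iter(predictions.values()))
    cover = np.zeros(first.shape, dtype=int)
    for label, m in masks.items():
        m = np.asarray(m, bool)
        if m.shape != first.shape:
            raise ValueError(f"mask for {label!r} is on a different grid")
        cover += m
    n_overlap = int(np.sum(cover > 1))
    if n_overlap:
        raise ValueError(f"class masks overlap on {n_overlap} pixel(s)")
    merged = np.full(first.shape, np.nan)
    for label, m in masks.items():
        r = predictions[label]
        if r.shape != first.shape:
            raise ValueError(f"prediction for {label!r} is on a different grid")
        sel = np.asarray(m, bool) & ~r.mask
        merged[sel] = r.data[sel]
    mask = ~np.isfinite(merged)
    return SpeciesDensityMosaic(
        per_class=predictions,
        masks={k: np.asarray(v, bool) for k, v in masks.items()},
        merged=Raster(merged, first.grid, first.crs, mask))


def aggregate_to_30m(mosaic: Raster, forest_mask: np.ndarray | None = None,
                     factor: int = 3) -> ReferenceRaster30m:
    """Block-aggregate a fine density map to the coarse grid.

    Each coarse cell is the arithmetic mean over its fine *forest* children
    (forest = unmasked pixels of the mosaic intersected with
    ``forest_mask`` when given); cells with no forest child are nodata.
    """
    rows, cols = mosaic.shape
    if rows % factor or cols % factor:
        raise ValueError(
            f"fine grid {mosaic.shape} does not nest a factor-{factor} coarse grid")
    forest = ~mosaic.mask
    if forest_mask is not None:
        forest &= np.asarray(forest_mask, bool)
    d = np.where(forest, mosaic.data, 0.0)
    r2, c2 = rows // factor, cols // factor
    sums = d.reshape(r2, factor, c2, factor).sum(axis=(1, 3))
    counts = forest.reshape(r2, factor, c2, factor).sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    grid30 = mosaic.grid.coarsen(factor)
    return ReferenceRaster30m(
        density=Raster(mean, grid30, mosaic.crs, counts == 0),
        forest_fraction=counts / float(factor * factor))


def _screen_and_fit(samples: pd.DataFrame, response: str,
                    candidates: list[str], spec: ModelSpec,
                    threshold: float, top_k: int | None,
                    vif_limit: float):
    report = screen_by_correlation(
        {c: samples[c].to_numpy() for c in candidates},
        samples[response].to_numpy(), threshold=threshold, top_k=top_k)
    selected = report.selected
    if not selected:
        raise ValueError("no vegetation index was selected for modeling")
    if len(selected) > 1:
        vif_rep, retained = vif_filter(samples[selected], limit=vif_limit)
        selected = list(retained.columns)
    else:
        vif_rep = None
    spec = ModelSpec(kind=spec.kind, predictor_names=tuple(selected),
                     hyperparameters=spec.hyperparameters,
                     split_fraction=spec.split_fraction,
                     split_seed=spec.split_seed)
    model = fit(spec, samples[selected], samples[response].to_numpy())
    return model, selected, report, vif_rep


def _vi_rasters(stack: RasterStack, names: list[str], sensor: str
                ) -> dict[str, Raster]:
    return {n: compute_vi(stack, n, sensor=sensor) for n in names}


def approach1(plot_samples: pd.DataFrame, stack_l8: RasterStack,
              forest_mask_30m: np.ndarray,
              candidates: list[str] | None = None,
              spec: ModelSpec | None = None,
              threshold: float = 0.5, top_k: int | None = 3,
              vif_limit: float = 10.0) -> ApproachResult:
    """Direct coarse-resolution modeling from plot measurements.

    ``plot_samples`` needs columns x, y, carbon_density; coarse vegetation
    indices are extracted at the containing 30 m cell of each plot center.
    """
    spec = spec or ModelSpec(kind="mlr")
    candidates = candidates or ["NDVI", "gNDVI", "SAVI", "DVI", "SR", "RDVI"]
    vis = _vi_rasters(stack_l8, candidates, "l8")
    pts = list(zip(plot_samples["x"], plot_samples["y"]))
    table = pd.DataFrame({n: extract_at_points(r, pts) for n, r in vis.items()})
    table["carbon_density"] = plot_samples["carbon_density"].to_numpy()
    table = table.dropna(axis=0)
    model, selected, rep, vif_rep = _screen_and_fit(
        table, "carbon_density", candidates, spec, threshold, top_k, vif_limit)
    density_map, n_floored = predict_density_map(
        model, vis, np.asarray(forest_mask_30m, bool))
    return ApproachResult(model, density_map, selected, n_floored, rep, vif_rep)


def approach2(reference: ReferenceRaster30m, stack_l8: RasterStack,
              candidates: list[str] | None = None,
              spec: ModelSpec | None = None,
              sample_n: int | None = 2000, seed: int = 0,
              fraction_threshold: float = 0.5,
              threshold: float = 0.5, top_k: int | None = 3,
              vif_limit: float = 10.0) -> ApproachResult:
    """Coarse-resolution modeling against the fine-resolution reference.

    Training pairs are the 30 m cells whose forest fraction reaches
    ``fraction_threshold`` (mixed-pixel guard), subsampled to ``sample_n``
    cells with the given seed.  The fitted model predicts over every cell
    with any forest child and can be reapplied to another date's stack.
    """
    spec = spec or ModelSpec(kind="mlr")
    candidates = candidates or ["NDVI", "gNDVI", "SAVI", "DVI", "SR", "RDVI"]
    ref = reference.density
    if not grids_nested(ref.grid, stack_l8.grid, factor=1):
        raise ValueError("reference and Landsat stacks must share the 30 m grid")
    vis = _vi_rasters(stack_l8, candidates, "l8")
    eligible = (~ref.mask) & (reference.forest_fraction >= fraction_threshold)
    for r in vis.values():
        eligible &= ~r.mask
    idx = np.argwhere(eligible)
    if len(idx) < 10:
        raise ValueError(
            f"only {len(idx)} eligible reference cells; need at least 10")
    if sample_n is not None and len(idx) > sample_n:
        rng = np.random.default_rng(seed)
        idx = idx[rng.choice(len(idx), size=sample_n, replace=False)]
    table = pd.DataFrame(
        {n: r.data[idx[:, 0], idx[:, 1]] for n, r in vis.items()})
    table["carbon_density"] = ref.data[idx[:, 0], idx[:, 1]]
    model, selected, rep, vif_rep = _screen_and_fit(
        table, "carbon_density", candidates, spec, threshold, top_k, vif_limit)
    density_map, n_floored = predict_density_map(model, vis, ~ref.mask)
    return ApproachResult(model, density_map, selected, n_floored, rep, vif_rep)


def apply_model_to_stack(model: FittedCarbonModel, stack_l8: RasterStack,
                         forest_mask: np.ndarray) -> tuple[Raster, int]:
    """Re-apply a fitted coarse model to another date's Landsat stack."""
    vis = _vi_rasters(stack_l8, list(model.predictor_names), "l8")
    return predict_density_map(model, vis, np.asarray(forest_mask, bool))


def discrepancy_classify(estimate: Raster, reference: Raster,
                         moderate_from: float = 0.30,
                         substantial_above: float = 0.60) -> DiscrepancySummary:
    """Classify per-pixel relative discrepancy |est - ref| / ref.

    Classes: minor (< 30%), moderate (30-60%, closed interval), substantial
    (> 60%).  Pixels with zero reference are excluded and counted.
    """
    if estimate.shape != reference.shape:
        raise ValueError("estimate and reference must be co-gridded")
    both = ~(estimate.mask | reference.mask)
    zero_ref = both & (reference.data == 0)
    compare = both & ~zero_ref
    rel = np.full(estimate.shape, np.nan)
    rel[compare] = np.abs(estimate.data[compare] - reference.data[compare]) \
        / np.abs(reference.data[compare])
    cls = np.zeros(estimate.shape, dtype=int)
    cls[compare & (rel < moderate_from)] = 1
    cls[compare & (rel >= moderate_from) & (rel <= substantial_above)] = 2
    cls[compare & (rel > substantial_above)] = 3
    n = int(compare.sum())
    if n == 0:
        raise ValueError("no jointly valid pixels to compare")
    fractions = {
        "minor": 100.0 * np.sum(cls == 1) / n,
        "moderate": 100.0 * np.sum(cls == 2) / n,
        "substantial": 100.0 * np.sum(cls == 3) / n,
    }
    return DiscrepancySummary(
        class_map=Raster(cls, estimate.grid, estimate.crs, ~compare),
        fractions=fractions, n_compared=n,
        n_excluded_zero_reference=int(zero_ref.sum()))


def total_storage(density: Raster, pixel_area_ha_: float | None = None,
                  area_weights: np.ndarray | None = None) -> StorageStats:
    """Total carbon storage (t) and density summary of a map.

    ``area_weights`` (e.g. per-cell forest fraction on the coarse grid)
    scales each pixel's area; totals then conserve mass across resolutions.
    """
    area = pixel_area_ha_ if pixel_area_ha_ is not None \
        else pixel_area_ha(density.resolution_m)
    valid = ~density.mask
    if not valid.any():
        warnings.warn("all pixels are nodata; total storage is 0")
        return StorageStats(0.0, np.nan, np.nan, np.nan, 0.0, 0)
    w = np.ones(density.shape) if area_weights is None \
        else np.asarray(area_weights, float)
    v = density.data[valid]
    wv = w[valid]
    total = float(np.sum(v * wv) * area)
    return StorageStats(
        total_t=total, mean_density=float(v.mean()),
        min_density=float(v.min()), max_density=float(v.max()),
        area_ha=float(wv.sum() * area), n_pixels=int(valid.sum()))


def composition_and_change(class_totals: dict[str, float],
                           date_totals: dict | None = None) -> StorageReport:
    """Per-class composition (%) and between-date change (t and %).

    ``class_totals`` maps class -> total storage (t) for the reporting date;
    ``date_totals`` maps date label -> whole-forest total, ordered earlier
    to later (change = later - earlier, percent relative to the earlier).
    """
    if any(v < 0 for v in class_totals.values()):
        raise ValueError("storage totals must be nonnegative")
    whole = sum(class_totals.values())
    comp = {k: (100.0 * v / whole if whole > 0 else 0.0)
            for k, v in class_totals.items()}
    change_t = change_pct = None
    date_totals = date_totals or {}
    if len(date_totals) >= 2:
        keys = list(date_totals)
        earlier, later = date_totals[keys[0]], date_totals[keys[-1]]
        change_t = later - earlier
        change_pct = 100.0 * change_t / earlier if earlier > 0 else np.nan
    return StorageReport(
        class_totals=dict(class_totals), whole_forest_total=whole,
        composition_pct=comp, date_totals=dict(date_totals),
        change_t=change_t, change_pct=change_pct)
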