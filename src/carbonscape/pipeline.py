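"""End-to-end convenience pipelines over the module-level operations.

These functions wire the standard workflow together: plot accounting ->
per-class fine-resolution (10 m) vegetation-index models -> whole-forest
mosaic -> 30 m reference -> the two coarse-resolution estimation
approaches.  Everything they do is available piecemeal from the individual
modules; they exist so scripts and experiments stay short.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import allometry as allo
from .crossres import (ApproachResult, ReferenceRaster30m,
                       SpeciesDensityMosaic, aggregate_to_30m, approach1,
                       approach2, mosaic_species, total_storage)
from .features import screen_by_correlation, vif_filter
from .indices import compute_vi, extract_at_points
from .models import ModelSpec, fit, predict_density_map
from .raster import Raster
from .synthetic import CLASS_LABELS, SyntheticScene, generate_plots

S2A_CANDIDATES = ["NDVI", "SAVI", "gNDVI", "DVI", "reNDVI", "SR", "reSR",
                  "ARVI", "RDVI"]
L8_CANDIDATES = ["NDVI", "gNDVI", "SAVI", "DVI", "SR", "RDVI"]


@dataclass
class FineScaleResult:
    per_class_models: dict
    mosaic: SpeciesDensityMosaic
    reference: ReferenceRaster30m
    samples: pd.DataFrame


def plot_density_table(plots: list[allo.PlotRecord],
                       registry: dict | None = None) -> pd.DataFrame:
    """Plot coordinates, class and allometric carbon density as one table."""
    registry = registry or allo.default_registry()
    rows = []
    for p in plots:
        sample = allo.plot_carbon_density(p, registry)
        rows.append({"plot_id": p.plot_id, "class_label": p.class_label,
                     "x": p.center["x"], "y": p.center["y"],
                     "carbon_density": sample.carbon_density})
    return pd.DataFrame(rows)


def fit_fine_scale(scene: SyntheticScene, samples: pd.DataFrame,
                   candidates: list[str] | None = None,
                   model_kind: str = "mlr",
                   threshold: float = 0.5, top_k: int = 3,
                   vif_limit: float = 10.0) -> FineScaleResult:
    """Per-class 10 m models -> whole-forest mosaic -> 30 m reference.

    For each dominant class, candidate vegetation indices are extracted at
    that class's plots, screened by |r| (with top-k fallback) and VIF, and a
    density model is fit and mapped over the class mask.  The per-class maps
    are mosaicked and block-aggregated to the 30 m reference.
    """
    candidates = candidates or S2A_CANDIDATES
    vis10 = {n: compute_vi(scene.stack_10m, n, sensor="s2a")
             for n in candidates}
    predictions, masks = {}, {}
    models = {}
    for label in CLASS_LABELS:
        sub = samples[samples["class_label"] == label]
        if len(sub) < 5 or not scene.class_mask(label).any():
            continue
        pts = list(zip(sub["x"], sub["y"]))
        table = pd.DataFrame({n: extract_at_points(r, pts)
                              for n, r in vis10.items()})
        y = sub["carbon_density"].to_numpy()
        report = screen_by_correlation(
            {n: table[n].to_numpy() for n in candidates}, y,
            threshold=threshold, top_k=top_k)
        selected = report.selected
        if len(selected) > 1:
            _, retained = vif_filter(table[selected], limit=vif_limit)
            selected = list(retained.columns)
        spec = ModelSpec(kind=model_kind, predictor_names=tuple(selected))
        model = fit(spec, table[selected], y)
        models[label] = model
        predictions[label], _ = predict_density_map(
            model, vis10, scene.class_mask(label))
        masks[label] = scene.class_mask(label)
    mosaic = mosaic_species(predictions, masks)
    reference = aggregate_to_30m(mosaic.merged)
    return FineScaleResult(per_class_models=models, mosaic=mosaic,
                           reference=reference, samples=samples)


@dataclass
class ApproachComparison:
    reference_total_t: float
    approach1_total_t: float
    approach2_total_t: float
    approach1: ApproachResult
    approach2: ApproachResult
    fine: FineScaleResult

    @property
    def approach2_at_least_as_close(self) -> bool:
        e1 = abs(self.approach1_total_t - self.reference_total_t)
        e2 = abs(self.approach2_total_t - self.reference_total_t)
        return e2 <= e1


def compare_approaches(scene: SyntheticScene, seed: int = 0,
                       model_kind: str = "mlr",
                       registry: dict | None = None) -> ApproachComparison:
    """Run both coarse-resolution approaches on one scene and compare their
    whole-forest totals against the fine-resolution reference total."""
    plots = generate_plots(scene)
    samples = plot_density_table(plots, registry)
    fine = fit_fine_scale(scene, samples)
    ref = fine.reference
    spec = ModelSpec(kind=model_kind, split_seed=seed)
    res1 = approach1(samples, scene.stack_30m, ref.forest_fraction > 0,
                     candidates=L8_CANDIDATES, spec=spec,
                     threshold=0.5, top_k=3)
    res2 = approach2(ref, scene.stack_30m, candidates=L8_CANDIDATES,
                     spec=spec, sample_n=2000, seed=seed,
                     threshold=0.5, top_k=3)
    weights = ref.forest_fraction
    t_ref = total_storage(ref.density, area_weights=weights).total_t
    t1 = total_storage(res1.density_map, area_weights=weights).total_t
    t2 = total_storage(res2.density_map, area_weights=weights).total_t
    return ApproachComparison(
        reference_total_t=t_ref, approach1_total_t=t1, approach2_total_t=t2,
        approach1=res1, approach2=res2, fine=fine)
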