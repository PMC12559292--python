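"""Fit the three density models per dominant class and map one of them.

Compares random forest, decision tree and multiple linear regression on the
synthetic Populus plots (7:3 split), prints the five fit metrics, and maps
the best model over the class mask to a storage total.
"""

import pandas as pd

from carbonscape import (ModelSpec, SceneConfig, compute_vi,
                         extract_at_points, fit, generate_plots,
                         generate_scene, plot_density_table,
                         predict_density_map, total_storage)

# a denser single-class survey than the default 20 plots, to give the
# machine-learning fits a fair training set
scene = generate_scene(SceneConfig(extent_pixels_10m=(210, 210), seed=31,
                                   n_plots_per_class={"Populus": 80}))
samples = plot_density_table(generate_plots(scene))
populus = samples[samples["class_label"] == "Populus"]

predictors = ("NDVI", "gNDVI")
vis = {n: compute_vi(scene.stack_10m, n, sensor="s2a") for n in predictors}
pts = list(zip(populus["x"], populus["y"]))
X = pd.DataFrame({n: extract_at_points(r, pts) for n, r in vis.items()})
y = populus["carbon_density"].to_numpy()

fitted = {}
for kind in ("rf", "dt", "mlr"):
    model = fit(ModelSpec(kind=kind, predictor_names=predictors), X, y)
    m = model.test_metrics
    fitted[kind] = model
    print(f"{kind:3s}  R2={m.r2:5.2f}  RMSE={m.rmse:5.2f}  rRMSE={m.rrmse:4.2f}"
          f"  MAE={m.mae:5.2f}  MBE={m.mbe:+5.2f}  (test n={m.n})")

best = max(fitted.values(), key=lambda m: m.test_metrics.r2)
density_map, n_floored = predict_density_map(
    best, vis, scene.class_mask("Populus"))
stats = total_storage(density_map)
print(f"\nbest model maps {stats.area_ha:.0f} ha of Populus at mean "
      f"{stats.mean_density:.1f} t/ha -> {stats.total_t:,.0f} t stored "
      f"({n_floored} negative predictions floored)")
# RMSE/MAE are in t/ha; MBE > 0 would mean the model underpredicts the
# plot densities.  The mapped total is density times the 0.01 ha pixel area
# summed over the class mask.
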