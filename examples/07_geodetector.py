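"""Geodetector factor and interaction analysis of the density surface.

Measures how much of the carbon-density variance the scene's categorical
factor rasters explain (factor detector), and whether two factors jointly
explain more than each alone (interaction detector).  A continuous
covariate is stratified into quantile bins first.
"""

import numpy as np

from carbonscape import (SceneConfig, discretize_continuous, factor_q,
                         generate_scene, interaction_q)

scene = generate_scene(SceneConfig(extent_pixels_10m=(150, 150), seed=61))
forest = scene.forest_mask_10m
density = scene.true_density_10m.data[forest]

strata = {name: r.data[forest] for name, r in scene.factor_rasters.items()}
for name, s in strata.items():
    res = factor_q(density, s)
    print(f"factor {name}: q = {res.q:.3f} "
          f"(construction target {scene.factor_targets[name]:.2f}, "
          f"{len(res.strata)} strata)")

# a continuous pseudo-covariate (noisy elevation proxy), quantile-stratified
rng = np.random.default_rng(61)
elevation = density * 2.0 + rng.normal(0, 15.0, density.size)
strata["elevation"] = discretize_continuous(elevation, k=5, method="quantile")
res = factor_q(density, strata["elevation"])
print(f"factor elevation (5 quantile bins): q = {res.q:.3f}")

pair = interaction_q(density, strata["terrain"], strata["climate"])
print(f"terrain x climate: q(A) = {pair.q_a:.3f}, q(B) = {pair.q_b:.3f}, "
      f"q(A∩B) = {pair.q:.3f} -> {pair.interaction}")
# q is the between-stratum share of total variance (0 = no explanatory
# power, 1 = density constant within every stratum); the interaction label
# compares the joint q with each factor's own q and with their sum.
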