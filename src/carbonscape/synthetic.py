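"""Synthetic paired-resolution scene generator with known ground truth.

Emulates the study system end to end so every pipeline stage is testable
without field or satellite data: a semi-arid forest mosaic of five dominant
classes (Populus, Salix, Pinus tabuliformis, other species, shrubs) on a
10 m grid that exactly nests a 30 m grid 3x3, with

- a latent carbon-density field (Gaussian-smoothed white noise, rescaled
  per class to the class's published density range and mean),
- six 10 m reflectance bands built as monotone saturating functions of
  density (red decreasing, NIR increasing via g = d/(d+K), reproducing the
  NDVI saturation behaviour of dense canopies) plus Gaussian band noise
  whose scale is calibrated by bisection so that corr(NDVI, density) over
  forest pixels hits a configured target,
- three 30 m bands that are exact 3x3 block means of the corresponding
  10 m bands before sensor noise, plus independent sensor noise,
- a six-class land-use truth map (cropland, forest, shrub, grassland,
  water, other) whose non-vegetated classes carry distinct base spectra,
- plot inventories whose stem lists are built by inverting the class's
  allometric model, so plot-level carbon accounting round-trips to the
  local true density, and
- categorical factor rasters with a calibrated geodetector q.

Every random draw flows from the root seed through a documented splitting
scheme (one substream per stage), so identical configs give bit-identical
scenes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from . import allometry as allo
from .indices import compute_vi
from .raster import GridSpec, Raster, RasterStack, block_reduce_mean

__all__ = ["SceneConfig", "SyntheticScene", "StrataResult",
           "generate_scene", "generate_plots", "generate_factor_strata",
           "CLASS_LABELS", "CLASS_CODES", "LANDUSE_CODES"]

CLASS_LABELS = ("Populus", "Salix", "Pinus tabuliformis", "other", "shrub")
CLASS_CODES = {label: i + 1 for i, label in enumerate(CLASS_LABELS)}

LANDUSE_CODES = {"cropland": 1, "forest": 2, "shrub": 3,
                 "grassland": 4, "water": 5, "other": 6}

# species used when synthesising plot inventories for each class
_CLASS_SPECIES = {
    "Populus": "Populus",
    "Salix": "Salix",
    "Pinus tabuliformis": "Pinus tabuliformis",
    "other": "Ulmus pumila",
    "shrub": "Caragana korshinskii",
}

# density (mean, min, max) in t/ha per class, from the 96-plot survey summary
_DEFAULT_DENSITY_PARAMS = {
    "Populus": (32.31, 4.04, 70.70),
    "Salix": (24.01, 2.09, 65.87),
    "Pinus tabuliformis": (18.25, 8.73, 73.86),
    "other": (23.31, 6.53, 45.03),
    "shrub": (9.13, 3.36, 15.69),
}

# forest-area share per class, derived from reported class storage/density
_DEFAULT_FRACTIONS = {
    "Populus": 0.07, "Salix": 0.02, "Pinus tabuliformis": 0.03,
    "other": 0.04, "shrub": 0.84,
}

_DEFAULT_PLOTS = {"Populus": 20, "Salix": 18, "Pinus tabuliformis": 20,
                  "other": 18, "shrub": 20}

_SAT_K = 50.0  # t/ha half-saturation of the reflectance response

# base reflectance per band for non-vegetated land-use classes
_LU_SPECTRA = {
    "cropland":  {"b2": 0.050, "b3": 0.090, "b4": 0.150, "b5": 0.200,
                  "b8": 0.350, "b8A": 0.360},
    "grassland": {"b2": 0.055, "b3": 0.095, "b4": 0.200, "b5": 0.210,
                  "b8": 0.280, "b8A": 0.290},
    "water":     {"b2": 0.060, "b3": 0.050, "b4": 0.035, "b5": 0.025,
                  "b8": 0.015, "b8A": 0.015},
    "other":     {"b2": 0.120, "b3": 0.180, "b4": 0.300, "b5": 0.330,
                  "b8": 0.360, "b8A": 0.370},
}

# vegetated pixels: reflectance = intercept + slope * g(density)
_VEG_SPECTRA = {
    "b2": (0.060, -0.020), "b3": (0.100, -0.030), "b4": (0.260, -0.200),
    "b5": (0.200, 0.050), "b8": (0.220, 0.330), "b8A": (0.230, 0.340),
}

_L8_FROM_S2A = {"b3": "b3", "b4": "b4", "b5": "b8"}  # green, red, NIR


@dataclass(frozen=True)
class SceneConfig:
    """Scene dimensions, class mixture, signal strength and sampling design."""

    extent_pixels_10m: tuple[int, int] = (300, 300)
    seed: int = 0
    species_fractions: dict = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    density_params: dict = field(
        default_factory=lambda: dict(_DEFAULT_DENSITY_PARAMS))
    vi_signal_r: float = 0.7
    sensor_noise_sd: float = 0.01
    n_plots_per_class: dict = field(default_factory=lambda: dict(_DEFAULT_PLOTS))
    forest_fraction: float = 0.8
    plot_noise_rel: float = 0.10
    field_smooth_sigma: float = 8.0

    def __post_init__(self) -> None:
        rows, cols = self.extent_pixels_10m
        if rows % 3 or cols % 3:
            raise ValueError(
                f"extent {self.extent_pixels_10m} must be divisible by 3 in "
                f"both dimensions for exact 10 m -> 30 m nesting")
        total = sum(self.species_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"species fractions must sum to 1 (got {total!r})")
        if set(self.species_fractions) != set(CLASS_LABELS):
            raise ValueError(f"species fractions must cover {CLASS_LABELS}")
        for label, (mean, lo, hi) in self.density_params.items():
            if not (0 < lo < hi and lo < mean < hi):
                raise ValueError(
                    f"{label}: density params need 0 < min < mean < max")
        if not 0.0 < self.vi_signal_r < 1.0:
            raise ValueError("vi_signal_r must lie in (0, 1)")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor noise sd must be nonnegative")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "extent_pixels_10m": list(self.extent_pixels_10m),
            "seed": self.seed,
            "species_fractions": dict(self.species_fractions),
            "density_params": {k: list(v) for k, v in self.density_params.items()},
            "vi_signal_r": self.vi_signal_r,
            "sensor_noise_sd": self.sensor_noise_sd,
            "n_plots_per_class": dict(self.n_plots_per_class),
            "forest_fraction": self.forest_fraction,
            "plot_noise_rel": self.plot_noise_rel,
            "field_smooth_sigma": self.field_smooth_sigma,
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload["extent_pixels_10m"] = tuple(payload["extent_pixels_10m"])
        payload["density_params"] = {
            k: tuple(v) for k, v in payload["density_params"].items()}
        return cls(**payload)


@dataclass
class SyntheticScene:
    config: SceneConfig
    true_density_10m: Raster
    species_mask_10m: Raster
    stack_10m: RasterStack
    stack_30m: RasterStack
    landuse_truth_10m: Raster
    landuse_truth_30m: Raster
    factor_rasters: dict[str, Raster]
    factor_targets: dict[str, float]
    clean_stack_10m: RasterStack
    clean_stack_30m: RasterStack
    calibrated_noise_sd: float

    @property
    def forest_mask_10m(self) -> np.ndarray:
        return self.species_mask_10m.data > 0

    def class_mask(self, label: str) -> np.ndarray:
        return self.species_mask_10m.data == CLASS_CODES[label]


@dataclass
class StrataResult:
    raster: Raster
    target_q: float
    achieved_q: float
    k: int


def _rng(seed: int, stage: int) -> np.random.Generator:
    """Documented seed-splitting scheme: one substream per pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), stage)))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")


def _match_mean_gamma(u: np.ndarray, lo: float, hi: float,
                      target_mean: float) -> np.ndarray:
    """Map u in [0,1] to [lo, hi] with a power chosen to match the mean."""

    def mean_err(gamma: float) -> float:
        return float(np.mean(lo + (hi - lo) * u ** gamma)) - target_mean

    if mean_err(1.0) == 0.0:
        gamma = 1.0
    else:
        lo_g, hi_g = 1e-3, 1e3
        if mean_err(lo_g) * mean_err(hi_g) > 0:  # unreachable mean: best effort
            gamma = 1.0
        else:
            gamma = brentq(mean_err, lo_g, hi_g, xtol=1e-10)
    return lo + (hi - lo) * u ** gamma


def _quantile_partition(order_values: np.ndarray,
                        fractions: list[float]) -> np.ndarray:
    """Assign codes 0..len(fractions)-1 by sorted rank with the given shares."""
    n = order_values.size
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(order_values, kind="stable")] = np.arange(n)
    bounds = np.cumsum(fractions) * n
    return np.searchsorted(bounds, ranks, side="right")


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Build the full paired-resolution scene from a validated config."""
    rows, cols = config.extent_pixels_10m
    shape = (rows, cols)
    sigma = config.field_smooth_sigma
    grid10 = GridSpec(0.0, rows * 10.0, 10.0)
    grid30 = grid10.coarsen(3)

    rng_fields = _rng(config.seed, 0)
    f_forest = _smooth_field(rng_fields, shape, sigma)
    f_species = _smooth_field(rng_fields, shape, sigma)
    f_landuse = _smooth_field(rng_fields, shape, sigma)

    # forest extent: top forest_fraction share of a smooth field
    thr = np.quantile(f_forest, 1.0 - config.forest_fraction)
    forest = f_forest >= thr

    # species mask: spatially coherent partition of the forest extent
    species = np.zeros(shape, dtype=int)
    fracs = [config.species_fractions[c] for c in CLASS_LABELS]
    codes = _quantile_partition(f_species[forest], fracs)
    species[forest] = codes + 1

    # non-forest land-use partition (shares of the non-forest area)
    landuse = np.zeros(shape, dtype=int)
    tree = forest & (species < CLASS_CODES["shrub"])
    landuse[tree] = LANDUSE_CODES["forest"]
    landuse[forest & ~tree] = LANDUSE_CODES["shrub"]
    nonforest = ~forest
    if nonforest.any():
        lu_codes = _quantile_partition(
            f_landuse[nonforest], [0.20, 0.55, 0.10, 0.15])
        lu_map = np.array([LANDUSE_CODES["cropland"], LANDUSE_CODES["grassland"],
                           LANDUSE_CODES["water"], LANDUSE_CODES["other"]])
        landuse[nonforest] = lu_map[lu_codes]

    # latent density: one smooth field, renormalised per class to its range
    rng_density = _rng(config.seed, 1)
    f_density = _smooth_field(rng_density, shape, sigma)
    density = np.zeros(shape)
    for label in CLASS_LABELS:
        sel = species == CLASS_CODES[label]
        if not sel.any():
            continue
        v = f_density[sel]
        lo_v, hi_v = v.min(), v.max()
        u = (v - lo_v) / (hi_v - lo_v) if hi_v > lo_v else np.full(v.shape, 0.5)
        mean, lo, hi = config.density_params[label]
        density[sel] = _match_mean_gamma(u, lo, hi, mean)

    # clean reflectance bands
    g = density / (density + _SAT_K)
    rng_bands = _rng(config.seed, 2)
    clean10: dict[str, np.ndarray] = {}
    for band, (intercept, slope) in _VEG_SPECTRA.items():
        base = np.full(shape, intercept)
        for lu, spectrum in _LU_SPECTRA.items():
            base[landuse == LANDUSE_CODES[lu]] = spectrum[band]
        veg = forest
        values = base + np.where(veg, slope * g, 0.0)
        values = values + 0.008 * _smooth_field(rng_bands, shape, sigma / 2.0)
        clean10[band] = np.clip(values, 0.0, 1.0)
    clean30 = {l8: block_reduce_mean(clean10[s2], 3)
               for l8, s2 in _L8_FROM_S2A.items()}

    # calibrate band noise so corr(NDVI, density) over forest hits the target
    noise_fields = {b: rng_bands.standard_normal(shape) for b in clean10}

    def forest_ndvi_corr(scale: float) -> float:
        b8 = np.clip(clean10["b8"] + scale * noise_fields["b8"], 0.0, 1.0)
        b4 = np.clip(clean10["b4"] + scale * noise_fields["b4"], 0.0, 1.0)
        den = b8 + b4
        ndvi = np.where(den > 0, (b8 - b4) / np.where(den > 0, den, 1.0), 0.0)
        return float(np.corrcoef(ndvi[forest], density[forest])[0, 1])

    r0 = forest_ndvi_corr(0.0)
    if r0 <= config.vi_signal_r:
        scale = 0.0  # noiseless field already at/below the requested signal
    else:
        lo_s, hi_s = 0.0, 0.5
        while forest_ndvi_corr(hi_s) > config.vi_signal_r and hi_s < 8.0:
            hi_s *= 2.0
        for _ in range(50):
            mid = 0.5 * (lo_s + hi_s)
            if forest_ndvi_corr(mid) > config.vi_signal_r:
                lo_s = mid
            else:
                hi_s = mid
        scale = 0.5 * (lo_s + hi_s)

    noisy10 = {b: np.clip(clean10[b] + scale * noise_fields[b], 0.0, 1.0)
               for b in clean10}
    rng_sensor = _rng(config.seed, 3)
    noisy30 = {b: np.clip(
        clean30[b] + config.sensor_noise_sd * rng_sensor.standard_normal(
            clean30[b].shape), 0.0, 1.0) for b in clean30}

    # 30 m land-use truth: majority vote over the nine 10 m children
    r2, c2 = rows // 3, cols // 3
    blocks = landuse.reshape(r2, 3, c2, 3).transpose(0, 2, 1, 3).reshape(r2, c2, 9)
    counts = np.stack([(blocks == code).sum(axis=2)
                       for code in range(1, 7)], axis=2)
    landuse30 = np.argmax(counts, axis=2) + 1  # ties -> lowest code

    scene = SyntheticScene(
        config=config,
        true_density_10m=Raster(density, grid10, mask=~forest),
        species_mask_10m=Raster(species, grid10),
        stack_10m=RasterStack(noisy10, grid10),
        stack_30m=RasterStack(noisy30, grid30),
        landuse_truth_10m=Raster(landuse, grid10),
        landuse_truth_30m=Raster(landuse30, grid30),
        factor_rasters={}, factor_targets={},
        clean_stack_10m=RasterStack(clean10, grid10),
        clean_stack_30m=RasterStack(clean30, grid30),
        calibrated_noise_sd=scale,
    )

    # two default categorical factor rasters with calibrated explanatory power
    for i, (name, k, effect) in enumerate(
            [("terrain", 5, 0.5), ("climate", 4, 0.25)]):
        res = generate_factor_strata(scene, k=k, effect_fraction=effect,
                                     seed=config.seed * 1000 + i)
        scene.factor_rasters[name] = res.raster
        scene.factor_targets[name] = res.target_q
    return scene


# ---------------------------------------------------------------------------
# plot inventory synthesis (inverse allometry)
# ---------------------------------------------------------------------------

def _solve_tree_dims(model: allo.AllometricModel, carbon_kg: float
                     ) -> tuple[float, float]:
    """Stem (dbh_cm, height_m) whose modelled carbon equals carbon_kg.

    Solves the organ-sum power law for the scalar x = D^2 H, then fixes the
    taper H = D/2 (H in m, D in cm)."""
    cc = model.carbon_coefficient

    def err(log_x: float) -> float:
        x = math.exp(log_x)
        total = sum(a * x ** b for a, b in model.organ_coefficients.values())
        return cc * total - carbon_kg

    log_x = brentq(err, math.log(1e-9), math.log(1e12), xtol=1e-12)
    x = math.exp(log_x)
    d = (2.0 * x) ** (1.0 / 3.0)
    return d, d / 2.0


def _solve_shrub_dims(model: allo.AllometricModel, carbon_kg: float
                      ) -> tuple[float, float]:
    """Shrub (crown_m, height_m) whose modelled carbon equals carbon_kg.

    Inverts W = a V^b for the crown volume, then fixes H = 0.8 M."""
    a, b = model.whole_coefficients
    w = carbon_kg / model.carbon_coefficient
    v = (w / a) ** (1.0 / b)
    m = (v / (math.pi / 6.0 * 0.8)) ** (1.0 / 3.0)
    return m, 0.8 * m


_HERB_JITTER = (0.9, 1.0, 1.1)  # multiplicative, mean exactly 1


def generate_plots(scene: SyntheticScene, config: SceneConfig | None = None,
                   registry: dict[str, allo.AllometricModel] | None = None,
                   herb_carbon_coefficient: float = allo.DEFAULT_HERB_CARBON_COEFFICIENT,
                   ) -> list[allo.PlotRecord]:
    """Synthesise plot inventories whose computed carbon density matches the
    local true density (up to the configured relative noise).

    Plot centers are sampled within each class's mask; a class whose mask is
    empty is skipped with a warning.  Tree plots carry identical stems whose
    common D^2 H solves the class's allometric total; shrub plots carry
    crown/height individuals; every plot carries three herb quadrats.
    """
    config = config or scene.config
    registry = registry or allo.default_registry()
    rng = _rng(config.seed, 5)
    plots: list[allo.PlotRecord] = []
    for label in CLASS_LABELS:
        n_wanted = int(config.n_plots_per_class.get(label, 0))
        if n_wanted == 0:
            continue
        if n_wanted < 2:
            raise ValueError(f"{label}: n_plots_per_class must be >= 2")
        pix = np.argwhere(scene.class_mask(label))
        if len(pix) == 0:
            warnings.warn(f"class {label!r} has an empty mask; no plots generated")
            continue
        take = min(n_wanted, len(pix))
        sel = pix[rng.choice(len(pix), size=take, replace=False)]
        species_label = _CLASS_SPECIES[label]
        model = registry[species_label]
        is_shrub = label == "shrub"
        area = allo.SHRUB_PLOT_AREA_HA if is_shrub else allo.TREE_PLOT_AREA_HA
        for i, (r, c) in enumerate(sel):
            x, y = scene.true_density_10m.grid.rowcol_to_xy(r, c)
            local = float(scene.true_density_10m.data[r, c])
            target = local * (1.0 + config.plot_noise_rel * rng.standard_normal())
            target = max(target, 0.05 * local)
            # herb layer: a few percent of the plot's density
            herb_density = min(float(rng.uniform(0.02, 0.06)) * target, target)
            base_mass_g = herb_density / 10.0 / herb_carbon_coefficient * 1000.0
            quadrats = [(0.65 * base_mass_g * j, 0.35 * base_mass_g * j)
                        for j in _HERB_JITTER]
            woody_t_ha = target - herb_density
            woody_kg = woody_t_ha * area * 1000.0
            plot = allo.PlotRecord(
                plot_id=f"{label.replace(' ', '_')}-{i:03d}",
                class_label=label, center={"x": float(x), "y": float(y)},
                plot_area=area, herb_quadrats=quadrats)
            if woody_kg > 0:
                if is_shrub:
                    n_ind = max(1, round(woody_kg / 2.0))
                    m, h = _solve_shrub_dims(model, woody_kg / n_ind)
                    plot.shrubs = [(species_label, m, h)] * n_ind
                else:
                    n_stems = max(1, round(woody_kg / 30.0))
                    d, h = _solve_tree_dims(model, woody_kg / n_stems)
                    plot.stems = [(species_label, d, h)] * n_stems
            plots.append(plot)
    return plots


# ---------------------------------------------------------------------------
# factor strata with calibrated geodetector q
# ---------------------------------------------------------------------------

def _kmeans_partition(v: np.ndarray, k: int) -> np.ndarray:
    """1-D k-means clustering of the values: the (near-)maximal-q partition
    attainable with k strata, robust to skewed mixtures."""
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=k, n_init=4, random_state=0)
    return km.fit_predict(v.reshape(-1, 1))


def _q_of_codes(v: np.ndarray, codes: np.ndarray, k: int) -> float:
    cnt = np.bincount(codes, minlength=k)
    sums = np.bincount(codes, weights=v, minlength=k)
    sqs = np.bincount(codes, weights=v * v, minlength=k)
    nz = cnt > 0
    ssw = float(np.sum(sqs[nz] - sums[nz] ** 2 / cnt[nz]))
    sst = float(np.sum((v - v.mean()) ** 2))
    return 1.0 - ssw / sst if sst > 0 else 0.0


def generate_factor_strata(scene: SyntheticScene, k: int,
                           effect_fraction: float, seed: int) -> StrataResult:
    """Categorical strata over the forest extent whose between-stratum share
    of density variance is calibrated to ``effect_fraction``.

    Construction: start from the 1-D k-means partition of density (the
    near-maximal-q partition attainable with k strata) and randomly
    reassign a number of pixels solved by bisection on the directly
    computed q.  A request beyond that partition's attainable maximum is
    capped there with a warning (a finite partition of a continuous field
    cannot reach q = 1 exactly).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if not 0.0 <= effect_fraction <= 1.0:
        raise ValueError("effect_fraction must lie in [0, 1]")
    forest = scene.forest_mask_10m
    v = scene.true_density_10m.data[forest].astype(float)
    n = v.size
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} forest pixels")
    rng = _rng(seed, 4)
    base = _kmeans_partition(v, k)
    rand_labels = rng.integers(0, k, size=n)
    perm = rng.permutation(n)

    def codes_at(t: int) -> np.ndarray:
        s = base.copy()
        s[perm[:t]] = rand_labels[perm[:t]]
        return s

    q_max = _q_of_codes(v, base, k)
    if effect_fraction >= q_max:
        t_best = 0
        if effect_fraction > q_max + 1e-9:
            warnings.warn(
                f"requested effect fraction {effect_fraction} exceeds the "
                f"attainable maximum {q_max:.4f} for k={k}; capped there")
    elif effect_fraction == 0.0:
        t_best = n
    else:
        lo_t, hi_t = 0, n
        while hi_t - lo_t > 1:
            mid = (lo_t + hi_t) // 2
            if _q_of_codes(v, codes_at(mid), k) > effect_fraction:
                lo_t = mid
            else:
                hi_t = mid
        # local scan to absorb non-monotone wiggles of q(t)
        span = range(max(0, lo_t - 25), min(n, lo_t + 26))
        t_best = min(span, key=lambda t: abs(
            _q_of_codes(v, codes_at(t), k) - effect_fraction))
    codes = codes_at(t_best)
    achieved = _q_of_codes(v, codes, k)
    out = np.zeros(scene.true_density_10m.shape, dtype=int)
    out[forest] = codes + 1
    raster = Raster(out, scene.true_density_10m.grid,
                    scene.true_density_10m.crs, ~forest)
    return StrataResult(raster=raster, target_q=float(effect_fraction),
                        achieved_q=float(achieved), k=k)
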