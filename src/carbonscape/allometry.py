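"""Allometric biomass and carbon accounting for field plots.

Individual tree biomass follows organ-wise power laws W = a * (D^2 H)^b with
the diameter at breast height D in cm, the height H in m and the organ dry
mass W in kg; the four organs (trunk, branch, leaf, root) are summed to a
whole-tree mass.  Shrub biomass uses a whole-plant form driven by crown
width M (m) and height H (m): either a power law in the crown volume
V = (pi/6) * M^2 * H (ellipsoid convention, configurable) or a quadratic
polynomial in H*M.  Dry mass converts to carbon through a species-specific
carbon coefficient (fraction of dry biomass that is carbon).  Herbaceous
carbon comes from oven-dried quadrat masses.

Plot carbon density is the plot's summed tree + shrub carbon (kg -> t,
divided by the plot area in ha) plus the mean herbaceous quadrat carbon
(kg C/m^2 scaled by 10 to t/ha).  Tree plots cover 20 x 20 m (0.04 ha),
shrub plots 10 x 10 m (0.01 ha), herb quadrats 1 x 1 m.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AllometricModel", "PlotRecord", "CarbonDensitySample",
    "crown_volume", "tree_biomass", "shrub_biomass", "individual_carbon",
    "herb_carbon", "plot_carbon_density", "default_registry",
    "plots_to_frame", "frame_to_plots", "write_plots_csv", "read_plots_csv",
]

ORGANS = ("trunk", "branch", "leaf", "root")

TREE_PLOT_AREA_HA = 0.04   # 20 x 20 m
SHRUB_PLOT_AREA_HA = 0.01  # 10 x 10 m
QUADRAT_AREA_M2 = 1.0

DEFAULT_HERB_CARBON_COEFFICIENT = 0.45  # configurable; guideline value not published


@dataclass(frozen=True)
class AllometricModel:
    """Biomass equation set plus carbon coefficient for one species group.

    ``form`` is one of:

    - ``organ_power``: W_organ = a * (D^2 H)^b per organ, summed over the
      four organs (trees);
    - ``whole_power``: W = a * V^b with V the crown volume (shrubs);
    - ``whole_poly``:  W = c0 + c1*(H*M) + c2*(H*M)^2 (shrubs).
    """

    species_label: str
    form: str
    carbon_coefficient: float
    organ_coefficients: dict[str, tuple[float, float]] | None = None
    whole_coefficients: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.carbon_coefficient < 1.0:
            raise ValueError(
                f"{self.species_label}: carbon coefficient must lie in (0, 1)")
        if self.form == "organ_power":
            if (self.organ_coefficients is None
                    or set(self.organ_coefficients) != set(ORGANS)):
                raise ValueError(
                    f"{self.species_label}: organ_power models must define "
                    f"all four organs {ORGANS}")
            if any(a <= 0 for a, _ in self.organ_coefficients.values()):
                raise ValueError(
                    f"{self.species_label}: organ scale coefficients must be positive")
        elif self.form == "whole_power":
            if self.whole_coefficients is None or len(self.whole_coefficients) != 2:
                raise ValueError(
                    f"{self.species_label}: whole_power needs coefficients (a, b)")
            if self.whole_coefficients[0] <= 0:
                raise ValueError(f"{self.species_label}: scale coefficient must be positive")
        elif self.form == "whole_poly":
            if self.whole_coefficients is None or len(self.whole_coefficients) != 3:
                raise ValueError(
                    f"{self.species_label}: whole_poly needs coefficients (c0, c1, c2)")
        else:
            raise ValueError(f"unknown allometric form {self.form!r}")


@dataclass
class PlotRecord:
    """One surveyed plot: stems, shrub individuals and herb quadrats."""

    plot_id: str
    class_label: str
    center: dict[str, float]
    plot_area: float  # ha
    stems: list[tuple[str, float, float]] = field(default_factory=list)      # (species, dbh_cm, height_m)
    shrubs: list[tuple[str, float, float]] = field(default_factory=list)     # (species, crown_m, height_m)
    herb_quadrats: list[tuple[float, float]] = field(default_factory=list)   # (above_g, below_g)

    def __post_init__(self) -> None:
        if self.plot_area <= 0:
            raise ValueError(f"plot {self.plot_id}: plot_area must be positive")
        for sp, d, h in self.stems:
            if d < 0 or h < 0:
                raise ValueError(f"plot {self.plot_id}: negative stem dimensions")
        for sp, m, h in self.shrubs:
            if m < 0 or h < 0:
                raise ValueError(f"plot {self.plot_id}: negative shrub dimensions")
        for a, b in self.herb_quadrats:
            if a < 0 or b < 0:
                raise ValueError(f"plot {self.plot_id}: negative quadrat masses")


@dataclass(frozen=True)
class CarbonDensitySample:
    plot_id: str
    class_label: str
    carbon_density: float  # t/ha
    components: dict[str, float]  # {tree, shrub, herb} in t/ha


def crown_volume(crown_width_m: float, height_m: float) -> float:
    """Ellipsoid crown volume V = (pi/6) * M^2 * H in m^3."""
    return math.pi / 6.0 * crown_width_m ** 2 * height_m


def tree_biomass(model: AllometricModel, dbh_cm: float, height_m: float
                 ) -> tuple[dict[str, float], float]:
    """Organ dry masses (kg) and their total for one stem."""
    if model.form != "organ_power":
        raise ValueError(
            f"tree_biomass requires an organ_power model, got {model.form!r} "
            f"for {model.species_label}")
    if dbh_cm <= 0 or height_m <= 0:
        raise ValueError("dbh and height must be positive")
    x = dbh_cm ** 2 * height_m
    organs = {o: a * x ** b for o, (a, b) in model.organ_coefficients.items()}
    return organs, sum(organs.values())


def shrub_biomass(model: AllometricModel, crown_width_m: float, height_m: float,
                  volume_fn=crown_volume) -> float:
    """Whole-shrub dry mass (kg) from crown width and height."""
    if crown_width_m <= 0 or height_m <= 0:
        raise ValueError("crown width and height must be positive")
    if model.form == "whole_power":
        a, b = model.whole_coefficients
        w = a * volume_fn(crown_width_m, height_m) ** b
    elif model.form == "whole_poly":
        c0, c1, c2 = model.whole_coefficients
        hm = height_m * crown_width_m
        w = c0 + c1 * hm + c2 * hm ** 2
    else:
        raise ValueError(
            f"shrub_biomass requires whole_power or whole_poly, got {model.form!r}")
    if not math.isfinite(w):
        raise FloatingPointError(
            f"{model.species_label}: biomass evaluation produced a non-finite value")
    return w


def individual_carbon(biomass_kg: float, carbon_coefficient: float) -> float:
    """kg C of one individual: dry mass times the carbon fraction."""
    if biomass_kg < 0 or carbon_coefficient <= 0:
        raise ValueError("biomass must be >= 0 and carbon coefficient > 0")
    return biomass_kg * carbon_coefficient


def herb_carbon(quadrats: list[tuple[float, float]],
                herb_carbon_coefficient: float = DEFAULT_HERB_CARBON_COEFFICIENT
                ) -> float:
    """Mean herbaceous carbon over quadrats, kg C per m^2.

    Each quadrat contributes (above + below dry mass in g -> kg) times the
    herb carbon coefficient over its 1 m^2 area.
    """
    if not quadrats:
        raise ValueError("herb_carbon needs at least one quadrat")
    per = [(a + b) / 1000.0 * herb_carbon_coefficient / QUADRAT_AREA_M2
           for a, b in quadrats]
    return float(np.mean(per))


def _resolve(registry: dict[str, AllometricModel], species: str,
             fallback: AllometricModel | None) -> AllometricModel:
    if species in registry:
        return registry[species]
    if fallback is not None:
        return fallback
    raise KeyError(
        f"species {species!r} not found in the allometric registry and no "
        f"fallback model was provided")


def plot_carbon_density(plot: PlotRecord,
                        registry: dict[str, AllometricModel],
                        herb_carbon_coefficient: float = DEFAULT_HERB_CARBON_COEFFICIENT,
                        fallback: AllometricModel | None = None,
                        volume_fn=crown_volume) -> CarbonDensitySample:
    """Roll a plot's individuals up to carbon density in t/ha.

    Woody carbon (kg) is converted to t and divided by the plot area (ha);
    the herbaceous component (kg C/m^2) converts to t/ha by the factor 10.
    """
    tree_kg = 0.0
    for species, dbh, height in plot.stems:
        model = _resolve(registry, species, fallback)
        _, total = tree_biomass(model, dbh, height)
        tree_kg += individual_carbon(total, model.carbon_coefficient)
    shrub_kg = 0.0
    for species, crown, height in plot.shrubs:
        model = _resolve(registry, species, fallback)
        try:
            w = shrub_biomass(model, crown, height, volume_fn=volume_fn)
        except FloatingPointError as exc:
            warnings.warn(f"plot {plot.plot_id}: {exc}; individual skipped")
            continue
        shrub_kg += individual_carbon(w, model.carbon_coefficient)
    tree = tree_kg / 1000.0 / plot.plot_area
    shrub = shrub_kg / 1000.0 / plot.plot_area
    herb = 0.0
    if plot.herb_quadrats:
        herb = herb_carbon(plot.herb_quadrats, herb_carbon_coefficient) * 10.0
    return CarbonDensitySample(
        plot_id=plot.plot_id,
        class_label=plot.class_label,
        carbon_density=tree + shrub + herb,
        components={"tree": tree, "shrub": shrub, "herb": herb},
    )


def default_registry() -> dict[str, AllometricModel]:
    """Published organ-wise equations and carbon coefficients for the Ordos
    species groups.

    Tree entries carry the published coefficients.  The two shrub whole-plant
    entries are shipped as corrected PLACEHOLDER forms: the published source
    for the Caragana korshinskii / Salix cheilophila power law and the
    Artemisia ordosica polynomial is typographically corrupted (an impossible
    exponent and a missing operator), so the forms here are plausible
    repairs — replace them from an authoritative source before using them for
    real inventories.  All coefficients live in config precisely so they can
    be overridden.
    """
    reg = {
        "Populus": AllometricModel(
            "Populus", "organ_power", 0.48,
            organ_coefficients={
                "trunk": (0.0859, 0.8001), "branch": (0.0036, 0.8437),
                "leaf": (0.0291, 0.6136), "root": (0.0143, 0.8772)}),
        "Salix": AllometricModel(
            "Salix", "organ_power", 0.47,
            organ_coefficients={
                "trunk": (0.0535, 0.8977), "branch": (0.0064, 0.9495),
                "leaf": (0.0070, 0.7347), "root": (0.0253, 0.8435)}),
        "Pinus tabuliformis": AllometricModel(
            "Pinus tabuliformis", "organ_power", 0.50,
            organ_coefficients={
                "trunk": (0.0455, 0.8716), "branch": (1.1125, 0.3455),
                "leaf": (0.0280, 0.6399), "root": (0.0191, 0.8682)}),
        "Ulmus pumila": AllometricModel(
            "Ulmus pumila", "organ_power", 0.48,
            organ_coefficients={
                "trunk": (0.0455, 0.8716), "branch": (0.0814, 0.7510),
                "leaf": (0.0178, 0.7584), "root": (0.0772, 0.8176)}),
        "Pinus sylvestris var. mongholica": AllometricModel(
            "Pinus sylvestris var. mongholica", "organ_power", 0.41,
            organ_coefficients={
                "trunk": (0.0805, 0.8063), "branch": (0.0669, 0.6268),
                "leaf": (0.0961, 0.6553), "root": (0.2385, 0.5227)}),
        # placeholder repair of a corrupted source exponent (not a published value)
        "Caragana korshinskii": AllometricModel(
            "Caragana korshinskii", "whole_power", 0.47,
            whole_coefficients=(0.90, 1.06)),
        "Salix cheilophila": AllometricModel(
            "Salix cheilophila", "whole_power", 0.47,
            whole_coefficients=(0.90, 1.06)),
        # placeholder repair of a polynomial with a missing operator (not published)
        "Artemisia ordosica": AllometricModel(
            "Artemisia ordosica", "whole_poly", 0.47,
            whole_coefficients=(0.061, 2.854e-6, 51.622)),
    }
    return reg


# ---------------------------------------------------------------------------
# Plot CSV schema: one row per individual
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["plot_id", "class_label", "layer", "species", "dbh_cm",
                "height_m", "crown_m", "above_g", "below_g", "x", "y"]


def plots_to_frame(plots: list[PlotRecord]) -> pd.DataFrame:
    rows = []
    for p in plots:
        base = dict(plot_id=p.plot_id, class_label=p.class_label,
                    x=p.center["x"], y=p.center["y"])
        for sp, d, h in p.stems:
            rows.append({**base, "layer": "tree", "species": sp,
                         "dbh_cm": d, "height_m": h})
        for sp, m, h in p.shrubs:
            rows.append({**base, "layer": "shrub", "species": sp,
                         "crown_m": m, "height_m": h})
        for a, b in p.herb_quadrats:
            rows.append({**base, "layer": "herb", "species": "herb",
                         "above_g": a, "below_g": b})
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_plots(frame: pd.DataFrame) -> list[PlotRecord]:
    plots: list[PlotRecord] = []
    for plot_id, grp in frame.groupby("plot_id", sort=False):
        cls = str(grp["class_label"].iloc[0])
        area = SHRUB_PLOT_AREA_HA if cls == "shrub" else TREE_PLOT_AREA_HA
        p = PlotRecord(
            plot_id=str(plot_id), class_label=cls,
            center={"x": float(grp["x"].iloc[0]), "y": float(grp["y"].iloc[0])},
            plot_area=area)
        for _, row in grp.iterrows():
            if row["layer"] == "tree":
                p.stems.append((str(row["species"]), float(row["dbh_cm"]),
                                float(row["height_m"])))
            elif row["layer"] == "shrub":
                p.shrubs.append((str(row["species"]), float(row["crown_m"]),
                                 float(row["height_m"])))
            elif row["layer"] == "herb":
                p.herb_quadrats.append((float(row["above_g"]),
                                        float(row["below_g"])))
            else:
                raise ValueError(f"unknown layer {row['layer']!r}")
        plots.append(p)
    return plots


def write_plots_csv(path: str | Path, plots: list[PlotRecord]) -> None:
    plots_to_frame(plots).to_csv(path, index=False)


def read_plots_csv(path: str | Path) -> list[PlotRecord]:
    return frame_to_plots(pd.read_csv(path))
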