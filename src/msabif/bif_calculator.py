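"""Country-level biodiversity impact factors (BIFs) from attributed losses.

A BIF expresses the area-integrated (and, for emissions, time-
integrated) loss of mean species abundance per unit of pressure
generated in a country:

* CO2 (or CO2-eq) emissions — MSA-loss km2 yr per kg, global (climate
  is a well-mixed pressure, so every country shares one factor);
* NH3 / NOx emissions — MSA-loss km2 yr per kg emitted, routed to the
  receiving regions through a source-receptor matrix and converted
  from deposited N back to the emitted substance with a nitrogen-ion
  conversion factor (plants only);
* land use — MSA-loss km2 per km2 of each land-use class occupied;
* roads — MSA-loss km2 per km of road (types 1-3).

Zonal ratios (loss-area over pressure extent) are accumulated in exact
rational arithmetic and rounded once at the end.  This keeps the
model's theoretical constancies exact: a factor that is analytically
identical across countries (e.g. plant habitat loss in cropland under
uniform warming) comes out bit-identical regardless of how many cells
each country happens to contain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .globio_engine import (
    FEATURE_MINE,
    FEATURE_ROAD,
    FRAGMENTING_CLASSES,
    EngineResult,
)
from .impact_relationships import Driver, Group
from .synthetic_world import (
    LANDUSE_BY_NAME,
    LANDUSE_NAMES,
    LandUse,
    SourceReceptorMatrix,
)

__all__ = [
    "NICF",
    "Constants",
    "nicf",
    "bif_co2",
    "bif_nitrogen",
    "bif_land_use",
    "bif_roads",
    "combine_groups",
    "derive_bif_table",
    "UNITS_EMISSION",
    "UNITS_LANDUSE",
    "UNITS_ROADS",
]

UNITS_EMISSION = "MSA-loss km2 yr kg-1"
UNITS_LANDUSE = "MSA-loss km2 km-2"
UNITS_ROADS = "MSA-loss km2 km-1"

# molar masses (g/mol)
_M_N, _M_NH3, _M_NO2, _M_NO = 14.0, 17.0, 46.0, 30.0

#: land-use classes carrying a fragmentation BIF (the fragmenting barriers)
FRAGMENTATION_BIF_CLASSES = tuple(LANDUSE_NAMES[c] for c in FRAGMENTING_CLASSES)


@dataclass(frozen=True)
class NICF:
    """Nitrogen-ion conversion factor: kg substance emitted per kg N deposited."""

    substance: str
    value: float
    no2_share: float = 0.90

    def __post_init__(self):
        if not 0.0 < self.value < 1.0:
            raise ValueError("NICF must lie strictly between 0 and 1")


@dataclass(frozen=True)
class Constants:
    """Physical constants of the factor derivation.

    ``iagtp_co2`` is the time-integrated absolute global temperature
    change potential of CO2 (degC yr per kg; default for a 100-year
    horizon).  ``gmti`` must equal the warming used in the engine run.
    """

    iagtp_co2: float = 47.6e-15
    gmti: float = 1.26
    horizon_yr: int = 100

    def __post_init__(self):
        if self.iagtp_co2 <= 0 or self.gmti <= 0:
            raise ValueError("IAGTP and GMTI must be positive")


def nicf(substance: str, no2_share: float = 0.90) -> NICF:
    """Nitrogen-ion conversion factor for NH3 or NOx.

    NH3 is 14/17 by molar mass.  NOx is a photostationary mix of NO2
    and NO (90/10 by default): ``share * 14/46 + (1 - share) * 14/30``.
    """
    if not 0.0 <= no2_share <= 1.0:
        raise ValueError("no2_share must lie in [0, 1]")
    s = substance.upper().replace("₃", "3").replace("ₓ", "X")
    if s == "NH3":
        return NICF("NH3", _M_N / _M_NH3, no2_share)
    if s == "NOX":
        value = no2_share * _M_N / _M_NO2 + (1.0 - no2_share) * _M_N / _M_NO
        return NICF("NOx", value, no2_share)
    raise ValueError(f"unknown nitrogen substance {substance!r}")


def _exact_ratio(numerator_terms: np.ndarray, denominator_terms: np.ndarray) -> float:
    """Sum both sides as exact rationals, divide, round once to float."""
    num = sum(map(Fraction, numerator_terms.ravel().tolist()), Fraction(0))
    den = sum(map(Fraction, denominator_terms.ravel().tolist()), Fraction(0))
    if den == 0:
        return 0.0
    return float(num / den)


# ---------------------------------------------------------------------------
# pressure-specific factors
# ---------------------------------------------------------------------------

def bif_co2(result: EngineResult, constants: Constants, group: Group) -> float:
    """Global CO2 impact factor: IAGTP times climate loss-area per degree.

    The cumulative climate-change MSA loss integrated over area, divided
    by the warming that caused it, gives loss-area per degC; multiplying
    by the IAGTP of CO2 converts to loss-area-time per kg emitted.
    """
    if not math.isclose(constants.gmti, result.world.gmti, rel_tol=0, abs_tol=0):
        raise ValueError(
            f"constants.gmti ({constants.gmti}) differs from the engine-run "
            f"GMTI ({result.world.gmti})")
    loss = result.losses.per_driver[(Group(group), Driver.CLIMATE)]
    loss_area = float(np.sum(loss * result.world.cell_area))
    return constants.iagtp_co2 * loss_area / constants.gmti


def bif_nitrogen(result: EngineResult, srm: SourceReceptorMatrix,
                 conversion: NICF, group: Group = Group.PLANTS) -> np.ndarray:
    """Per-country impact factor for a nitrogen substance (plants only).

    For each receiving region the loss-area per kg of nitrogen deposited
    is the region's deposition-attributed loss integrated over area
    divided by the total mass of N deposited there.  The emitting
    region's factor is the SRM-weighted sum over receiving regions,
    scaled by the nitrogen-ion conversion factor; every country inherits
    its region's value.
    """
    world = result.world
    if Group(group) != Group.PLANTS:
        raise ValueError("nitrogen deposition factors exist for plants only")
    key = (Group.PLANTS, Driver.NITROGEN)
    loss = result.losses.per_driver[key]
    region_ids = sorted(set(world.region_of_country.values()))
    if len(region_ids) != srm.n_regions or region_ids != list(range(srm.n_regions)):
        raise ValueError("SRM regions must be 0..n-1 and cover every mapped region")
    region_of_cell = np.vectorize(world.region_of_country.get)(world.country_index)

    cell_ha = world.cell_area * 100.0
    eff = np.zeros(srm.n_regions)  # loss-area per kg N deposited, per region
    for k in range(srm.n_regions):
        m = region_of_cell == k
        dep_kg = float(np.sum(world.deposition[m]) * cell_ha)
        if dep_kg <= 0.0:
            if np.any(srm.fractions[:, k] > 0):
                warnings.warn(
                    f"region {k} receives emissions but has zero deposition; "
                    "contributing 0", RuntimeWarning, stacklevel=2)
            continue
        eff[k] = float(np.sum(loss[m]) * world.cell_area) / dep_kg

    region_bif = srm.fractions @ eff * conversion.value
    countries = np.arange(int(world.country_index.max()) + 1)
    return np.array([region_bif[world.region_of_country[c]] for c in countries])


#: drivers defined per land-use class in the factor set
_LU_DRIVERS = {
    Driver.HABITAT_LOSS: tuple(LANDUSE_NAMES[c] for c in LandUse if c != LandUse.NATURAL),
    Driver.FRAGMENTATION: FRAGMENTATION_BIF_CLASSES,
    Driver.DISTURBANCE: ("mine",),
}


def bif_land_use(result: EngineResult, landuse_class: str, driver: Driver,
                 group: Group) -> np.ndarray:
    """Per-country impact factor for one land-use class and direct driver.

    The class's attributed loss-area anywhere in the country is divided
    by the country's area of that class.  Habitat-loss losses occur in
    the class's own cells; mine-disturbance losses occur wherever the
    nearest disturbing feature is a mine; fragmentation losses caused by
    land use occur in the fragmented habitat and are split equally among
    the fragmenting classes present in the country.  A country without
    the class has a zero factor (the pressure is absent there).
    """
    driver = Driver(driver)
    group = Group(group)
    if landuse_class not in _LU_DRIVERS.get(driver, ()):
        raise ValueError(
            f"no {driver.value} factor is defined for land-use class "
            f"{landuse_class!r}")
    if driver in (Driver.FRAGMENTATION, Driver.DISTURBANCE) and group != Group.VERTEBRATES:
        raise ValueError(f"{driver.value} affects vertebrates only")

    world = result.world
    A = world.cell_area
    cls_code = int(LANDUSE_BY_NAME[landuse_class])
    n_countries = int(world.country_index.max()) + 1
    out = np.zeros(n_countries)

    for j in range(n_countries):
        in_j = world.country_index == j
        cls_cells = in_j & (world.landuse == cls_code)
        class_area = np.full(int(cls_cells.sum()), A)
        if class_area.size == 0:
            continue  # pressure absent: factor is zero
        if driver == Driver.HABITAT_LOSS:
            loss = result.losses.per_driver[(group, Driver.HABITAT_LOSS)]
            num = loss[cls_cells] * A
        elif driver == Driver.DISTURBANCE:
            loss = result.losses.per_driver[(group, Driver.DISTURBANCE)]
            caused = in_j & (result.distances.feature_type == FEATURE_MINE)
            num = loss[caused] * A
        else:  # fragmentation caused by land use, split among present classes
            if result.losses.fragmentation_landuse is None:
                raise ValueError("run the engine with decompose=True first")
            present = [c for c in FRAGMENTING_CLASSES
                       if np.any(in_j & (world.landuse == int(c)))]
            total = result.losses.fragmentation_landuse[in_j] * A
            num = total / len(present)
        out[j] = _exact_ratio(np.asarray(num), class_area)
    return out


def bif_roads(result: EngineResult, driver: Driver,
              group: Group = Group.VERTEBRATES) -> np.ndarray:
    """Per-country impact factor for roads (fragmentation or disturbance).

    The road-caused attributed loss-area in the country is divided by
    the country's total length of road types 1-3 (km).  Roadless
    countries have a zero factor.
    """
    driver = Driver(driver)
    if Group(group) != Group.VERTEBRATES:
        raise ValueError("road factors exist for vertebrates only")
    if driver not in (Driver.FRAGMENTATION, Driver.DISTURBANCE):
        raise ValueError("road factors cover fragmentation and disturbance only")
    world = result.world
    if np.any(result.road_length_km < 0):
        raise ValueError("negative road length")
    if driver == Driver.FRAGMENTATION:
        if result.losses.fragmentation_road is None:
            raise ValueError("run the engine with decompose=True first")
        loss = result.losses.fragmentation_road
        caused = np.ones(world.shape, dtype=bool)
    else:
        loss = result.losses.per_driver[(Group.VERTEBRATES, Driver.DISTURBANCE)]
        caused = result.distances.feature_type == FEATURE_ROAD

    n_countries = int(world.country_index.max()) + 1
    out = np.zeros(n_countries)
    for j in range(n_countries):
        rl = result.road_length_km[j] if j < len(result.road_length_km) else 0.0
        if rl <= 0.0:
            continue
        m = (world.country_index == j) & caused
        out[j] = float(np.sum(loss[m]) * world.cell_area) / rl
    return out


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def _records(country_values, pressure, landuse_class, driver, group, units):
    for j, v in enumerate(np.atleast_1d(country_values)):
        yield {
            "country": j,
            "pressure": pressure,
            "landuse_class": landuse_class or "",
            "direct_driver": driver,
            "species_group": group,
            "value": float(v),
            "units": units,
        }


def combine_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Add arithmetic-mean combined-group records to a factor table.

    For every (country, pressure, class, driver) the combined factor is
    the mean of the plant and vertebrate factors, substituting zero for
    a group the driver does not affect (e.g. vertebrates for nitrogen
    deposition, plants for fragmentation and disturbance).
    """
    keys = ["country", "pressure", "landuse_class", "direct_driver", "units"]
    base = table[table["species_group"].isin([g.value for g in Group])]
    wide = base.pivot_table(index=keys, columns="species_group", values="value",
                            fill_value=0.0, aggfunc="first")
    for g in Group:
        if g.value not in wide:
            wide[g.value] = 0.0
    combined = ((wide[Group.PLANTS.value] + wide[Group.VERTEBRATES.value]) / 2.0)
    extra = combined.reset_index().rename(columns={0: "value"})
    extra["species_group"] = "combined"
    return pd.concat([table, extra[table.columns]], ignore_index=True)


def derive_bif_table(result: EngineResult,
                     srm_nh3: SourceReceptorMatrix | None = None,
                     srm_nox: SourceReceptorMatrix | None = None,
                     constants: Constants | None = None,
                     no2_share: float = 0.90) -> pd.DataFrame:
    """Derive the full long-form factor table from one engine run.

    Emits one record per (country, pressure, land-use class, direct
    driver, species group), pressure-level ``all``-driver aggregates for
    land use and roads, and combined-group means.
    """
    constants = constants or Constants(gmti=result.world.gmti)
    rows: list[dict] = []

    for group in Group:
        v = bif_co2(result, constants, group)
        n = int(result.world.country_index.max()) + 1
        rows.extend(_records(np.full(n, v), "co2", None, Driver.CLIMATE.value,
                             group.value, UNITS_EMISSION))

    for pressure, srm in (("nh3", srm_nh3), ("nox", srm_nox)):
        if srm is None:
            continue
        conv = nicf(pressure, no2_share)
        vals = bif_nitrogen(result, srm, conv)
        rows.extend(_records(vals, pressure, None, Driver.NITROGEN.value,
                             Group.PLANTS.value, UNITS_EMISSION))

    for driver, classes in _LU_DRIVERS.items():
        groups = list(Group) if driver == Driver.HABITAT_LOSS else [Group.VERTEBRATES]
        for cls in classes:
            for group in groups:
                vals = bif_land_use(result, cls, driver, group)
                rows.extend(_records(vals, "landuse", cls, driver.value,
                                     group.value, UNITS_LANDUSE))

    for driver in (Driver.FRAGMENTATION, Driver.DISTURBANCE):
        vals = bif_roads(result, driver)
        rows.extend(_records(vals, "roads", None, driver.value,
                             Group.VERTEBRATES.value, UNITS_ROADS))

    table = pd.DataFrame(rows)

    # pressure-level aggregates (sum of the per-driver factors)
    aggs = []
    for (pressure, cls), sub in table.groupby(["pressure", "landuse_class"]):
        if pressure not in ("landuse", "roads") or sub["direct_driver"].nunique() < 2:
            continue
        for group, gsub in sub.groupby("species_group"):
            total = gsub.groupby("country")["value"].sum()
            aggs.extend(_records(total.values, pressure, cls or None, "all",
                                 group, gsub["units"].iloc[0]))
    if aggs:
        table = pd.concat([table, pd.DataFrame(aggs)], ignore_index=True)
    return combine_groups(table)
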