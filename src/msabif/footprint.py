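"""Apply impact-factor tables to inventories of emissions, land use and transport.

Emission and land-use entries multiply their matching factor directly
(units already align: kg of substance, km2 yr of occupation).  Road
impacts are attributed to actors proportionally to their share of the
region's transport fuel use:

    BF_road = BIF_road * RL * T * FU_actor / FU_region

and can alternatively be converted to per-activity factors (per ton-km
or person-km) via the activity's fuel intensity.  Greenhouse gases
other than CO2, or alternative time horizons, are handled by scaling
the default CO2 factor with a packaged conversion table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "ActorInventory",
    "RegionTransport",
    "GHGConversionTable",
    "load_default_ghg_table",
    "road_footprint_actor",
    "road_bif_activity",
    "convert_ghg",
    "total_footprint",
]


@dataclass
class RegionTransport:
    """Region-level road and transport-fuel totals.

    ``road_length_km`` is the total length of road types 1-3 in the
    region; ``fuel_total_mj`` the annual transport fuel use across all
    actors (MJ/yr); ``fuel_intensity`` the per-activity fuel intensity
    (MJ per ton-km or person-km), if a per-activity factor is wanted.
    """

    region: int
    road_length_km: float
    fuel_total_mj: float
    fuel_intensity: float | None = None

    def __post_init__(self):
        if self.road_length_km < 0:
            raise ValueError("road length must be non-negative")
        if self.fuel_total_mj < 0:
            raise ValueError("fuel use must be non-negative")


@dataclass
class ActorInventory:
    """Annual pressures of one actor (a sector or the consumers) in a region.

    ``emissions_kg`` maps substance ("co2", "nh3", "nox", or another
    greenhouse gas to be routed through the conversion table) to kg/yr;
    ``landuse_km2yr`` maps land-use class to km2 yr of occupation;
    ``transport_fuel_mj`` is the actor's direct transport fuel use.
    """

    actor: str
    region: int
    emissions_kg: dict[str, float] = field(default_factory=dict)
    landuse_km2yr: dict[str, float] = field(default_factory=dict)
    transport_fuel_mj: float = 0.0

    def __post_init__(self):
        if any(v < 0 for v in self.emissions_kg.values()):
            raise ValueError("emissions must be non-negative")
        if any(v < 0 for v in self.landuse_km2yr.values()):
            raise ValueError("land occupation must be non-negative")
        if self.transport_fuel_mj < 0:
            raise ValueError("fuel use must be non-negative")


class GHGConversionTable:
    """Multipliers on the default (CO2, 100-yr) factor per gas and horizon."""

    def __init__(self, frame: pd.DataFrame):
        self._factors: dict[tuple[str, int], float] = {}
        for _, row in frame.iterrows():
            f = float(row["factor"])
            if f <= 0:
                raise ValueError("conversion factors must be positive")
            self._factors[(str(row["gas"]), int(row["horizon_yr"]))] = f

    def factor(self, gas: str, horizon_yr: int) -> float:
        key = (gas, int(horizon_yr))
        if key not in self._factors:
            raise KeyError(f"no conversion factor for gas={gas!r}, "
                           f"horizon={horizon_yr} yr")
        return self._factors[key]

    @property
    def entries(self) -> dict[tuple[str, int], float]:
        return dict(self._factors)


def load_default_ghg_table() -> GHGConversionTable:
    """Load the packaged gas x time-horizon conversion factors."""
    with resources.files("msabif.data").joinpath("ghg_conversion.csv").open() as fh:
        return GHGConversionTable(pd.read_csv(fh))


def convert_ghg(bif_co2_default: float, gas: str, horizon_yr: int,
                table: GHGConversionTable) -> float:
    """Scale the default CO2 factor to another gas and/or time horizon."""
    return bif_co2_default * table.factor(gas, horizon_yr)


def road_footprint_actor(bif_road: float, transport: RegionTransport,
                         actor_fuel_mj: float, duration_yr: float = 1.0) -> float:
    """Road biodiversity footprint of one actor (MSA-loss km2 yr).

    The region's total road impact (factor times road length times
    duration of use) is allocated to the actor by its share of the
    region's transport fuel use.
    """
    if actor_fuel_mj < 0:
        raise ValueError("actor fuel use must be non-negative")
    if actor_fuel_mj == 0:
        return 0.0
    if transport.fuel_total_mj <= 0:
        raise ValueError("region has zero transport fuel but the actor uses fuel")
    if actor_fuel_mj > transport.fuel_total_mj * (1 + 1e-9):
        raise ValueError("actor fuel use exceeds the region total")
    return bif_road * transport.road_length_km * duration_yr \
        * actor_fuel_mj / transport.fuel_total_mj


def road_bif_activity(bif_road: float, transport: RegionTransport) -> float:
    """Per-activity road factor (MSA-loss km2 yr per ton-km or person-km)."""
    if transport.fuel_total_mj <= 0:
        raise ValueError("region transport fuel total must be positive")
    if transport.fuel_intensity is None:
        raise ValueError("transport.fuel_intensity is required")
    return bif_road * transport.road_length_km \
        * transport.fuel_intensity / transport.fuel_total_mj


def total_footprint(inventory: ActorInventory, bif_table: pd.DataFrame,
                    transport: RegionTransport | None = None,
                    species_group: str = "combined",
                    duration_yr: float = 1.0,
                    ghg_table: GHGConversionTable | None = None,
                    ghg_horizon_yr: int = 100) -> pd.DataFrame:
    """Pressure-wise and total footprint of one actor (MSA-loss km2 yr).

    Each inventory entry is multiplied with the matching factor for the
    actor's region and species group.  Emission substances other than
    co2/nh3/nox are routed through the greenhouse-gas conversion table
    (pass gases either pre-converted to CO2-equivalents under "co2" or
    by their own name with a ``ghg_table`` — never both, to avoid
    double counting).  The road part follows the fuel-share allocation.
    """
    def lookup(pressure, landuse_class=""):
        sub = bif_table[
            (bif_table["country"] == inventory.region)
            & (bif_table["pressure"] == pressure)
            & (bif_table["landuse_class"] == landuse_class)
            & (bif_table["species_group"] == species_group)
        ]
        if pressure in ("landuse", "roads"):
            agg = sub[sub["direct_driver"] == "all"]
            sub = agg if len(agg) else sub
        if len(sub) == 0:
            raise KeyError(f"no factor for region {inventory.region}, "
                           f"pressure {pressure!r}, class {landuse_class!r}, "
                           f"group {species_group!r}")
        if len(sub) > 1 and sub["direct_driver"].nunique() > 1:
            return float(sub.groupby("country")["value"].sum().iloc[0])
        return float(sub["value"].iloc[0])

    rows = []
    for substance, kg in inventory.emissions_kg.items():
        s = substance.lower()
        if s in ("co2", "nh3", "nox"):
            factor = lookup(s)
        else:
            if ghg_table is None:
                raise KeyError(
                    f"substance {substance!r} needs a GHG conversion table or "
                    "pre-conversion to CO2-equivalents")
            factor = convert_ghg(lookup("co2"), substance, ghg_horizon_yr, ghg_table)
        rows.append({"pressure": s, "quantity": kg, "footprint": kg * factor})

    for cls, km2yr in inventory.landuse_km2yr.items():
        factor = lookup("landuse", cls)
        rows.append({"pressure": f"landuse_{cls}", "quantity": km2yr,
                     "footprint": km2yr * factor})

    if inventory.transport_fuel_mj > 0:
        if transport is None:
            raise ValueError("transport totals required for a fuel-using actor")
        bif_road = lookup("roads")
        fp = road_footprint_actor(bif_road, transport,
                                  inventory.transport_fuel_mj, duration_yr)
        rows.append({"pressure": "roads", "quantity": inventory.transport_fuel_mj,
                     "footprint": fp})

    rows.append({"pressure": "total", "quantity": float("nan"),
                 "footprint": float(sum(r["footprint"] for r in rows))})
    return pd.DataFrame(rows, columns=["pressure", "quantity", "footprint"])
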