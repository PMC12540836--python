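"""Grid engine: per-cell, per-driver MSA, loss attribution and fragmentation split.

The engine evaluates every applicable (species group, direct driver)
response curve on each grid cell, multiplies the per-driver MSA values
into a combined intactness per group, and attributes the total loss
``1 - MSA`` back to the drivers proportionally to their individual
deficits.  Habitat fragmentation is further decomposed into a land-use
and a road share with a three-run procedure: one default run, one run
with roads removed and one with the fragmenting land-use barriers
removed, the full-run loss being split proportionally to the two
single-pressure losses.

Subordination rules are expressed as an applicability matrix applied
*before* both the product and the attribution, so a driver excluded in
a given land-use context contributes neither to the combined MSA nor
to the loss shares there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .impact_relationships import (
    DISTURBANCE_CUTOFF_M,
    Driver,
    Group,
    RelationshipSet,
)
from .synthetic_world import LANDUSE_NAMES, LandUse, RoadSegment, World

__all__ = [
    "DriverApplicability",
    "PatchMap",
    "DistanceField",
    "MSAStack",
    "LossStack",
    "EngineConfig",
    "EngineResult",
    "rasterize_roads",
    "compute_patches",
    "compute_disturbance_field",
    "compute_msa_stack",
    "attribute_losses",
    "decompose_fragmentation",
    "run_engine",
]

#: Feature-type codes in the disturbance distance field.
FEATURE_NONE, FEATURE_ROAD, FEATURE_MINE = 0, 1, 2

#: Road types that disturb wildlife (highways, primary, secondary).
DISTURBING_ROAD_TYPES = (1, 2, 3)

#: Land-use classes that count as habitat for patch delineation.
HABITAT_CLASSES = (LandUse.NATURAL, LandUse.PLANTATION)

#: Land-use barrier classes whose conversion fragments habitat.
FRAGMENTING_CLASSES = (LandUse.URBAN, LandUse.CROPLAND, LandUse.PASTURE)


class DriverApplicability:
    """Boolean matrix saying which driver affects which group in which land use.

    Defaults encode the subordination rules of the intactness model:

    * plants — climate everywhere; nitrogen deposition only in natural
      and plantation cells (agricultural land is fertilized anyway);
      habitat loss in the five human-use classes;
    * vertebrates — climate everywhere; habitat loss in the five
      human-use classes; disturbance everywhere except urban land;
      fragmentation in natural and plantation cells; no nitrogen.
    """

    def __init__(self, table: dict[tuple[Group, Driver], frozenset[LandUse]] | None = None):
        if table is None:
            all_classes = frozenset(LandUse)
            used = frozenset(c for c in LandUse if c != LandUse.NATURAL)
            table = {
                (Group.PLANTS, Driver.CLIMATE): all_classes,
                (Group.PLANTS, Driver.NITROGEN): frozenset(HABITAT_CLASSES),
                (Group.PLANTS, Driver.HABITAT_LOSS): used,
                (Group.VERTEBRATES, Driver.CLIMATE): all_classes,
                (Group.VERTEBRATES, Driver.HABITAT_LOSS): used,
                (Group.VERTEBRATES, Driver.DISTURBANCE): all_classes - {LandUse.URBAN},
                (Group.VERTEBRATES, Driver.FRAGMENTATION): frozenset(HABITAT_CLASSES),
            }
        self.table = {k: frozenset(v) for k, v in table.items()}

    def drivers_for(self, group: Group) -> list[Driver]:
        return [d for (g, d) in self.table if g == group]

    def mask(self, group: Group, driver: Driver, landuse: np.ndarray) -> np.ndarray:
        """Boolean per-cell mask of where the driver applies."""
        classes = self.table.get((Group(group), Driver(driver)), frozenset())
        if not classes:
            return np.zeros(landuse.shape, dtype=bool)
        return np.isin(landuse, [int(c) for c in classes])


@dataclass
class PatchMap:
    """Connected components of habitat cells and their sizes.

    ``labels`` holds a patch id per cell (0 = matrix/barrier);
    ``sizes_ha`` maps patch id to its area in hectares.  ``bounded``
    flags patches that touch at least one barrier cell: a patch whose
    only boundary is the domain edge is a window into an unbounded
    landscape and counts as unfragmented (effective size infinite).
    """

    labels: np.ndarray
    sizes_ha: np.ndarray   # indexed by patch id; entry 0 unused
    bounded: np.ndarray    # indexed by patch id; entry 0 unused

    @property
    def n_patches(self) -> int:
        return len(self.sizes_ha) - 1

    def patch_size_of_cell(self) -> np.ndarray:
        """Per-cell patch size in ha (0 for matrix cells)."""
        return self.sizes_ha[self.labels]

    def effective_size_of_cell(self) -> np.ndarray:
        """Per-cell size used by the fragmentation curve (inf if unbounded)."""
        eff = np.where(self.bounded, self.sizes_ha, np.inf)
        eff[0] = 0.0
        return eff[self.labels]


@dataclass
class DistanceField:
    """Distance (m) to the nearest disturbing feature and its type.

    Cells with no feature within the impact cutoff carry ``inf`` and
    feature type ``FEATURE_NONE``.  Ties between an equidistant road
    and mine are broken toward the mine.
    """

    distance_m: np.ndarray
    feature_type: np.ndarray  # FEATURE_NONE | FEATURE_ROAD | FEATURE_MINE
    cutoff_m: float


@dataclass
class MSAStack:
    """Per-driver and combined MSA per species group."""

    per_driver: dict[tuple[Group, Driver], np.ndarray]
    combined: dict[Group, np.ndarray]

    def drivers(self, group: Group) -> list[Driver]:
        return [d for (g, d) in self.per_driver if g == group]


@dataclass
class LossStack:
    """Attributed per-driver MSA losses (and the fragmentation split).

    ``fragmentation_landuse`` / ``fragmentation_road`` are only present
    after :func:`decompose_fragmentation` has been applied.
    """

    per_driver: dict[tuple[Group, Driver], np.ndarray]
    total: dict[Group, np.ndarray]
    fragmentation_landuse: np.ndarray | None = None
    fragmentation_road: np.ndarray | None = None


@dataclass
class EngineConfig:
    """Numerical and topological choices of the grid engine."""

    connectivity: int = 8            # patch connectivity: 4 or 8
    cutoff_m: float = DISTURBANCE_CUTOFF_M
    d_min_m: float | None = None     # distance floor; default half a cell width

    def __post_init__(self):
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class EngineResult:
    """Everything one engine run produces, ready for factor derivation."""

    world: World
    stack: MSAStack
    losses: LossStack
    patches: PatchMap
    distances: DistanceField
    road_mask: np.ndarray
    road_length_km: np.ndarray  # per country
    config: EngineConfig


# ---------------------------------------------------------------------------
# road rasterization
# ---------------------------------------------------------------------------

def _segment_pieces(p, q, cell_w: float, shape):
    """Split segment p->q (km coords) at grid lines.

    Yields ``(row, col, length_km)`` for each piece, the owning cell
    taken from the piece midpoint (floor convention on boundaries).
    """
    (x0, y0), (x1, y1) = p, q
    dx, dy = x1 - x0, y1 - y0
    length = math.hypot(dx, dy)
    if length == 0.0:
        return
    ts = {0.0, 1.0}
    if dx != 0.0:
        for k in range(int(math.ceil(min(x0, x1) / cell_w)), int(math.floor(max(x0, x1) / cell_w)) + 1):
            t = (k * cell_w - x0) / dx
            if 0.0 < t < 1.0:
                ts.add(t)
    if dy != 0.0:
        for k in range(int(math.ceil(min(y0, y1) / cell_w)), int(math.floor(max(y0, y1) / cell_w)) + 1):
            t = (k * cell_w - y0) / dy
            if 0.0 < t < 1.0:
                ts.add(t)
    ts = sorted(ts)
    for ta, tb in zip(ts[:-1], ts[1:]):
        plen = (tb - ta) * length
        if plen <= 1e-12:
            continue
        tm = 0.5 * (ta + tb)
        col = int((x0 + tm * dx) / cell_w)
        row = int((y0 + tm * dy) / cell_w)
        row = min(max(row, 0), shape[0] - 1)
        col = min(max(col, 0), shape[1] - 1)
        yield row, col, plen


def rasterize_roads(roads: list[RoadSegment], shape: tuple[int, int],
                    cell_width_km: float, country_index: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize the disturbing road network (types 1-3).

    Returns a boolean per-cell road-presence mask and the total
    geometric road length (km) per country.  A cell is a road cell iff
    a type 1-3 polyline crosses it with positive length; lengths are
    attributed to the country of the cell each piece lies in, so no
    length is counted twice at cell boundaries.  Types 4 and 5 (minor
    roads) are ignored: they are much less disturbing to wildlife.
    """
    road_mask = np.zeros(shape, dtype=bool)
    lengths = np.zeros(int(country_index.max()) + 1)
    for seg in roads:
        if seg.road_type not in (1, 2, 3, 4, 5):
            raise ValueError(f"unknown road type {seg.road_type}")
        if seg.road_type not in DISTURBING_ROAD_TYPES:
            continue
        coords = list(seg.geometry.coords)
        for p, q in zip(coords[:-1], coords[1:]):
            for row, col, plen in _segment_pieces(p, q, cell_width_km, shape):
                road_mask[row, col] = True
                lengths[country_index[row, col]] += plen
    return road_mask, lengths


# ---------------------------------------------------------------------------
# patches and distances
# ---------------------------------------------------------------------------

def compute_patches(landuse: np.ndarray, road_mask: np.ndarray,
                    cell_area_km2: float, connectivity: int = 8,
                    habitat_classes=HABITAT_CLASSES) -> PatchMap:
    """Label connected natural-habitat patches.

    Habitat cells are those with a habitat land-use class (natural and
    plantation by default) that are not road cells; all other cells are
    barriers.  Components are labelled under 4- or 8-connectivity and
    sized in hectares (1 km2 = 100 ha).  A patch is *bounded* if any of
    its cells is 8-adjacent to a barrier cell; a patch fenced only by
    the domain edge is treated as part of an unbounded landscape.
    """
    habitat = np.isin(landuse, [int(c) for c in habitat_classes]) & ~road_mask
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(habitat, structure=structure)
    counts = np.bincount(labels.ravel(), minlength=n + 1).astype(float)
    sizes_ha = counts * cell_area_km2 * 100.0
    sizes_ha[0] = 0.0
    near_barrier = ndimage.binary_dilation(
        ~habitat, structure=ndimage.generate_binary_structure(2, 2))
    touching = np.unique(labels[habitat & near_barrier])
    bounded = np.zeros(n + 1, dtype=bool)
    bounded[touching[touching > 0]] = True
    return PatchMap(labels=labels, sizes_ha=sizes_ha, bounded=bounded)


def compute_disturbance_field(road_mask: np.ndarray, mine_mask: np.ndarray,
                              cell_width_km: float,
                              cutoff_m: float = DISTURBANCE_CUTOFF_M,
                              d_min_m: float | None = None) -> DistanceField:
    """Euclidean distance to the nearest road or mine cell, with its type.

    Distances are centre-to-centre between cells; cells on a feature
    get the floor distance ``d_min_m`` (default half a cell width, the
    expected distance from a random point in a cell to its own centre
    scale).  Beyond ``cutoff_m`` the distance is infinite and the type
    is ``FEATURE_NONE``.  An exact tie between road and mine goes to
    the mine.
    """
    cell_m = cell_width_km * 1000.0
    if d_min_m is None:
        d_min_m = cell_m / 2.0
    shape = road_mask.shape

    def _dist(mask):
        if not mask.any():
            return np.full(shape, np.inf)
        return ndimage.distance_transform_edt(~mask) * cell_m

    d_road = _dist(road_mask)
    d_mine = _dist(mine_mask)
    use_mine = d_mine <= d_road  # tie -> mine
    distance = np.where(use_mine, d_mine, d_road)
    ftype = np.where(use_mine, FEATURE_MINE, FEATURE_ROAD)
    beyond = distance > cutoff_m
    distance = np.where(beyond, np.inf, np.maximum(distance, d_min_m))
    ftype = np.where(beyond, FEATURE_NONE, ftype)
    return DistanceField(distance_m=distance, feature_type=ftype, cutoff_m=cutoff_m)


# ---------------------------------------------------------------------------
# MSA stack and loss attribution
# ---------------------------------------------------------------------------

def compute_msa_stack(world: World, relationships: RelationshipSet,
                      applicability: DriverApplicability,
                      patches: PatchMap, distances: DistanceField,
                      d_min_m: float | None = None) -> MSAStack:
    """Evaluate every applicable (group, driver) curve per cell and combine.

    Where a driver does not apply (subordination, or no feature in
    range) its layer is exactly 1, so it drops out of both the product
    and the subsequent loss attribution.
    """
    shape = world.shape
    lu = world.landuse
    if d_min_m is None:
        d_min_m = world.cell_width_km * 1000.0 / 2.0
    per_driver: dict[tuple[Group, Driver], np.ndarray] = {}
    combined: dict[Group, np.ndarray] = {}

    for group in Group:
        drivers = applicability.drivers_for(group)
        prod = np.ones(shape)
        for driver in drivers:
            layer = np.ones(shape)
            mask = applicability.mask(group, driver, lu)
            if driver == Driver.CLIMATE:
                layer[mask] = relationships.msa_climate(group, world.gmti)
            elif driver == Driver.NITROGEN:
                layer[mask] = relationships.msa_nitrogen(group, world.deposition[mask])
            elif driver == Driver.HABITAT_LOSS:
                for cls in LandUse:
                    if cls == LandUse.NATURAL:
                        continue
                    cls_mask = mask & (lu == int(cls))
                    if cls_mask.any():
                        layer[cls_mask] = relationships.msa_habitat_loss(
                            group, LANDUSE_NAMES[cls])
            elif driver == Driver.FRAGMENTATION:
                fmask = mask & (patches.labels > 0)
                if fmask.any():
                    sizes = patches.effective_size_of_cell()[fmask]
                    layer[fmask] = relationships.msa_fragmentation(group, sizes)
            elif driver == Driver.DISTURBANCE:
                dmask = mask & (distances.feature_type != FEATURE_NONE)
                if dmask.any():
                    layer[dmask] = relationships.msa_disturbance(
                        group, distances.distance_m[dmask],
                        cutoff_m=distances.cutoff_m, d_min=d_min_m)
            else:  # pragma: no cover - enum is closed
                raise ValueError(f"unhandled driver {driver}")
            per_driver[(group, driver)] = layer
            prod = prod * layer
        combined[group] = prod
    return MSAStack(per_driver=per_driver, combined=combined)


def attribute_losses(stack: MSAStack) -> LossStack:
    """Attribute the total loss ``1 - MSA`` to drivers by their deficits.

    Each driver's share is its own deficit ``1 - MSA_x`` over the sum of
    all deficits, scaled by the combined loss.  Cells where no driver is
    active (all per-driver MSA = 1) get zero losses.
    """
    per_driver: dict[tuple[Group, Driver], np.ndarray] = {}
    total: dict[Group, np.ndarray] = {}
    for group, comb in stack.combined.items():
        deficits = {d: 1.0 - stack.per_driver[(group, d)] for d in stack.drivers(group)}
        denom = np.zeros_like(comb)
        for d in deficits.values():
            denom = denom + d
        total_loss = 1.0 - comb
        safe = np.where(denom > 0.0, denom, 1.0)
        for driver, deficit in deficits.items():
            loss = np.where(denom > 0.0, deficit / safe * total_loss, 0.0)
            per_driver[(group, driver)] = loss
        total[group] = total_loss
    return LossStack(per_driver=per_driver, total=total)


# ---------------------------------------------------------------------------
# fragmentation decomposition (three-run procedure)
# ---------------------------------------------------------------------------

def _fragmentation_loss(world: World, relationships: RelationshipSet,
                        applicability: DriverApplicability,
                        patches: PatchMap, distances: DistanceField,
                        d_min_m: float | None) -> np.ndarray:
    stack = compute_msa_stack(world, relationships, applicability,
                              patches, distances, d_min_m)
    losses = attribute_losses(stack)
    key = (Group.VERTEBRATES, Driver.FRAGMENTATION)
    return losses.per_driver.get(key, np.zeros(world.shape))


def decompose_fragmentation(world: World, relationships: RelationshipSet,
                            applicability: DriverApplicability,
                            road_mask: np.ndarray, distances: DistanceField,
                            config: EngineConfig,
                            full_loss: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split the full-run fragmentation loss into land-use and road shares.

    Two single-pressure runs are performed: one with the road barriers
    removed (land-use-only fragmentation) and one with the urban,
    cropland and pasture barriers treated as habitat (road-only
    fragmentation; mines stay barriers as they destroy habitat
    outright).  A finite grid carries a residual fragmentation signal
    even with no barriers at all (patches cannot exceed the domain), so
    a no-barrier baseline run is subtracted from both single-pressure
    losses before the split; on a global grid this baseline vanishes
    (continent-sized patches), on a bounded synthetic world it keeps a
    pressure that is absent from receiving any share.  Per cell, the
    full-run loss L is split proportionally to the excess single-run
    losses; if both excesses are zero where L > 0 the split falls back
    to 50/50 with a warning.
    """
    no_roads = compute_patches(world.landuse, np.zeros_like(road_mask),
                               world.cell_area, config.connectivity)
    lu_only = _fragmentation_loss(world, relationships, applicability,
                                  no_roads, distances, config.d_min_m)

    open_classes = tuple(HABITAT_CLASSES) + tuple(FRAGMENTING_CLASSES)
    no_landuse = compute_patches(world.landuse, road_mask, world.cell_area,
                                 config.connectivity, habitat_classes=open_classes)
    road_only = _fragmentation_loss(world, relationships, applicability,
                                    no_landuse, distances, config.d_min_m)

    baseline_patches = compute_patches(world.landuse, np.zeros_like(road_mask),
                                       world.cell_area, config.connectivity,
                                       habitat_classes=open_classes)
    baseline = _fragmentation_loss(world, relationships, applicability,
                                   baseline_patches, distances, config.d_min_m)
    lu_only = np.maximum(lu_only - baseline, 0.0)
    road_only = np.maximum(road_only - baseline, 0.0)

    denom = lu_only + road_only
    active = full_loss > 0.0
    degenerate = active & (denom <= 0.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} cells have fragmentation loss but no "
            "single-pressure signal; splitting 50/50 between land use and roads",
            RuntimeWarning, stacklevel=2)
    safe = np.where(denom > 0.0, denom, 1.0)
    share_lu = np.where(denom > 0.0, lu_only / safe, 0.5)
    lu_split = np.where(active, full_loss * share_lu, 0.0)
    road_split = np.where(active, full_loss - lu_split, 0.0)
    return lu_split, road_split


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_engine(world: World, relationships: RelationshipSet,
               applicability: DriverApplicability | None = None,
               config: EngineConfig | None = None,
               decompose: bool = True) -> EngineResult:
    """Run the full per-cell pipeline on a world.

    Rasterizes roads, labels habitat patches, builds the disturbance
    distance field, evaluates the MSA stack, attributes losses and
    (optionally) decomposes the fragmentation loss into land-use and
    road shares.
    """
    world.validate()
    applicability = applicability or DriverApplicability()
    config = config or EngineConfig()
    road_mask, road_lengths = rasterize_roads(
        world.roads, world.shape, world.cell_width_km, world.country_index)
    patches = compute_patches(world.landuse, road_mask, world.cell_area,
                              config.connectivity)
    distances = compute_disturbance_field(road_mask, world.mine_mask,
                                          world.cell_width_km, config.cutoff_m,
                                          config.d_min_m)
    stack = compute_msa_stack(world, relationships, applicability,
                              patches, distances, config.d_min_m)
    losses = attribute_losses(stack)
    if decompose:
        key = (Group.VERTEBRATES, Driver.FRAGMENTATION)
        full = losses.per_driver.get(key, np.zeros(world.shape))
        lu_split, road_split = decompose_fragmentation(
            world, relationships, applicability, road_mask, distances,
            config, full)
        losses.fragmentation_landuse = lu_split
        losses.fragmentation_road = road_split
    return EngineResult(world=world, stack=stack, losses=losses,
                        patches=patches, distances=distances,
                        road_mask=road_mask, road_length_km=road_lengths,
                        config=config)
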