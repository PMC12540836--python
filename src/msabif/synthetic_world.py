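"""Reproducible synthetic gridded worlds for intactness modelling.

A :class:`World` bundles the co-registered layers the MSA engine needs:
a categorical land-use grid, a smooth non-negative nitrogen-deposition
field (kg N ha-1 yr-1), a vector road network with road types 1-5, a
mine mask, a country index and a uniform cell area, plus the scalar
global mean temperature increase (GMTI, degC).

Worlds are abstract equal-area grids: the cell width is
``sqrt(cell_area)`` km and road geometry lives in km coordinates with
the origin at the top-left corner (x to the right along columns, y
downward along rows).

All randomness flows from a single seed through named substreams, so a
spec generates the same world bit-for-bit every time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString

__all__ = [
    "LandUse",
    "WorldSpec",
    "World",
    "RoadSegment",
    "SourceReceptorMatrix",
    "EmissionInventory",
    "generate_world",
    "generate_srm",
    "generate_emissions",
]


class LandUse(IntEnum):
    """Per-cell land-use class."""

    NATURAL = 0
    CROPLAND = 1
    PASTURE = 2
    PLANTATION = 3
    URBAN = 4
    MINE = 5


#: Human-readable names used in tables and CSV output.
LANDUSE_NAMES = {
    LandUse.NATURAL: "natural",
    LandUse.CROPLAND: "cropland",
    LandUse.PASTURE: "pasture",
    LandUse.PLANTATION: "plantation",
    LandUse.URBAN: "urban",
    LandUse.MINE: "mine",
}
LANDUSE_BY_NAME = {v: k for k, v in LANDUSE_NAMES.items()}

#: Classes with a habitat-loss relationship (all human uses).
USED_CLASSES = (LandUse.CROPLAND, LandUse.PASTURE, LandUse.PLANTATION,
                LandUse.URBAN, LandUse.MINE)


@dataclass(frozen=True)
class RoadSegment:
    """A road polyline with its GRIP-style type (1-5).

    Only types 1-3 (highways, primary and secondary roads) disturb
    wildlife in the engine; types 4-5 are carried through untouched.
    """

    road_type: int
    geometry: LineString

    def __post_init__(self):
        if self.road_type not in (1, 2, 3, 4, 5):
            raise ValueError(f"unknown road type {self.road_type}; expected 1-5")


@dataclass
class WorldSpec:
    """Parameters controlling world generation.

    ``landuse_fractions`` are sampling proportions over the non-mine
    classes (mines are placed afterwards as ``n_mines`` single cells).
    ``road_density`` maps road type (1-5) to the expected number of road
    segments per country.  ``deposition_params`` is ``(mean, scale)``:
    the target mean deposition in kg N ha-1 yr-1 and the spatial
    correlation scale in cells.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_area: float = 1.0  # km2 per cell
    n_countries: int = 4
    region_of_country: dict[int, int] | None = None
    landuse_fractions: dict[str, float] = field(default_factory=lambda: {
        "natural": 0.60, "cropland": 0.15, "pasture": 0.10,
        "plantation": 0.10, "urban": 0.05,
    })
    road_density: dict[int, float] = field(default_factory=lambda: {
        1: 1.0, 2: 2.0, 3: 3.0, 4: 1.0, 5: 1.0,
    })
    n_mines: int = 4
    deposition_params: tuple[float, float] = (5.0, 5.0)
    gmti: float = 1.26
    seed: int = 0
    country_layout: str = "blocks"  # "blocks" | "voronoi"

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if self.n_countries < 1:
            raise ValueError("n_countries must be positive")
        if self.n_mines < 0:
            raise ValueError("n_mines must be non-negative")
        if self.gmti < 0:
            raise ValueError("gmti must be non-negative")
        fr = self.landuse_fractions
        if any(v < 0 for v in fr.values()):
            raise ValueError("land-use fractions must be non-negative")
        if not math.isclose(sum(fr.values()), 1.0, abs_tol=1e-9):
            raise ValueError("land-use fractions must sum to 1")
        unknown = set(fr) - set(LANDUSE_BY_NAME)
        if unknown:
            raise ValueError(f"unknown land-use classes: {sorted(unknown)}")
        if self.region_of_country is None:
            # default: every country is its own region
            self.region_of_country = {c: c for c in range(self.n_countries)}
        if set(self.region_of_country) != set(range(self.n_countries)):
            raise ValueError("region_of_country must map every country exactly once")


@dataclass
class World:
    """Co-registered synthetic input layers plus the warming scalar."""

    landuse: np.ndarray          # (rows, cols) int, LandUse codes
    deposition: np.ndarray       # (rows, cols) float, kg N ha-1 yr-1
    roads: list[RoadSegment]
    country_index: np.ndarray    # (rows, cols) int
    cell_area: float             # km2, uniform
    gmti: float                  # degC
    region_of_country: dict[int, int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.landuse.shape

    @property
    def cell_width_km(self) -> float:
        return math.sqrt(self.cell_area)

    @property
    def n_countries(self) -> int:
        return int(self.country_index.max()) + 1

    @property
    def mine_mask(self) -> np.ndarray:
        return self.landuse == int(LandUse.MINE)

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        if self.landuse.shape != self.deposition.shape or \
                self.landuse.shape != self.country_index.shape:
            raise ValueError("layer shapes differ")
        if np.any(self.deposition < 0):
            raise ValueError("deposition must be non-negative everywhere")
        if not np.isin(self.landuse, [int(c) for c in LandUse]).all():
            raise ValueError("unknown land-use code in grid")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        countries = np.unique(self.country_index)
        missing = set(countries.tolist()) - set(self.region_of_country)
        if missing:
            raise ValueError(f"countries without a region: {sorted(missing)}")


@dataclass
class SourceReceptorMatrix:
    """Fraction of an emitted nitrogen substance deposited per receiving region.

    Rows are emitting regions, columns receiving regions.  Rows are
    substochastic: the remainder of each row deposits outside the
    modelled land surface (oceans).
    """

    substance: str               # "NH3" | "NOx"
    fractions: np.ndarray        # (n_regions, n_regions)

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 2 or f.shape[0] != f.shape[1]:
            raise ValueError("fractions must be a square matrix")
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(f.sum(axis=1) > 1 + 1e-12):
            raise ValueError("row sums must not exceed 1")
        self.fractions = f

    @property
    def n_regions(self) -> int:
        return self.fractions.shape[0]


@dataclass
class EmissionInventory:
    """Per-region annual emission totals of one nitrogen substance (kg/yr)."""

    substance: str
    totals: np.ndarray  # (n_regions,) kg/yr

    def __post_init__(self):
        t = np.asarray(self.totals, dtype=float)
        if np.any(t < 0):
            raise ValueError("emission totals must be non-negative")
        self.totals = t


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

_SUBSTREAMS = {"country": 0, "landuse": 1, "mines": 2, "roads": 3,
               "deposition": 4, "srm": 5, "emissions": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[stream],)))


def _block_layout(n_countries: int, n_rows: int, n_cols: int) -> np.ndarray:
    """Partition the grid into contiguous rectangular country blocks."""
    br = int(math.floor(math.sqrt(n_countries)))
    while n_countries % br:
        br -= 1
    bc = n_countries // br
    row_edges = np.linspace(0, n_rows, br + 1).astype(int)
    col_edges = np.linspace(0, n_cols, bc + 1).astype(int)
    idx = np.empty((n_rows, n_cols), dtype=np.int64)
    cid = 0
    for i in range(br):
        for j in range(bc):
            idx[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = cid
            cid += 1
    return idx


def _voronoi_layout(n_countries: int, n_rows: int, n_cols: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Assign each cell to the nearest of random country centres."""
    centres = np.column_stack([rng.uniform(0, n_rows, n_countries),
                               rng.uniform(0, n_cols, n_countries)])
    rr, cc = np.meshgrid(np.arange(n_rows) + 0.5, np.arange(n_cols) + 0.5, indexing="ij")
    d2 = (rr[..., None] - centres[:, 0]) ** 2 + (cc[..., None] - centres[:, 1]) ** 2
    return np.argmin(d2, axis=-1).astype(np.int64)


def _country_bbox_km(country_index: np.ndarray, country: int, cell_w: float):
    rows, cols = np.where(country_index == country)
    return (cols.min() * cell_w, rows.min() * cell_w,
            (cols.max() + 1) * cell_w, (rows.max() + 1) * cell_w)


def generate_world(spec: WorldSpec) -> World:
    """Generate a :class:`World` from a :class:`WorldSpec`.

    Land-use classes are sampled independently per cell from the spec
    fractions; mines are then placed on ``n_mines`` distinct random
    cells.  Roads are straight two-point polylines drawn inside each
    country's bounding box, with per-type segment counts Poisson
    distributed around the spec's densities.  Deposition is a Gaussian-
    smoothed exponential noise field rescaled to the requested mean.
    """
    shape = (spec.n_rows, spec.n_cols)
    cell_w = math.sqrt(spec.cell_area)

    if spec.country_layout == "voronoi":
        country_index = _voronoi_layout(spec.n_countries, *shape, _rng(spec.seed, "country"))
    elif spec.country_layout == "blocks":
        country_index = _block_layout(spec.n_countries, *shape)
    else:
        raise ValueError(f"unknown country_layout {spec.country_layout!r}")

    # categorical land use
    classes = sorted(spec.landuse_fractions, key=lambda n: int(LANDUSE_BY_NAME[n]))
    probs = np.array([spec.landuse_fractions[c] for c in classes])
    codes = np.array([int(LANDUSE_BY_NAME[c]) for c in classes])
    lu_rng = _rng(spec.seed, "landuse")
    landuse = codes[lu_rng.choice(len(codes), size=shape, p=probs / probs.sum())]

    # mines overwrite n_mines distinct cells
    if spec.n_mines:
        if spec.n_mines > landuse.size:
            raise ValueError("n_mines exceeds number of grid cells")
        flat = _rng(spec.seed, "mines").choice(landuse.size, size=spec.n_mines, replace=False)
        landuse.flat[flat] = int(LandUse.MINE)

    # roads: straight segments inside each country's bounding box
    road_rng = _rng(spec.seed, "roads")
    roads: list[RoadSegment] = []
    for country in range(spec.n_countries):
        x0, y0, x1, y1 = _country_bbox_km(country_index, country, cell_w)
        for rtype in sorted(spec.road_density):
            lam = spec.road_density[rtype]
            if lam < 0:
                raise ValueError("road density must be non-negative")
            for _ in range(road_rng.poisson(lam)):
                p = road_rng.uniform([x0, y0], [x1, y1])
                q = road_rng.uniform([x0, y0], [x1, y1])
                if np.allclose(p, q):
                    continue
                roads.append(RoadSegment(rtype, LineString([p, q])))

    # smooth non-negative deposition field
    mean, corr = spec.deposition_params
    if mean < 0:
        raise ValueError("deposition mean must be non-negative")
    if mean == 0:
        deposition = np.zeros(shape)
    else:
        noise = _rng(spec.seed, "deposition").exponential(1.0, size=shape)
        deposition = ndimage.gaussian_filter(noise, sigma=corr, mode="reflect")
        deposition *= mean / deposition.mean()

    world = World(
        landuse=landuse,
        deposition=deposition,
        roads=roads,
        country_index=country_index,
        cell_area=spec.cell_area,
        gmti=spec.gmti,
        region_of_country=dict(spec.region_of_country),
    )
    world.validate()
    return world


def generate_srm(n_regions: int, self_fraction: float = 0.5,
                 seed: int = 0) -> SourceReceptorMatrix:
    """Generate a substochastic source-receptor matrix.

    Diagonal entries equal ``self_fraction`` (deposition within the
    emitting region's own territory).  The off-diagonal mass is a random
    share of the remaining budget, spread randomly over the other
    regions; the residual deposits outside the modelled land (oceans).
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if not 0.0 <= self_fraction <= 1.0:
        raise ValueError("self_fraction must lie in [0, 1]")
    rng = _rng(seed, "srm")
    f = np.zeros((n_regions, n_regions))
    np.fill_diagonal(f, self_fraction)
    if n_regions > 1:
        for j in range(n_regions):
            budget = (1.0 - self_fraction) * rng.uniform(0.5, 1.0)
            w = rng.uniform(0.0, 1.0, n_regions - 1)
            w = budget * w / w.sum()
            f[j, np.arange(n_regions) != j] = w
    return SourceReceptorMatrix(substance="NH3", fractions=f)


def generate_emissions(substance: str, n_regions: int, mean_kg: float = 1e8,
                       seed: int = 0) -> EmissionInventory:
    """Generate lognormal per-region annual emission totals (kg/yr)."""
    if mean_kg < 0:
        raise ValueError("mean emission must be non-negative")
    rng = _rng(seed, "emissions")
    totals = rng.lognormal(mean=0.0, sigma=0.5, size=n_regions)
    totals *= mean_kg / totals.mean() if mean_kg > 0 else 0.0
    return EmissionInventory(substance=substance, totals=totals)
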