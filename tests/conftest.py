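import numpy as np
import pytest

from msabif import (
    RelationshipSet,
    World,
    WorldSpec,
    generate_world,
    load_default_relationships,
)


@pytest.fixture(scope="session")
def relationships() -> RelationshipSet:
    return load_default_relationships()


@pytest.fixture
def small_world() -> World:
    """A 30x30, 2-country world with all pressures present."""
    return generate_world(WorldSpec(n_rows=30, n_cols=30, n_countries=2,
                                    n_mines=2, seed=11))


def make_world(landuse, country_index=None, roads=(), deposition=None,
               cell_area=1.0, gmti=0.0, region_of_country=None) -> World:
    """Hand-build a world from explicit layers (defaults: one country, no N)."""
    landuse = np.asarray(landuse, dtype=np.int64)
    if country_index is None:
        country_index = np.zeros_like(landuse)
    country_index = np.asarray(country_index, dtype=np.int64)
    if deposition is None:
        deposition = np.zeros(landuse.shape, dtype=float)
    if region_of_country is None:
        region_of_country = {int(c): int(c) for c in np.unique(country_index)}
    return World(landuse=landuse, deposition=np.asarray(deposition, dtype=float),
                 roads=list(roads), country_index=country_index,
                 cell_area=cell_area, gmti=gmti,
                 region_of_country=region_of_country)
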