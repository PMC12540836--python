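"""Engine correctness against independent oracles and hand arithmetic."""


import numpy as np
import pytest
from shapely.geometry import LineString, box

from msabif import (
    Driver,
    DriverApplicability,
    Group,
    LandUse,
    RoadSegment,
    WorldSpec,
    attribute_losses,
    compute_disturbance_field,
    compute_patches,
    generate_world,
    rasterize_roads,
    run_engine,
)
from msabif.globio_engine import (
    FEATURE_MINE,
    FEATURE_NONE,
    FEATURE_ROAD,
    EngineConfig,
)

from conftest import make_world

NAT, CROP, PAST, PLANT, URB, MINE = (int(c) for c in LandUse)


# ---------------------------------------------------------------------------
# road rasterization
# ---------------------------------------------------------------------------

def test_single_horizontal_segment_length():
    country = np.zeros((10, 12), dtype=np.int64)
    seg = RoadSegment(2, LineString([(0.5, 3.5), (10.5, 3.5)]))  # 10 km
    mask, lengths = rasterize_roads([seg], (10, 12), 1.0, country)
    assert lengths[0] == pytest.approx(10.0, abs=1e-12)
    assert np.array_equal(np.where(mask.any(axis=1))[0], [3])
    assert mask[3, :11].all() and not mask[3, 11]


def test_minor_road_types_are_ignored():
    country = np.zeros((10, 12), dtype=np.int64)
    for rtype in (4, 5):
        seg = RoadSegment(rtype, LineString([(0.5, 3.5), (10.5, 3.5)]))
        mask, lengths = rasterize_roads([seg], (10, 12), 1.0, country)
        assert not mask.any()
        assert lengths[0] == 0.0


def test_diagonal_segment_matches_box_intersection_oracle():
    rng = np.random.default_rng(17)
    shape, w = (3, 3), 1.0
    for _ in range(20):
        p = tuple(rng.uniform(0.05, 2.95, 2))
        q = tuple(rng.uniform(0.05, 2.95, 2))
        seg = RoadSegment(1, LineString([p, q]))
        mask, _ = rasterize_roads([seg], shape, w, np.zeros(shape, dtype=np.int64))
        oracle = np.zeros(shape, dtype=bool)
        for r in range(3):  # brute-force positive-length overlap per cell box
            for c in range(3):
                cell = box(c * w, r * w, (c + 1) * w, (r + 1) * w)
                oracle[r, c] = seg.geometry.intersection(cell).length > 1e-9
        assert np.array_equal(mask, oracle)


def test_cross_border_length_split_between_countries():
    country = np.zeros((4, 10), dtype=np.int64)
    country[:, 5:] = 1
    seg = RoadSegment(3, LineString([(2.0, 1.5), (8.0, 1.5)]))
    _, lengths = rasterize_roads([seg], (4, 10), 1.0, country)
    assert lengths[0] == pytest.approx(3.0, abs=1e-12)
    assert lengths[1] == pytest.approx(3.0, abs=1e-12)


def test_unknown_road_type_rejected():
    with pytest.raises(ValueError):
        RoadSegment(7, LineString([(0, 0), (1, 1)]))


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

def test_uniform_natural_grid_is_one_patch():
    lu = np.full((10, 10), NAT)
    patches = compute_patches(lu, np.zeros((10, 10), dtype=bool), cell_area_km2=0.01)
    assert patches.n_patches == 1
    assert patches.sizes_ha[1] == pytest.approx(100.0)  # 100 cells x 1 ha


def test_full_width_road_row_bisects_habitat():
    lu = np.full((10, 10), NAT)
    road = np.zeros((10, 10), dtype=bool)
    road[5, :] = True
    patches = compute_patches(lu, road, cell_area_km2=1.0)
    assert patches.n_patches == 2


def flood_fill_labels(habitat: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent BFS component labelling."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    labels = np.zeros(habitat.shape, dtype=int)
    nxt = 0
    for r in range(habitat.shape[0]):
        for c in range(habitat.shape[1]):
            if habitat[r, c] and labels[r, c] == 0:
                nxt += 1
                queue = [(r, c)]
                labels[r, c] = nxt
                while queue:
                    rr, cc = queue.pop()
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < habitat.shape[0] and 0 <= nc < habitat.shape[1] \
                                and habitat[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = nxt
                            queue.append((nr, nc))
    return labels


@pytest.mark.parametrize("connectivity", [4, 8])
def test_patch_labels_match_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(23)
    for _ in range(5):
        lu = rng.choice([NAT, CROP, PLANT, URB, MINE], size=(20, 20),
                        p=[0.4, 0.2, 0.2, 0.1, 0.1])
        road = rng.random((20, 20)) < 0.05
        patches = compute_patches(lu, road, 1.0, connectivity)
        habitat = np.isin(lu, [NAT, PLANT]) & ~road
        oracle = flood_fill_labels(habitat, connectivity)
        # same partition: label arrays agree up to renumbering
        assert (patches.labels > 0).tolist() == (oracle > 0).tolist()
        pairs = {(int(a), int(b)) for a, b in
                 zip(patches.labels[habitat], oracle[habitat])}
        assert len(pairs) == len({a for a, _ in pairs}) == len({b for _, b in pairs})
        for pid in range(1, patches.n_patches + 1):
            assert patches.sizes_ha[pid] == np.sum(patches.labels == pid) * 100.0


# ---------------------------------------------------------------------------
# disturbance distances
# ---------------------------------------------------------------------------

def test_distance_three_cells_from_road():
    road = np.zeros((1, 8), dtype=bool)
    road[0, 0] = True
    field = compute_disturbance_field(road, np.zeros_like(road), cell_width_km=0.3)
    assert field.distance_m[0, 3] == pytest.approx(900.0)
    assert field.feature_type[0, 3] == FEATURE_ROAD


def test_equidistant_tie_broken_to_mine():
    road = np.zeros((1, 5), dtype=bool)
    mine = np.zeros((1, 5), dtype=bool)
    road[0, 0] = True
    mine[0, 4] = True
    field = compute_disturbance_field(road, mine, cell_width_km=1.0)
    assert field.feature_type[0, 2] == FEATURE_MINE


def test_on_feature_cells_get_floor_distance():
    road = np.zeros((3, 3), dtype=bool)
    road[1, 1] = True
    field = compute_disturbance_field(road, np.zeros_like(road), cell_width_km=0.4)
    assert field.distance_m[1, 1] == pytest.approx(200.0)  # half a cell width


def test_cells_beyond_cutoff_are_unaffected():
    road = np.zeros((1, 30), dtype=bool)
    road[0, 0] = True
    field = compute_disturbance_field(road, np.zeros_like(road), cell_width_km=1.0,
                                      cutoff_m=5000.0)
    assert np.isinf(field.distance_m[0, 20])
    assert field.feature_type[0, 20] == FEATURE_NONE
    assert field.feature_type[0, 5] == FEATURE_ROAD  # 5000 m: inside the zone


def test_distance_field_matches_pairwise_oracle():
    rng = np.random.default_rng(31)
    for _ in range(5):
        shape = (30, 30)
        road = rng.random(shape) < 0.02
        mine = rng.random(shape) < 0.01
        field = compute_disturbance_field(road, mine, cell_width_km=0.3,
                                          cutoff_m=5000.0)
        cells = np.argwhere(np.ones(shape, dtype=bool))
        for feats, code in ((np.argwhere(road), FEATURE_ROAD),
                            (np.argwhere(mine), FEATURE_MINE)):
            if len(feats) == 0:
                continue
            d = np.sqrt(((cells[:, None, :] - feats[None, :, :]) ** 2).sum(-1)) * 300.0
            dmin = d.min(axis=1).reshape(shape)
            if code == FEATURE_ROAD:
                d_road = dmin
            else:
                d_mine = dmin
        d_road = d_road if road.any() else np.full(shape, np.inf)
        d_mine = d_mine if mine.any() else np.full(shape, np.inf)
        expect = np.minimum(d_road, d_mine)
        inside = expect <= 5000.0
        assert np.allclose(field.distance_m[inside],
                           np.maximum(expect[inside], 150.0))
        assert np.all(np.isinf(field.distance_m[~inside]))
        ties_to_mine = d_mine <= d_road
        assert np.array_equal(field.feature_type[inside] == FEATURE_MINE,
                              ties_to_mine[inside])


# ---------------------------------------------------------------------------
# MSA stack and subordination
# ---------------------------------------------------------------------------

def run_on(world, relationships, config=None):
    return run_engine(world, relationships, DriverApplicability(),
                      config or EngineConfig())


def test_pristine_natural_cell_combined_msa_is_climate_only(relationships):
    world = make_world(np.full((4, 4), NAT), gmti=0.0)
    res = run_on(world, relationships)
    for group in Group:
        expected = relationships.msa_climate(group, 0.0)
        assert np.allclose(res.stack.combined[group], expected)


def test_urban_vertebrates_only_habitat_loss_and_climate(relationships):
    lu = np.full((5, 5), URB)
    world = make_world(lu, roads=[RoadSegment(1, LineString([(0.1, 2.5), (4.9, 2.5)]))],
                       gmti=1.26)
    res = run_on(world, relationships)
    # disturbance and fragmentation layers stay exactly 1 in urban land
    assert np.all(res.stack.per_driver[(Group.VERTEBRATES, Driver.DISTURBANCE)] == 1.0)
    assert np.all(res.stack.per_driver[(Group.VERTEBRATES, Driver.FRAGMENTATION)] == 1.0)
    assert np.all(res.losses.per_driver[(Group.VERTEBRATES, Driver.DISTURBANCE)] == 0.0)
    expected = relationships.msa_climate(Group.VERTEBRATES, 1.26) \
        * relationships.msa_habitat_loss(Group.VERTEBRATES, "urban")
    assert np.allclose(res.stack.combined[Group.VERTEBRATES], expected)


def test_cropland_plants_ignore_nitrogen(relationships):
    lu = np.full((4, 4), CROP)
    world = make_world(lu, deposition=np.full((4, 4), 25.0), gmti=0.5)
    res = run_on(world, relationships)
    assert np.all(res.stack.per_driver[(Group.PLANTS, Driver.NITROGEN)] == 1.0)
    assert np.all(res.losses.per_driver[(Group.PLANTS, Driver.NITROGEN)] == 0.0)


def test_natural_plants_feel_nitrogen(relationships):
    world = make_world(np.full((4, 4), NAT), deposition=np.full((4, 4), 25.0))
    res = run_on(world, relationships)
    layer = res.stack.per_driver[(Group.PLANTS, Driver.NITROGEN)]
    assert np.allclose(layer, relationships.msa_nitrogen(Group.PLANTS, 25.0))


# ---------------------------------------------------------------------------
# loss attribution
# ---------------------------------------------------------------------------

def test_attribution_hand_examples(relationships):
    from msabif.globio_engine import MSAStack
    shape = (1, 1)
    stack = MSAStack(
        per_driver={(Group.PLANTS, Driver.CLIMATE): np.full(shape, 0.8),
                    (Group.PLANTS, Driver.HABITAT_LOSS): np.full(shape, 0.5)},
        combined={Group.PLANTS: np.full(shape, 0.4)})
    losses = attribute_losses(stack)
    assert losses.per_driver[(Group.PLANTS, Driver.CLIMATE)][0, 0] == \
        pytest.approx(0.6 * 0.2 / 0.7)
    assert losses.per_driver[(Group.PLANTS, Driver.HABITAT_LOSS)][0, 0] == \
        pytest.approx(0.6 * 0.5 / 0.7)

    single = MSAStack(per_driver={(Group.PLANTS, Driver.CLIMATE): np.full(shape, 0.8)},
                      combined={Group.PLANTS: np.full(shape, 0.8)})
    assert attribute_losses(single).per_driver[(Group.PLANTS, Driver.CLIMATE)][0, 0] == \
        pytest.approx(0.2)

    pristine = MSAStack(per_driver={(Group.PLANTS, Driver.CLIMATE): np.ones(shape),
                                    (Group.PLANTS, Driver.NITROGEN): np.ones(shape)},
                        combined={Group.PLANTS: np.ones(shape)})
    for arr in attribute_losses(pristine).per_driver.values():
        assert np.all(arr == 0.0)


def test_losses_conserve_total_deficit(relationships):
    for seed in range(3):
        world = generate_world(WorldSpec(n_rows=40, n_cols=40, seed=seed))
        res = run_engine(world, relationships)
        for group, comb in res.stack.combined.items():
            total = sum(res.losses.per_driver[(group, d)]
                        for d in res.stack.drivers(group))
            assert np.max(np.abs(total - (1.0 - comb))) < 1e-9
            for d in res.stack.drivers(group):
                arr = res.losses.per_driver[(group, d)]
                assert np.all(arr >= 0) and np.all(arr <= 1)


# ---------------------------------------------------------------------------
# fragmentation decomposition
# ---------------------------------------------------------------------------

def frag_loss(res):
    return res.losses.per_driver[(Group.VERTEBRATES, Driver.FRAGMENTATION)]


def test_roads_only_world_assigns_full_loss_to_roads(relationships):
    lu = np.full((10, 10), NAT)
    world = make_world(lu, roads=[RoadSegment(1, LineString([(0.1, 5.5), (9.9, 5.5)]))])
    res = run_on(world, relationships)
    assert np.allclose(res.losses.fragmentation_road, frag_loss(res))
    assert np.all(res.losses.fragmentation_landuse == 0.0)


def test_cropland_only_world_assigns_full_loss_to_landuse(relationships):
    lu = np.full((10, 10), NAT)
    lu[4, :] = CROP
    world = make_world(lu)
    res = run_on(world, relationships)
    assert np.allclose(res.losses.fragmentation_landuse, frag_loss(res))
    assert np.all(res.losses.fragmentation_road == 0.0)
    assert frag_loss(res).max() > 0


def test_mixed_world_shares_sum_to_full_loss(relationships):
    for seed in range(3):
        world = generate_world(WorldSpec(n_rows=30, n_cols=30, seed=seed))
        res = run_engine(world, relationships)
        total = res.losses.fragmentation_landuse + res.losses.fragmentation_road
        assert np.allclose(total, frag_loss(res), atol=1e-12)
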