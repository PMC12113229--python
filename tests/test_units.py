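"""Hexagonal planning units, disturbance costs, feature aggregation and the
Marxan data-file dialect, checked against exact geometric identities."""

import math

import numpy as np
import pytest
from shapely.geometry import box

import ecoreserve as er
from ecoreserve.ensemble import SuitabilityMap
from ecoreserve.grid import EnvStack, GridSpec
from ecoreserve.units import (DisturbanceScheme, aggregate_feature_amounts,
                              compute_costs, disturbance_index, grid_boundary,
                              hex_polygon, hex_tessellate, read_marxan_dir,
                              unit_landuse_proportions, write_bound_dat,
                              write_pu_dat, write_puvspr_dat, write_spec_dat)


# ---------------------------------------------------------------- geometry

def test_hex_polygon_area_and_perimeter_identities():
    side = 123.4
    # vertices are rounded to 1e-6 m, so identities hold to ~1e-5 relative
    h = hex_polygon(0.0, 0.0, side)
    assert h.area == pytest.approx(1.5 * math.sqrt(3.0) * side ** 2,
                                   rel=1e-5)
    assert h.length == pytest.approx(6 * side, rel=1e-5)


@pytest.fixture(scope="module")
def hex_units():
    # 4 km x 3 km rectangle, 0.5 km2 units
    return hex_tessellate(box(0, 0, 4000, 3000), unit_area_km2=0.5), 12.0


def test_tessellation_conserves_total_area(hex_units):
    units, total = hex_units
    assert units.area_km2.sum() == pytest.approx(total, rel=1e-9)


def test_complete_units_have_nominal_area_and_six_neighbours(hex_units):
    units, _ = hex_units
    complete = [k for k, s in enumerate(units.status) if s == "complete"]
    assert complete  # the rectangle holds several full hexes
    for k in complete:
        assert units.area_km2[k] == pytest.approx(0.5, rel=1e-5)
    # interior units (no exposed outer edge) must have all 6 neighbours;
    # complete units flush with the boundary may have fewer
    interior = [k for k in complete if units.outer_km[k] < 1e-6]
    assert interior
    for k in interior:
        assert len(units.neighbours(units.ids[k])) == 6


def test_shared_plus_outer_equals_perimeter(hex_units):
    units, _ = hex_units
    for k, uid in enumerate(units.ids):
        shared = sum(units.shared_edge_km(uid, nb)
                     for nb in units.neighbours(uid))
        perim = units.polygons[k].length / 1000.0
        assert shared + units.outer_km[k] == pytest.approx(perim, rel=1e-9)


def test_shared_edge_is_symmetric_and_full_for_adjacent_hexes(hex_units):
    units, _ = hex_units
    side_km = math.sqrt(2 * 0.5 / (3 * math.sqrt(3)))
    complete = {units.ids[k] for k, s in enumerate(units.status)
                if s == "complete"}
    found_full_edge = False
    for (a, b), length in units.edges.items():
        assert units.shared_edge_km(a, b) == units.shared_edge_km(b, a)
        if a in complete and b in complete:
            assert length == pytest.approx(side_km, rel=1e-5)
            found_full_edge = True
    assert found_full_edge


def test_degenerate_boundary_rejected_small_area_warns():
    from shapely.geometry import Polygon
    with pytest.raises(ValueError):
        hex_tessellate(Polygon(), 1.0)
    with pytest.warns(UserWarning, match="smaller than one planning unit"):
        hex_tessellate(box(0, 0, 100, 100), unit_area_km2=1.0)


def test_grid_boundary_matches_raster_extent():
    spec = GridSpec(10, 20, 30.0, 500.0, 9000.0)
    b = grid_boundary(spec)
    assert b.bounds == (500.0, 9000.0 - 300.0, 500.0 + 600.0, 9000.0)


# ------------------------------------------------------------- disturbance

def test_disturbance_index_weighted_sum_oracle():
    scheme = DisturbanceScheme.default()
    m = disturbance_index({1: 0.5, 7: 0.5}, scheme)
    assert m == pytest.approx(0.5 * (1 / 7) + 0.5 * 1.0, abs=1e-12)
    with pytest.raises(ValueError, match="sum"):
        disturbance_index({1: 0.6}, scheme)


def test_disturbance_scheme_monotonicity_enforced():
    with pytest.raises(ValueError, match="non-decreasing"):
        DisturbanceScheme(level_of={1: 1, 2: 2},
                          intensity={1: 0.9, 2: 0.1})


def test_scheme_yaml_roundtrip(tmp_path):
    s = DisturbanceScheme.default()
    p = tmp_path / "scheme.yaml"
    s.to_yaml(p)
    s2 = DisturbanceScheme.from_yaml(p)
    assert s2.level_of == s.level_of and s2.intensity == s.intensity


def _uniform_landuse_stack(code: int, n=20, cell=100.0):
    spec = GridSpec(n, n, cell, 0.0, n * cell)
    stack = EnvStack(spec)
    stack.add_layer("landuse", np.full((n, n), float(code)),
                    kind="categorical")
    return stack


def test_uniform_landuse_gives_uniform_cost():
    stack = _uniform_landuse_stack(3)
    units = hex_tessellate(grid_boundary(stack.spec), unit_area_km2=0.25)
    costs = compute_costs(stack, units)
    # every populated unit sees only level 3 -> M = 3/7 exactly
    assign = units.assign_cells(stack.spec, stack.mask)
    populated = np.isin(np.arange(len(units)), np.unique(assign))
    np.testing.assert_allclose(costs[populated], 3.0 / 7.0, atol=1e-12)


def test_higher_disturbance_class_raises_cost():
    lo = _uniform_landuse_stack(2)
    hi = _uniform_landuse_stack(6)
    units_lo = hex_tessellate(grid_boundary(lo.spec), 0.25)
    units_hi = hex_tessellate(grid_boundary(hi.spec), 0.25)
    assert compute_costs(hi, units_hi).mean() > compute_costs(lo, units_lo).mean()


def test_unit_proportions_sum_to_one_where_populated(small_stack):
    units = hex_tessellate(grid_boundary(small_stack.spec),
                           unit_area_km2=0.05)
    props = unit_landuse_proportions(small_stack, units)
    populated = [p for p in props if p]
    assert populated
    for p in populated:
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)


# ------------------------------------------------------- amount aggregation

def test_amount_aggregation_conserves_total_suitability():
    rng = np.random.default_rng(5)
    n = 24
    spec = GridSpec(n, n, 100.0, 0.0, n * 100.0)
    vals = rng.random((n, n))
    smap = SuitabilityMap(values=vals, spec=spec, species="sp")
    units = hex_tessellate(grid_boundary(spec), unit_area_km2=0.3)
    amounts = aggregate_feature_amounts(smap, units)
    total_expected = vals.sum() * spec.cell_area_km2
    assert amounts.sum() == pytest.approx(total_expected, rel=1e-9)
    assert np.all(amounts >= 0)
    assert units.amounts["sp"] is amounts


def test_amount_threshold_mode_counts_suitable_area_only():
    n = 16
    spec = GridSpec(n, n, 100.0, 0.0, n * 100.0)
    vals = np.where(np.arange(n * n).reshape(n, n) % 2 == 0, 0.9, 0.1)
    smap = SuitabilityMap(values=vals, spec=spec, species="sp")
    units = hex_tessellate(grid_boundary(spec), unit_area_km2=0.3)
    amounts = aggregate_feature_amounts(smap, units, threshold=0.7)
    assert amounts.sum() == pytest.approx(
        (vals > 0.7).sum() * spec.cell_area_km2, rel=1e-9)


# -------------------------------------------------------- Marxan dat files

def test_dat_files_roundtrip_bit_identical(tmp_path, hex_units):
    units, _ = hex_units
    rng = np.random.default_rng(0)
    units.costs = rng.uniform(0.1, 1.0, len(units))
    rows = [(1, uid, float(a))
            for uid, a in zip(units.ids, rng.random(len(units)))]
    d = tmp_path
    write_pu_dat(d / "pu.dat", units)
    write_spec_dat(d / "spec.dat",
                   [{"id": 1, "target": 12.345, "spf": 16.74, "name": "sp"}])
    write_puvspr_dat(d / "puvspr.dat", rows)
    write_bound_dat(d / "bound.dat", units)

    pu, spec, puvspr, bound = read_marxan_dir(d)
    assert list(pu.columns) == ["id", "cost", "status"]
    assert len(pu) == len(units)
    np.testing.assert_allclose(pu.cost.to_numpy(), units.costs, rtol=1e-9)
    assert spec.loc[0, "spf"] == 16.74
    # puvspr sorted by (pu, species) as the format requires
    assert puvspr.pu.is_monotonic_increasing
    # boundary: id1==id2 rows carry the outer edge
    outer_rows = bound[bound.id1 == bound.id2]
    outer_map = dict(zip(outer_rows.id1, outer_rows.boundary))
    for k, uid in enumerate(units.ids):
        if units.outer_km[k] > 0:
            assert outer_map[uid] == pytest.approx(units.outer_km[k],
                                                   rel=1e-9)
        else:
            assert uid not in outer_map
    # writing again reproduces byte-identical files
    first = {f: (d / f).read_bytes()
             for f in ("pu.dat", "spec.dat", "puvspr.dat", "bound.dat")}
    write_pu_dat(d / "pu.dat", units)
    write_spec_dat(d / "spec.dat",
                   [{"id": 1, "target": 12.345, "spf": 16.74, "name": "sp"}])
    write_puvspr_dat(d / "puvspr.dat", rows)
    write_bound_dat(d / "bound.dat", units)
    for f, payload in first.items():
        assert (d / f).read_bytes() == payload


def test_geojson_export_has_one_feature_per_unit(tmp_path, hex_units):
    import json
    units, _ = hex_units
    p = tmp_path / "units.geojson"
    units.to_geojson(p)
    gj = json.loads(p.read_text())
    assert gj["type"] == "FeatureCollection"
    assert len(gj["features"]) == len(units)
    props = gj["features"][0]["properties"]
    assert {"id", "area_km2", "status"} <= set(props)
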