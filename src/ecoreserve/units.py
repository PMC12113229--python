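"""Hexagonal planning units, disturbance-index costs, feature amounts.

The study area is tessellated with flat-topped regular hexagons sized so a
full hexagon has the requested area (default 1 km2); hexagons straddling
the boundary are clipped, adjacency is read off shared edges, and each
unit's cost is the anthropogenic disturbance index

    M = sum_n f_n * h_n

over a 7-level land-use grading scheme (f_n = area share of level n inside
the unit, h_n = the level's disturbance intensity, default n/7). Species
suitability is aggregated to suitability-weighted habitat area per unit.
The four Marxan data files (pu.dat, spec.dat, puvspr.dat, bound.dat) are
read and written in a fixed tab-separated dialect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, Point, box
from shapely.strtree import STRtree

from .ensemble import SuitabilityMap
from .grid import EnvStack, GridSpec

_ROUND = 6  # vertex coordinate rounding (1e-6 m) so shared edges match


def hex_polygon(cx: float, cy: float, side: float) -> Polygon:
    """Flat-topped regular hexagon (east/west vertices on the x-axis)."""
    pts = [
        (round(cx + side * math.cos(k * math.pi / 3), _ROUND),
         round(cy + side * math.sin(k * math.pi / 3), _ROUND))
        for k in range(6)
    ]
    return Polygon(pts)


@dataclass
class PlanningUnitSet:
    ids: list[int]
    polygons: list[Polygon]
    area_km2: np.ndarray
    status: list[str]  # complete | partial
    edges: dict[tuple[int, int], float]  # (id_i, id_j) i<j -> shared km
    outer_km: np.ndarray  # exposed study-boundary edge per unit, km
    costs: np.ndarray | None = None
    amounts: dict[str, np.ndarray] = field(default_factory=dict)
    _cell_assign: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, uid: int) -> int:
        return self.ids.index(uid)

    def shared_edge_km(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        return self.edges.get(key, 0.0)

    def neighbours(self, uid: int) -> list[int]:
        out = []
        for (a, b) in self.edges:
            if a == uid:
                out.append(b)
            elif b == uid:
                out.append(a)
        return sorted(out)

    def assign_cells(self, spec: GridSpec, mask: np.ndarray) -> np.ndarray:
        """Unit index (-1 outside) of every valid cell centre; cached."""
        key = (id(spec), spec.shape)
        if key in self._cell_assign:
            return self._cell_assign[key]
        xs, ys = spec.cell_centers()
        pts = [Point(x, y) for x, y in zip(xs[mask], ys[mask])]
        tree = STRtree(self.polygons)
        assign = np.full(len(pts), -1, dtype=int)
        qi, ui = tree.query(pts, predicate="intersects")
        # a centre exactly on a shared edge matches twice; keep the first
        seen = {}
        for p, u in zip(qi, ui):
            if p not in seen:
                seen[p] = u
        for p, u in seen.items():
            assign[p] = u
        self._cell_assign[key] = assign
        return assign

    def to_geojson(self, path) -> None:
        from .io import write_geojson

        props = []
        for k, uid in enumerate(self.ids):
            p = {
                "id": uid,
                "area_km2": float(self.area_km2[k]),
                "status": self.status[k],
            }
            if self.costs is not None:
                p["cost"] = float(self.costs[k])
            for feat, arr in self.amounts.items():
                p[f"amount_{feat}"] = float(arr[k])
            props.append(p)
        write_geojson(path, self.polygons, props)


def hex_tessellate(boundary: Polygon, unit_area_km2: float = 1.0) -> PlanningUnitSet:
    """Clip a flat-topped hexagonal lattice to the study boundary.

    Full-hex area equals ``unit_area_km2``; units with empty intersection
    are dropped; adjacency and shared-edge lengths come from the clipped
    geometry, and each unit's remaining perimeter is its exposed outer edge.
    """
    if boundary.is_empty or not boundary.is_valid:
        raise ValueError("boundary polygon is empty or invalid")
    area_m2 = unit_area_km2 * 1e6
    if boundary.area < area_m2:
        warnings.warn(
            "study area smaller than one planning unit; degenerate set",
            stacklevel=2,
        )
    side = math.sqrt(2.0 * area_m2 / (3.0 * math.sqrt(3.0)))
    minx, miny, maxx, maxy = boundary.bounds
    dx = 1.5 * side
    dy = math.sqrt(3.0) * side
    i0 = int(math.floor((minx - side) / dx)) - 1
    i1 = int(math.ceil((maxx + side) / dx)) + 1
    j0 = int(math.floor((miny - dy) / dy)) - 1
    j1 = int(math.ceil((maxy + dy) / dy)) + 1

    polys, lattice = [], []
    for i in range(i0, i1 + 1):
        off = dy / 2.0 if (i % 2) else 0.0
        for j in range(j0, j1 + 1):
            cx, cy = i * dx, j * dy + off
            hexp = hex_polygon(cx, cy, side)
            clipped = hexp.intersection(boundary)
            if clipped.is_empty or clipped.area < 1e-9 * area_m2:
                continue
            polys.append(clipped)
            lattice.append((i, j))

    n = len(polys)
    ids = list(range(1, n + 1))
    areas = np.array([p.area for p in polys]) / 1e6
    status = [
        "complete" if p.area >= area_m2 * (1 - 1e-6) else "partial"
        for p in polys
    ]
    pos = {ij: k for k, ij in enumerate(lattice)}
    edges: dict[tuple[int, int], float] = {}
    for k, (i, j) in enumerate(lattice):
        if i % 2:
            cand = [(i, j + 1), (i + 1, j), (i + 1, j + 1), (i - 1, j + 1)]
        else:
            cand = [(i, j + 1), (i + 1, j), (i + 1, j - 1), (i - 1, j - 1)]
        for ij2 in cand:
            k2 = pos.get(ij2)
            if k2 is None:
                continue
            key = (min(ids[k], ids[k2]), max(ids[k], ids[k2]))
            if key in edges:
                continue
            seg = polys[k].intersection(polys[k2])
            length = getattr(seg, "length", 0.0)
            if length > 1e-9:
                edges[key] = length / 1000.0
    shared_total = np.zeros(n)
    for (a, b), l in edges.items():
        shared_total[ids.index(a)] += l
        shared_total[ids.index(b)] += l
    perims = np.array([p.length for p in polys]) / 1000.0
    outer = np.clip(perims - shared_total, 0.0, None)
    return PlanningUnitSet(
        ids=ids, polygons=polys, area_km2=areas, status=status,
        edges=edges, outer_km=outer,
    )


@dataclass
class DisturbanceScheme:
    """Land-use code -> disturbance level (1..7) and level intensities."""

    level_of: dict[int, int]
    intensity: dict[int, float]

    def __post_init__(self) -> None:
        levels = sorted(set(self.level_of.values()))
        missing = [lv for lv in levels if lv not in self.intensity]
        if missing:
            raise ValueError(f"no intensity for levels {missing}")
        hs = [self.intensity[lv] for lv in sorted(self.intensity)]
        if any(b < a for a, b in zip(hs, hs[1:])):
            raise ValueError("intensities must be non-decreasing in level")

    @classmethod
    def default(cls, n_levels: int = 7) -> "DisturbanceScheme":
        return cls(
            level_of={c: c for c in range(1, n_levels + 1)},
            intensity={n: n / n_levels for n in range(1, n_levels + 1)},
        )

    @classmethod
    def from_yaml(cls, path) -> "DisturbanceScheme":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            level_of={int(k): int(v) for k, v in raw["level_of"].items()},
            intensity={int(k): float(v) for k, v in raw["intensity"].items()},
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"level_of": self.level_of, "intensity": self.intensity})
        )


def disturbance_index(proportions: dict[int, float],
                      scheme: DisturbanceScheme) -> float:
    """M = sum_n f_n * h_n over the disturbance levels present."""
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"level proportions sum to {total}, not 1")
    m = 0.0
    for level, f in proportions.items():
        if level not in scheme.intensity:
            raise ValueError(f"level {level} not in scheme")
        m += f * scheme.intensity[level]
    return m


def unit_landuse_proportions(
    stack: EnvStack, units: PlanningUnitSet, layer: str = "landuse",
    scheme: DisturbanceScheme | None = None,
) -> list[dict[int, float]]:
    """Per-unit area share of each disturbance level from cell centres."""
    scheme = scheme or DisturbanceScheme.default()
    assign = units.assign_cells(stack.spec, stack.mask)
    codes = stack[layer][stack.mask].astype(int)
    out = []
    for k in range(len(units)):
        sel = codes[assign == k]
        if sel.size == 0:
            out.append({})
            continue
        props: dict[int, float] = {}
        for code in np.unique(sel):
            level = scheme.level_of[int(code)]
            props[level] = props.get(level, 0.0) + (sel == code).mean()
        out.append(props)
    return out


def compute_costs(
    stack: EnvStack, units: PlanningUnitSet,
    scheme: DisturbanceScheme | None = None,
) -> np.ndarray:
    """Disturbance index M per planning unit; stored on the unit set.

    Units containing no cell centres (boundary slivers) get the mean
    observed cost, with a warning.
    """
    scheme = scheme or DisturbanceScheme.default()
    props = unit_landuse_proportions(stack, units, scheme=scheme)
    costs = np.full(len(units), np.nan)
    for k, p in enumerate(props):
        if p:
            costs[k] = disturbance_index(p, scheme)
    empty = np.isnan(costs)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} planning units contain no cell centres; "
            "assigned the mean cost",
            stacklevel=2,
        )
        costs[empty] = np.nanmean(costs)
    units.costs = costs
    return costs


def aggregate_feature_amounts(
    smap: SuitabilityMap, units: PlanningUnitSet,
    threshold: float | None = None,
) -> np.ndarray:
    """Suitability-weighted habitat area (km2) per unit.

    amount = sum over cells whose centres fall in the unit of
    suitability x cell area, so total amount is conserved under
    aggregation. With ``threshold`` set, suitability is binarized first
    (strict >) giving plain suitable-area accounting.
    """
    valid = np.isfinite(smap.values)
    assign = units.assign_cells(smap.spec, valid)
    suit = smap.values[valid]
    if threshold is not None:
        suit = (suit > threshold).astype(float)
    cell_area = smap.spec.cell_area_km2
    amounts = np.zeros(len(units))
    for k in range(len(units)):
        sel = suit[assign == k]
        if sel.size == 0:
            warnings.warn(
                f"unit {units.ids[k]} contains no cell centres; amount 0",
                stacklevel=2,
            )
            continue
        amounts[k] = sel.sum() * cell_area
    units.amounts[smap.species] = amounts
    return amounts


# ---------------------------------------------------------------------------
# Marxan data-file dialect: tab-separated, one header line, %.10g numbers.

def _fmt(v: float) -> str:
    return f"{v:.10g}"


def write_pu_dat(path, units: PlanningUnitSet, status: dict[int, int] | None = None):
    status = status or {}
    with open(path, "w") as fh:
        fh.write("id\tcost\tstatus\n")
        costs = units.costs if units.costs is not None else np.zeros(len(units))
        for k, uid in enumerate(units.ids):
            fh.write(f"{uid}\t{_fmt(costs[k])}\t{status.get(uid, 0)}\n")


def write_spec_dat(path, features: list[dict]):
    """features: [{'id': 1, 'target': ..., 'spf': ..., 'name': ...}, ...]"""
    with open(path, "w") as fh:
        fh.write("id\ttarget\tspf\tname\n")
        for f in features:
            fh.write(
                f"{f['id']}\t{_fmt(f['target'])}\t{_fmt(f['spf'])}\t{f['name']}\n"
            )


def write_puvspr_dat(path, rows: list[tuple[int, int, float]]):
    """rows of (species_id, pu_id, amount), sorted by (pu, species)."""
    with open(path, "w") as fh:
        fh.write("species\tpu\tamount\n")
        for sp, pu, amount in sorted(rows, key=lambda r: (r[1], r[0])):
            fh.write(f"{sp}\t{pu}\t{_fmt(amount)}\n")


def write_bound_dat(path, units: PlanningUnitSet, include_outer: bool = True):
    """Shared-edge table; outer boundary written as id1 == id2 rows."""
    with open(path, "w") as fh:
        fh.write("id1\tid2\tboundary\n")
        rows = [(a, b, l) for (a, b), l in units.edges.items()]
        if include_outer:
            rows += [
                (uid, uid, units.outer_km[k])
                for k, uid in enumerate(units.ids)
                if units.outer_km[k] > 0
            ]
        for a, b, l in sorted(rows):
            fh.write(f"{a}\t{b}\t{_fmt(l)}\n")


def read_dat(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_marxan_dir(directory):
    """Read the four dat files; returns (pu, spec, puvspr, bound) frames."""
    directory = Path(directory)
    return (
        read_dat(directory / "pu.dat"),
        read_dat(directory / "spec.dat"),
        read_dat(directory / "puvspr.dat"),
        read_dat(directory / "bound.dat"),
    )


def grid_boundary(spec: GridSpec) -> Polygon:
    """Rectangular study boundary matching the raster extent."""
    return box(
        spec.x_origin,
        spec.y_origin - spec.nrows * spec.cell_size,
        spec.x_origin + spec.ncols * spec.cell_size,
        spec.y_origin,
    )
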