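"""Synthetic landscape, ground-truth niche, and camera-trap-like sampling.

The generator emulates the statistical structure the downstream analysis
assumes: a stack of spatially autocorrelated environmental layers on a
30 m grid (land use, elevation, vegetation greenness, two bioclimatic
surfaces, plus rasterized road and water features), a known occurrence
probability surface p(x) = logistic(eta(x)), and presence records collected
at camera stations whose placement may be biased by accessibility.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import EnvStack, GridSpec

PRESENCE = "presence"
PSEUDO_ABSENCE = "pseudo_absence"


@dataclass
class LayerSpec:
    """Marginal + spatial-correlation description of one random field."""

    corr_length: float = 8.0  # cells; Gaussian smoothing scale
    mean: float = 0.0
    sd: float = 1.0
    low: float | None = None  # optional clipping after scaling
    high: float | None = None


@dataclass
class LandscapeConfig:
    grid_shape: tuple[int, int] = (128, 128)
    cell_size: float = 30.0
    seed: int = 0
    layer_specs: dict[str, LayerSpec] = field(default_factory=dict)
    n_landuse_classes: int = 7
    # area fractions of disturbance classes 1..7 (undisturbed forest dominates)
    landuse_fractions: tuple[float, ...] = (0.45, 0.20, 0.12, 0.08, 0.06, 0.05, 0.04)
    n_roads: int = 2
    n_streams: int = 3

    def __post_init__(self) -> None:
        r, c = self.grid_shape
        if r < 8 or c < 8:
            raise ValueError("grid_shape must be at least 8x8")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        defaults = {
            "dem": LayerSpec(corr_length=14.0, mean=650.0, sd=220.0, low=0.0),
            "evi": LayerSpec(corr_length=6.0, mean=0.55, sd=0.15, low=0.0, high=1.0),
            "bio3": LayerSpec(corr_length=12.0, mean=55.0, sd=4.0),
            "bio14": LayerSpec(corr_length=9.0, mean=18.0, sd=6.0, low=0.0),
        }
        for name, spec in defaults.items():
            self.layer_specs.setdefault(name, spec)


def gaussian_random_field(shape, corr_length: float, rng: np.random.Generator):
    """Unit-variance smooth field: Gaussian-filtered white noise, standardized.

    corr_length is the smoothing sigma in cells; 0 gives plain white noise.
    """
    z = rng.standard_normal(shape)
    if corr_length > 0:
        z = gaussian_filter(z, sigma=corr_length, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def _random_walk_mask(shape, rng, n_lines: int, drift_axis: int) -> np.ndarray:
    """Rasterized random-walk polylines crossing the grid (roads/streams)."""
    nrows, ncols = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(max(1, n_lines)):
        if drift_axis == 1:  # march west->east, wander in rows
            r = int(rng.integers(0, nrows))
            for c in range(ncols):
                mask[r, c] = True
                r = int(np.clip(r + rng.integers(-1, 2), 0, nrows - 1))
        else:  # march north->south
            c = int(rng.integers(0, ncols))
            for r in range(nrows):
                mask[r, c] = True
                c = int(np.clip(c + rng.integers(-1, 2), 0, ncols - 1))
    return mask


def _classify_fractions(field: np.ndarray, fractions) -> np.ndarray:
    """Quantile-bin a smooth field into classes 1..k with given area shares."""
    probs = np.cumsum(fractions)[:-1] / np.sum(fractions)
    edges = np.quantile(field, probs)
    return (np.searchsorted(edges, field, side="right") + 1).astype(float)


def generate_env_stack(config: LandscapeConfig) -> EnvStack:
    """Build the environmental stack: dem, evi, bio3, bio14, landuse,
    road_mask, water_mask. Slope/aspect and the distance layers are derived
    later by the preprocessing step."""
    rng = np.random.default_rng(config.seed)
    spec = GridSpec(
        nrows=config.grid_shape[0],
        ncols=config.grid_shape[1],
        cell_size=config.cell_size,
    )
    stack = EnvStack(spec=spec)
    for name in ("dem", "evi", "bio3", "bio14"):
        ls = config.layer_specs[name]
        z = gaussian_random_field(spec.shape, ls.corr_length, rng)
        z = ls.mean + ls.sd * z
        if ls.low is not None or ls.high is not None:
            z = np.clip(z, ls.low, ls.high)
        stack.add_layer(name, z, kind="continuous")

    # spatially coherent 7-class land use; class code == disturbance level
    base = gaussian_random_field(spec.shape, 10.0, rng)
    landuse = _classify_fractions(base, config.landuse_fractions[: config.n_landuse_classes])
    road = _random_walk_mask(spec.shape, rng, config.n_roads, drift_axis=1)
    water = _random_walk_mask(spec.shape, rng, config.n_streams, drift_axis=0)
    # cells on roads count as the most disturbed class
    landuse[road] = config.n_landuse_classes
    stack.add_layer("landuse", landuse, kind="categorical",
                    categories=list(range(1, config.n_landuse_classes + 1)))
    stack.add_layer("road_mask", road.astype(float), kind="categorical",
                    categories=[0, 1])
    stack.add_layer("water_mask", water.astype(float), kind="categorical",
                    categories=[0, 1])
    return stack


@dataclass
class TrueNiche:
    """Ground-truth occurrence model: p(x) = logistic(eta(x)).

    eta is linear in standardized covariates, quadratic in EVI (unimodal
    preference peaking at ``evi_opt`` on the standardized scale), increasing
    in distance-to-road (road avoidance), and directional in aspect through
    eastness/southness components. Covariates are standardized internally
    against the landscape mean/sd so coefficients are per-SD effects.
    """

    intercept: float = -2.2
    linear: dict[str, float] = field(
        default_factory=lambda: {"dem": 1.9, "slope": -2.9, "dist_water": -1.4}
    )
    evi_opt: float = 0.8       # standardized EVI at peak preference
    evi_quad: float = -4.0     # curvature (negative => unimodal)
    road_coef: float = 4.8     # per-SD effect of distance-to-road
    eastness_coef: float = 2.2
    southness_coef: float = 1.4

    def required_layers(self) -> list[str]:
        need = set(self.linear) | {"evi", "dist_road", "eastness", "southness"}
        return sorted(need)

    def linear_predictor(self, stack: EnvStack) -> np.ndarray:
        missing = [n for n in self.required_layers() if n not in stack]
        if missing:
            raise KeyError(f"niche covariates missing from stack: {missing}")
        m = stack.mask

        def z(name):
            v = stack[name]
            mu, sd = v[m].mean(), v[m].std()
            return (v - mu) / (sd if sd > 0 else 1.0)

        eta = np.full(stack.spec.shape, self.intercept, dtype=float)
        for name, coef in self.linear.items():
            eta += coef * z(name)
        ze = z("evi")
        eta += self.evi_quad * (ze - self.evi_opt) ** 2
        eta += self.road_coef * z("dist_road")
        # aspect components are already in [-1, 1]; used raw
        eta += self.eastness_coef * stack["eastness"]
        eta += self.southness_coef * stack["southness"]
        return eta

    def probability(self, stack: EnvStack) -> np.ndarray:
        return expit(self.linear_predictor(stack))


@dataclass
class OccurrenceSet:
    """Point records of presences and generated pseudo-absences."""

    records: pd.DataFrame  # columns x, y, species, label
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        need = {"x", "y", "species", "label"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(need)}")

    def __len__(self) -> int:
        return len(self.records)

    def presences(self) -> pd.DataFrame:
        return self.records[self.records.label == PRESENCE]

    def absences(self) -> pd.DataFrame:
        return self.records[self.records.label == PSEUDO_ABSENCE]

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance="user") -> "OccurrenceSet":
        return cls(pd.read_csv(path), provenance=provenance)

    def to_geojson(self, path) -> None:
        from shapely.geometry import Point

        from .io import write_geojson

        geoms = [Point(r.x, r.y) for r in self.records.itertuples()]
        props = [
            {"species": r.species, "label": r.label}
            for r in self.records.itertuples()
        ]
        write_geojson(path, geoms, props)

    def concat(self, other: "OccurrenceSet") -> "OccurrenceSet":
        return OccurrenceSet(
            pd.concat([self.records, other.records], ignore_index=True),
            provenance=self.provenance,
        )


def sample_occurrences(
    stack: EnvStack,
    niche: TrueNiche,
    n_cameras: int,
    detections_per_camera: int = 1,
    bias: np.ndarray | None = None,
    seed: int = 0,
    species: str = "sp1",
) -> OccurrenceSet:
    """Simulate camera-trap presences.

    Camera cells are drawn without replacement with probability proportional
    to the accessibility ``bias`` surface (uniform when absent). Each camera
    makes ``detections_per_camera`` independent Bernoulli(p(x)) trials; a
    camera that detects at least once contributes one presence record at its
    cell centre. Only presences are returned.
    """
    if n_cameras < 1:
        raise ValueError("n_cameras must be >= 1")
    rng = np.random.default_rng(seed)
    p = niche.probability(stack)
    valid = np.flatnonzero(stack.mask.ravel())
    if n_cameras > valid.size:
        raise ValueError("more cameras than valid cells")
    if bias is not None:
        w = np.asarray(bias, dtype=float).ravel()[valid]
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("bias must be non-negative with positive total")
        w = w / w.sum()
    else:
        w = None
    cells = rng.choice(valid, size=n_cameras, replace=False, p=w)
    rows, cols = np.unravel_index(cells, stack.spec.shape)
    pc = p[rows, cols]
    k = max(1, int(detections_per_camera))
    detected = rng.random((n_cameras, k)) < pc[:, None]
    hit = detected.any(axis=1)
    if not hit.any():
        warnings.warn(
            "no camera recorded a detection; occurrence set is empty",
            stacklevel=2,
        )
    x, y = stack.spec.xy_of(rows[hit], cols[hit])
    df = pd.DataFrame(
        {"x": x, "y": y, "species": species, "label": PRESENCE}
    )
    return OccurrenceSet(df, provenance="simulated")


def sample_presences(
    stack: EnvStack,
    niche: TrueNiche,
    n_presences: int,
    detections_per_camera: int = 1,
    bias: np.ndarray | None = None,
    seed: int = 0,
    species: str = "sp1",
    batch: int = 200,
    max_batches: int = 200,
) -> OccurrenceSet:
    """Draw camera batches until ``n_presences`` presences are collected,
    then truncate to exactly that many. Deterministic under the seed."""
    frames = []
    total = 0
    for b in range(max_batches):
        occ = sample_occurrences(
            stack, niche, batch, detections_per_camera, bias,
            seed=seed + 7919 * b, species=species,
        )
        frames.append(occ.records)
        total += len(occ)
        if total >= n_presences:
            break
    df = pd.concat(frames, ignore_index=True).head(n_presences)
    if len(df) < n_presences:
        warnings.warn(
            f"only {len(df)} presences collected of {n_presences} requested",
            stacklevel=2,
        )
    return OccurrenceSet(df, provenance="simulated")


def generate_pseudo_absences(
    stack: EnvStack,
    presences: OccurrenceSet,
    n_absence: int | None = None,
    seed: int = 0,
    species: str | None = None,
) -> OccurrenceSet:
    """Uniform random pseudo-absences on valid cells, excluding presence cells.

    Default count equals the number of presences (balanced classes).
    """
    pres = presences.presences()
    if n_absence is None:
        n_absence = len(pres)
    if n_absence < 1:
        raise ValueError("n_absence must be >= 1")
    rng = np.random.default_rng(seed)
    row, col = stack.spec.index_of(pres.x.to_numpy(), pres.y.to_numpy())
    occupied = np.zeros(stack.spec.shape, dtype=bool)
    occupied[row, col] = True
    candidates = np.flatnonzero((stack.mask & ~occupied).ravel())
    if n_absence > candidates.size:
        raise ValueError(
            f"requested {n_absence} pseudo-absences but only "
            f"{candidates.size} free valid cells"
        )
    chosen = rng.choice(candidates, size=n_absence, replace=False)
    rows, cols = np.unravel_index(chosen, stack.spec.shape)
    x, y = stack.spec.xy_of(rows, cols)
    sp = species if species is not None else (
        pres.species.iloc[0] if len(pres) else "sp1"
    )
    df = pd.DataFrame({"x": x, "y": y, "species": sp, "label": PSEUDO_ABSENCE})
    return OccurrenceSet(df, provenance="simulated")
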