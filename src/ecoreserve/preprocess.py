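"""Covariate derivation and multicollinearity screening.

Derives the analysis-ready layers the learners consume — Euclidean
distance-to-feature rasters, Horn slope/aspect from the DEM, and the
eastness/southness decomposition of the circular aspect — then screens
continuous covariates by pairwise Pearson correlation (|r| >= 0.7 drops
one member of the pair) followed by variance-inflation filtering
(VIF > 10 drops the worst layer, recomputed iteratively). Categorical and
circular layers are exempt from the screen and always retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .grid import EnvStack


def distance_raster(feature_mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Per-cell Euclidean distance (metres) to the nearest feature cell."""
    mask = np.asarray(feature_mask).astype(bool)
    if not mask.any():
        raise ValueError("feature mask is empty; distance undefined")
    return distance_transform_edt(~mask, sampling=cell_size)


def slope_aspect_from_dem(dem: np.ndarray, cell_size: float):
    """Horn 3x3 slope (degrees) and downslope aspect (degrees CW from north).

    Aspect points downhill: an east-rising plane drains west (270 deg).
    Flat cells get aspect = NaN.
    """
    dem = np.asarray(dem, dtype=float)
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")
    z = np.pad(dem, 1, mode="edge")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    # rows grow southward, so +row is -north
    dzdn = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdn)))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdn)) % 360.0
    flat = (dzdx == 0) & (dzdn == 0)
    aspect[flat] = np.nan
    return slope, aspect


def aspect_components(aspect_deg: np.ndarray):
    """Eastness = sin(aspect), southness = -cos(aspect); 0 on flat cells.

    Both lie in [-1, 1]: eastness is 1 on east-facing (90 deg) slopes,
    southness is 1 on south-facing (180 deg) slopes.
    """
    rad = np.radians(aspect_deg)
    east = np.where(np.isfinite(rad), np.sin(rad), 0.0)
    south = np.where(np.isfinite(rad), -np.cos(rad), 0.0)
    return east, south


def derive_standard_layers(stack: EnvStack) -> EnvStack:
    """Add dist_water, dist_road, slope, aspect, eastness, southness.

    Expects ``dem`` plus binary ``road_mask`` / ``water_mask`` layers.
    Returns a new stack; the input is unchanged.
    """
    out = stack.copy()
    cs = stack.spec.cell_size
    if "road_mask" in stack:
        out.add_layer("dist_road", distance_raster(stack["road_mask"], cs))
    if "water_mask" in stack:
        out.add_layer("dist_water", distance_raster(stack["water_mask"], cs))
    if "dem" in stack:
        slope, aspect = slope_aspect_from_dem(stack["dem"], cs)
        out.add_layer("slope", slope)
        aspect_filled = np.where(np.isfinite(aspect), aspect, 0.0)
        out.add_layer("aspect", aspect_filled, kind="circular")
        east, south = aspect_components(aspect)
        out.add_layer("eastness", east)
        out.add_layer("southness", south)
    return out


@dataclass
class CollinearityReport:
    retained: list[str]
    dropped: dict[str, str] = field(default_factory=dict)  # name -> reason
    r_matrix: pd.DataFrame | None = None  # final pairwise |r| among retained
    vif: dict[str, float] = field(default_factory=dict)
    exempt: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "retained": self.retained,
            "dropped": self.dropped,
            "exempt": self.exempt,
            "vif": self.vif,
            "r_matrix": None
            if self.r_matrix is None
            else self.r_matrix.round(6).to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def __str__(self) -> str:
        lines = ["Collinearity screen"]
        lines.append(f"  retained: {', '.join(self.retained)}")
        for name, reason in self.dropped.items():
            lines.append(f"  dropped : {name} ({reason})")
        if self.vif:
            lines.append("  VIF     : " + ", ".join(
                f"{n}={v:.2f}" for n, v in self.vif.items()))
        return "\n".join(lines)


def _vif(values: np.ndarray) -> np.ndarray:
    """VIF per column via OLS R^2 of each column on the others."""
    n, k = values.shape
    out = np.ones(k)
    for j in range(k):
        yj = values[:, j]
        Xj = np.column_stack(
            [np.ones(n)] + [values[:, m] for m in range(k) if m != j]
        )
        beta, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        tss = ((yj - yj.mean()) ** 2).sum()
        r2 = 0.0 if tss == 0 else 1.0 - (resid ** 2).sum() / tss
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def collinearity_filter(
    stack: EnvStack,
    sample: pd.DataFrame | None = None,
    r_max: float = 0.7,
    vif_max: float = 10.0,
) -> tuple[EnvStack, CollinearityReport]:
    """Drop collinear continuous layers; categorical/circular are retained.

    ``sample`` is a point table (columns x, y) at which layer values are
    measured — normally the combined presence + pseudo-absence sample. When
    omitted the full valid grid is used.

    Stage 1 (pairwise): while any |r| >= r_max, drop from the worst pair the
    member with the larger mean |r| against all other remaining layers
    (ties: drop the lexicographically later name). Stage 2 (VIF): while any
    VIF > vif_max, drop the max-VIF layer and recompute.
    """
    cont = stack.continuous_names()
    if len(cont) < 2:
        raise ValueError("need at least 2 continuous layers to screen")
    if sample is not None:
        vals = stack.values_at(
            sample["x"].to_numpy(), sample["y"].to_numpy(), names=cont
        )
        if vals.shape[0] <= len(cont):
            raise ValueError("sample size must exceed the number of layers")
    else:
        vals = np.column_stack([stack[n][stack.mask] for n in cont])

    data = pd.DataFrame(vals, columns=cont)
    # constant columns carry no information and break r/VIF; drop first
    dropped: dict[str, str] = {}
    for n in list(data.columns):
        if data[n].std() == 0:
            dropped[n] = "constant"
            data = data.drop(columns=n)

    def mean_abs_r(df):
        return df.corr().abs().where(lambda m: ~np.eye(len(m), dtype=bool)).mean()

    while data.shape[1] >= 2:
        r = data.corr().abs()
        np.fill_diagonal(r.values, 0.0)
        if r.values.max() < r_max:
            break
        i, j = np.unravel_index(np.argmax(r.values), r.shape)
        a, b = r.columns[i], r.columns[j]
        mar = mean_abs_r(data)
        if mar[a] > mar[b]:
            victim = a
        elif mar[b] > mar[a]:
            victim = b
        else:
            victim = max(a, b)
        dropped[victim] = f"pairwise-r (|r|={r.iloc[i, j]:.3f} with "
        dropped[victim] += f"{b if victim == a else a})"
        data = data.drop(columns=victim)

    while data.shape[1] >= 2:
        v = _vif(data.to_numpy())
        if np.nanmax(v) <= vif_max:
            break
        victim = data.columns[int(np.nanargmax(v))]
        dropped[victim] = f"VIF ({np.nanmax(v):.2f})"
        data = data.drop(columns=victim)

    retained_cont = list(data.columns)
    if not retained_cont:
        raise ValueError("all continuous layers dropped; degenerate stack")

    exempt = [n for n in stack.names if stack.kinds.get(n) != "continuous"]
    keep = retained_cont + exempt
    reduced = stack.subset([n for n in stack.names if n in keep])
    vif_final = dict(zip(retained_cont, _vif(data.to_numpy())))
    report = CollinearityReport(
        retained=retained_cont,
        dropped=dropped,
        r_matrix=data.corr().abs(),
        vif={k: float(v) for k, v in vif_final.items()},
        exempt=exempt,
    )
    return reduced, report
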