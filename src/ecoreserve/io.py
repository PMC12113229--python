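"""Plain-text raster and vector serialization.

Rasters are exchanged as ESRI ASCII grids (``.asc``): a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
whitespace-separated rows, north row first. Vector outputs are GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping

from .grid import NODATA, EnvStack, GridSpec


def write_ascii_grid(path, arr: np.ndarray, spec: GridSpec, mask=None,
                     nodata: float = NODATA) -> None:
    arr = np.asarray(arr, dtype=float)
    out = arr.copy()
    if mask is not None:
        out[~mask] = nodata
    out[~np.isfinite(out)] = nodata
    yll = spec.y_origin - spec.nrows * spec.cell_size
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {spec.x_origin:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {spec.cell_size:.6f}\n"
        f"NODATA_value {nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec, float]:
    """Returns (array with NaN at nodata, GridSpec, nodata value)."""
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows, ncols = int(hdr["nrows"]), int(hdr["ncols"])
    cell = hdr["cellsize"]
    spec = GridSpec(
        nrows=nrows,
        ncols=ncols,
        cell_size=cell,
        x_origin=hdr["xllcorner"],
        y_origin=hdr["yllcorner"] + nrows * cell,
    )
    data = data.reshape(nrows, ncols)
    nodata = hdr.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    return data, spec, nodata


def write_stack(directory, stack: EnvStack) -> None:
    """One .asc per layer plus a JSON manifest of kinds/categories."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.layers.items():
        write_ascii_grid(directory / f"{name}.asc", arr, stack.spec, stack.mask)
    meta = {"kinds": stack.kinds, "categories": stack.categories}
    (directory / "stack.json").write_text(json.dumps(meta, indent=2))


def read_stack(directory) -> EnvStack:
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    stack = None
    for name, kind in meta["kinds"].items():
        arr, spec, _ = read_ascii_grid(directory / f"{name}.asc")
        if stack is None:
            stack = EnvStack(spec=spec, mask=np.isfinite(arr) | (kind != "continuous"))
        filled = np.where(np.isfinite(arr), arr, 0.0)
        stack.add_layer(name, filled, kind=kind,
                        categories=meta["categories"].get(name))
    return stack


def feature_collection(geoms, properties: list[dict]) -> dict:
    geoms = list(geoms)
    if len(geoms) != len(properties):
        raise ValueError(
            f"{len(geoms)} geometries but {len(properties)} property records"
        )
    feats = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, properties)
    ]
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(path, geoms, properties: list[dict]) -> None:
    Path(path).write_text(json.dumps(feature_collection(geoms, properties)))
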