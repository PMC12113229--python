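"""Suitable-habitat masks and multi-species overlap accounting.

Suitability maps are binarized at a strict threshold (default 0.7:
suitability > 0.7 is suitable habitat), and per-cell species counts give
the overlap classes; areas are raster-native (cell count x cell area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import SuitabilityMap


@dataclass
class SuitableMask:
    values: np.ndarray  # bool grid; False off-mask
    spec: object
    species: str
    threshold: float
    valid: np.ndarray | None = None  # validity mask

    @property
    def area_km2(self) -> float:
        return float(self.values.sum()) * self.spec.cell_area_km2


def binarize_suitability(smap: SuitabilityMap, threshold: float = 0.7) -> SuitableMask:
    """Strict comparison: a cell is suitable iff suitability > threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    valid = np.isfinite(smap.values)
    mask = np.zeros(smap.values.shape, dtype=bool)
    mask[valid] = smap.values[valid] > threshold
    return SuitableMask(
        values=mask, spec=smap.spec, species=smap.species,
        threshold=threshold, valid=valid,
    )


def overlap_map(masks: list[SuitableMask]) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-cell count of species with suitable habitat, plus a class table.

    Returns (count raster, table of area km2 per species-count class
    1..n_species). The class areas sum exactly to the union area.
    """
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    shape = masks[0].values.shape
    cell_area = masks[0].spec.cell_area_km2
    for m in masks[1:]:
        if m.values.shape != shape or m.spec != masks[0].spec:
            raise ValueError("masks are not on the same grid")
    counts = np.zeros(shape, dtype=int)
    for m in masks:
        counts += m.values.astype(int)
    rows = []
    for k in range(1, len(masks) + 1):
        rows.append({
            "n_species": k,
            "n_cells": int((counts == k).sum()),
            "area_km2": float((counts == k).sum()) * cell_area,
        })
    return counts, pd.DataFrame(rows)
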