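"""Raster grid primitives.

All analysis rasters live on one north-up planar grid in metric
coordinates. A :class:`GridSpec` holds the affine placement (origin of the
upper-left corner plus square cell size); an :class:`EnvStack` bundles the
named layers, their measurement kinds and a shared validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA = -9999.0

#: measurement kinds a layer may declare
KINDS = ("continuous", "categorical", "circular")


@dataclass(frozen=True)
class GridSpec:
    """Placement of a north-up raster: rows grow southward, cols eastward."""

    nrows: int
    ncols: int
    cell_size: float
    x_origin: float = 0.0  # west edge (metres)
    y_origin: float = 0.0  # north edge (metres)

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y)."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def xy_of(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2


@dataclass
class EnvStack:
    """Named co-registered environmental layers.

    Every layer shares ``spec`` and the validity ``mask`` (True = valid).
    ``kinds`` records per-layer measurement type; ``categories`` lists the
    legal codes of each categorical layer.
    """

    spec: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)
    mask: np.ndarray | None = None
    categories: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        for name, arr in self.layers.items():
            self._check_layer(name, arr)

    def _check_layer(self, name: str, arr: np.ndarray) -> None:
        if arr.shape != self.spec.shape:
            raise ValueError(
                f"layer {name!r} shape {arr.shape} != grid {self.spec.shape}"
            )
        kind = self.kinds.get(name, "continuous")
        if kind not in KINDS:
            raise ValueError(f"unknown layer kind {kind!r} for {name!r}")
        if kind == "continuous" and not np.all(np.isfinite(arr[self.mask])):
            raise ValueError(f"continuous layer {name!r} non-finite on valid cells")
        if kind == "categorical" and name in self.categories:
            codes = np.asarray(self.categories[name])
            vals = arr[self.mask]
            if not np.isin(vals, codes).all():
                raise ValueError(f"categorical layer {name!r} has undeclared codes")

    def add_layer(
        self,
        name: str,
        arr: np.ndarray,
        kind: str = "continuous",
        categories: list[int] | None = None,
    ) -> None:
        self.kinds[name] = kind
        if categories is not None:
            self.categories[name] = list(categories)
        self._check_layer(name, np.asarray(arr, dtype=float))
        self.layers[name] = np.asarray(arr, dtype=float)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def continuous_names(self) -> list[str]:
        return [n for n in self.layers if self.kinds.get(n) == "continuous"]

    def values_at(self, x: np.ndarray, y: np.ndarray, names: list[str] | None = None):
        """Sample layer values at the cells containing the given points.

        Returns an (n_points, n_layers) array; raises if any point falls
        outside the grid or on a nodata cell.
        """
        row, col = self.spec.index_of(x, y)
        if (
            (row < 0).any()
            or (row >= self.spec.nrows).any()
            or (col < 0).any()
            or (col >= self.spec.ncols).any()
        ):
            raise ValueError("points fall outside the grid")
        if not self.mask[row, col].all():
            raise ValueError("points fall on nodata cells")
        names = names if names is not None else self.names
        return np.column_stack([self.layers[n][row, col] for n in names])

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(
            spec=self.spec,
            layers={n: self.layers[n] for n in names},
            kinds={n: self.kinds.get(n, "continuous") for n in names},
            mask=self.mask.copy(),
            categories={n: v for n, v in self.categories.items() if n in names},
        )

    def copy(self) -> "EnvStack":
        return EnvStack(
            spec=self.spec,
            layers={n: a.copy() for n, a in self.layers.items()},
            kinds=dict(self.kinds),
            mask=self.mask.copy(),
            categories={n: list(v) for n, v in self.categories.items()},
        )
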