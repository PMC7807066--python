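"""Raster grid containers.

All gridded data in the package live on a :class:`Grid`: a regular,
cell-centre-registered lattice with row 0 as the northernmost row.  Synthetic
landscapes use planar equal-area coordinates in kilometres (``crs ==
"planar_km"``), so cell counts are areas; real-world layers may use WGS84
lon/lat (``crs == "epsg:4326"``), in which case point distances are
great-circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "Grid",
    "GridSurface",
    "PredictorStack",
    "BinaryRangeMap",
]


@dataclass(frozen=True)
class Grid:
    """A regular raster lattice (cell-centre registration, row 0 = north)."""

    n_rows: int
    n_cols: int
    cell_size_km: float
    x_origin_km: float = 0.0
    y_origin_km: float = 0.0
    crs: str = "planar_km"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def x_centers(self) -> np.ndarray:
        return self.x_origin_km + (np.arange(self.n_cols) + 0.5) * self.cell_size_km

    def y_centers(self) -> np.ndarray:
        """Y coordinate per row, row 0 first (northernmost, largest y)."""
        rows = np.arange(self.n_rows)
        return self.y_origin_km + (self.n_rows - rows - 0.5) * self.cell_size_km

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, each of shape ``shape``."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        w = self.n_cols * self.cell_size_km
        h = self.n_rows * self.cell_size_km
        return (
            (x >= self.x_origin_km)
            & (x < self.x_origin_km + w)
            & (y >= self.y_origin_km)
            & (y < self.y_origin_km + h)
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing planar points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        if not np.all(inside):
            raise ValueError(f"{int((~inside).sum())} point(s) outside grid extent")
        col = np.floor((x - self.x_origin_km) / self.cell_size_km).astype(int)
        row = self.n_rows - 1 - np.floor((y - self.y_origin_km) / self.cell_size_km).astype(int)
        return row, col

    def same_grid(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_km, other.cell_size_km)
            and np.isclose(self.x_origin_km, other.x_origin_km)
            and np.isclose(self.y_origin_km, other.y_origin_km)
            and self.crs == other.crs
        )

    def require_same(self, other: "Grid", what: str = "grids") -> None:
        if not self.same_grid(other):
            raise ValueError(f"{what} are not co-registered")


@dataclass
class GridSurface:
    """A single continuous raster layer (suitability, bias, density, ...)."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def copy(self) -> "GridSurface":
        return GridSurface(self.grid, self.values.copy())

    def flat(self) -> np.ndarray:
        return self.values.ravel()


class PredictorStack:
    """Named, co-registered continuous raster layers.

    NaN encodes nodata; a cell is usable only if finite in every layer.
    """

    def __init__(self, grid: Grid, layers: Mapping[str, np.ndarray]):
        if len(layers) == 0:
            raise ValueError("a PredictorStack needs at least one layer")
        names = list(layers)
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        self.grid = grid
        self._layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {grid.shape}")
            self._layers[name] = arr

    # -- mapping-ish access -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self._layers[name]

    def __len__(self) -> int:
        return len(self._layers)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self._layers.items())

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return PredictorStack(self.grid, {n: self._layers[n] for n in names})

    def copy(self) -> "PredictorStack":
        return PredictorStack(self.grid, {n: a.copy() for n, a in self.items()})

    def valid_mask(self) -> np.ndarray:
        """Boolean grid: True where every layer is finite."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for _, arr in self.items():
            mask &= np.isfinite(arr)
        return mask

    def as_table(self, names: list[str] | None = None) -> np.ndarray:
        """(n_cells, n_layers) array of cell values in C (row-major) order."""
        names = self.names if names is None else names
        return np.column_stack([self._layers[n].ravel() for n in names])


@dataclass
class BinaryRangeMap:
    """Thresholded presence/absence grid."""

    grid: Grid
    present: np.ndarray
    threshold: float
    scenario: str = ""

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != self.grid.shape:
            raise ValueError("mask shape mismatch")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    @property
    def area_km2(self) -> float:
        return self.n_present * self.grid.cell_area_km2
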