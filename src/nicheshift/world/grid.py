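"""Abstract equal-area grid.

The pipeline operates on a rectangular grid of nominally equal-area cells,
so every "area" downstream is a cell count times ``cell_area``.  Cell
identity is the 0-based pair ``(row, col)``; row 0 is the northernmost row.
A pseudo-latitude in degrees is attached to each row so that latitudinal
climate gradients and latitude-linked national covariates can be generated;
the grid spans a single hemisphere from ``lat_north`` down to ``lat_south``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Cell = tuple[int, int]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular equal-area grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; each must be at least 4.
    cell_area : float
        Uniform nominal area per cell (arbitrary units), must be positive.
    lat_north, lat_south : float
        Pseudo-latitude (degrees) of the northern and southern grid edges.
    """

    n_rows: int
    n_cols: int
    cell_area: float = 1.0
    lat_north: float = 70.0
    lat_south: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 4 or self.n_cols < 4:
            raise ValueError(
                f"grid must be at least 4x4, got {self.n_rows}x{self.n_cols}"
            )
        if self.cell_area <= 0:
            raise ValueError(f"cell_area must be positive, got {self.cell_area}")
        if self.lat_north <= self.lat_south:
            raise ValueError("lat_north must exceed lat_south")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def row_latitudes(self) -> np.ndarray:
        """Pseudo-latitude of each row centre, row 0 northernmost."""
        step = (self.lat_north - self.lat_south) / self.n_rows
        return self.lat_north - step * (np.arange(self.n_rows) + 0.5)

    def latitude_field(self) -> np.ndarray:
        """(n_rows, n_cols) array of cell latitudes."""
        return np.repeat(
            self.row_latitudes()[:, None], self.n_cols, axis=1
        )

    def flat_index(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.asarray(rows) * self.n_cols + np.asarray(cols)

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


def cells_to_mask(grid: GridSpec, cells: set[Cell] | np.ndarray) -> np.ndarray:
    """Boolean (n_rows, n_cols) mask from a set of (row, col) cells."""
    mask = np.zeros(grid.shape, dtype=bool)
    if isinstance(cells, np.ndarray):
        mask[cells[:, 0], cells[:, 1]] = True
    else:
        for r, c in cells:
            mask[r, c] = True
    return mask


def mask_to_cells(mask: np.ndarray) -> set[Cell]:
    rows, cols = np.nonzero(mask)
    return {(int(r), int(c)) for r, c in zip(rows, cols)}
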