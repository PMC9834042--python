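"""Grid geometry shared by every raster in a landscape bundle.

All rasters are plain 2-D numpy arrays registered to a :class:`GridSpec`.
Row 0 is the northern edge; cells are square, equal-area, ``cell_size_km``
on a side (default 2 km).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "NEIGHBOR_OFFSETS", "NEIGHBOR_DISTANCES", "require_raster"]

# D8 neighbour offsets in fixed code order: E, SE, S, SW, W, NW, N, NE.
# This ordering is load-bearing: ties in steepest-descent routing are broken
# by the first code in this list.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)
)
_SQRT2 = float(np.sqrt(2.0))
NEIGHBOR_DISTANCES: tuple[float, ...] = (1.0, _SQRT2, 1.0, _SQRT2, 1.0, _SQRT2, 1.0, _SQRT2)


@dataclass(frozen=True)
class GridSpec:
    """Shape and geometry of one co-registered raster stack."""

    n_rows: int
    n_cols: int
    cell_size_km: float = 2.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}")
        if self.cell_size_km <= 0:
            raise ValueError(f"cell_size_km must be positive, got {self.cell_size_km}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km ** 2

    def flat_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def rowcol(self, flat: int) -> tuple[int, int]:
        return divmod(flat, self.n_cols)

    def in_bounds(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


def require_raster(arr: np.ndarray, spec: GridSpec, name: str = "raster") -> np.ndarray:
    """Check that *arr* is a 2-D array matching *spec*; return it as ndarray."""
    arr = np.asarray(arr)
    if arr.ndim != 2 or arr.shape != spec.shape:
        raise ValueError(f"{name} has shape {arr.shape}, expected {spec.shape}")
    return arr
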