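"""Coastal risk reduction, projected from the shoreline back to habitat."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..grids import require_raster
from .assets import AssetMask, NCPLayer, masked_layer
from ._disc import disk_kernel

__all__ = ["shore_mask", "coastal_ncp"]


def shore_mask(land: np.ndarray, marine: np.ndarray) -> np.ndarray:
    """Land cells 8-adjacent to the sea."""
    near_sea = ndimage.binary_dilation(np.asarray(marine, dtype=bool),
                                       structure=np.ones((3, 3)))
    return np.asarray(land, dtype=bool) & near_sea


def coastal_ncp(exposure_with: np.ndarray, exposure_without: np.ndarray,
                shore: np.ndarray, population: np.ndarray,
                elevation_m: np.ndarray, asset: AssetMask,
                protective_distance_cells: float = 2.0,
                elevation_cutoff_m: float = 10.0) -> NCPLayer:
    """Risk reduced by habitat times the people protected, credited to habitat.

    Per shore cell: ``risk_reduced = exposure_without - exposure_with``;
    protected people are those within the protective distance and below the
    elevation cutoff; the product is split equally among the habitat cells
    (on- or off-shore) within protective distance.  Shore cells with no
    habitat in range reduce no risk.
    """
    grid = asset.grid
    e_with = np.asarray(require_raster(exposure_with, grid, "exposure_with"), dtype=np.float64)
    e_without = np.asarray(require_raster(exposure_without, grid, "exposure_without"), dtype=np.float64)
    shore = np.asarray(require_raster(shore, grid, "shore"), dtype=bool)
    population = np.asarray(require_raster(population, grid, "population"), dtype=np.float64)
    elevation = np.asarray(require_raster(elevation_m, grid, "elevation_m"), dtype=np.float64)
    if (e_without < 0).any() or (e_without > 1).any():
        raise ValueError("exposure_without outside [0, 1]")
    if (e_with[shore] > e_without[shore] + 1e-12).any():
        raise ValueError("exposure_with exceeds exposure_without on shore cells")

    kernel = disk_kernel(protective_distance_cells)
    habitat = asset.is_asset
    low_pop = np.where(elevation < elevation_cutoff_m, population, 0.0)

    values = np.zeros(grid.shape, dtype=np.float64)
    r_off, c_off = np.nonzero(kernel)
    r_off = r_off - kernel.shape[0] // 2
    c_off = c_off - kernel.shape[1] // 2
    for r, c in zip(*np.nonzero(shore)):
        nr = r + r_off
        nc = c + c_off
        ok = (nr >= 0) & (nr < grid.n_rows) & (nc >= 0) & (nc < grid.n_cols)
        nr, nc = nr[ok], nc[ok]
        hab_sel = habitat[nr, nc]
        n_habitat = int(hab_sel.sum())
        if n_habitat == 0:
            continue  # no habitat in range: nothing to credit
        risk_reduced = e_without[r, c] - e_with[r, c]
        protected_people = float(low_pop[nr, nc].sum())
        segment_value = risk_reduced * protected_people
        if segment_value <= 0:
            continue
        values[nr[hab_sel], nc[hab_sel]] += segment_value / n_habitat
    return masked_layer("coastal_protection", values, asset, scale="country",
                        realm="both", units="risk index x persons protected")
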