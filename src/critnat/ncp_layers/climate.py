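"""The two globally prioritized surfaces: vulnerable carbon and moisture recycling.

Moisture transport uses a conservative source-to-receptor kernel (rows sum
to at most 1; the residual exits the domain) in place of full atmospheric
moisture-tracking physics.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from ..grids import GridSpec, require_raster
from ..synthkit.config import LandCover
from .assets import AssetMask, NCPLayer, masked_layer

__all__ = ["carbon_ncp", "moisture_ncp", "drift_kernel"]


def carbon_ncp(carbon_stock: np.ndarray, vulnerability_frac: dict[LandCover, float],
               land_cover: np.ndarray, asset: AssetMask) -> NCPLayer:
    """Carbon lost in a typical disturbance event: stock x class vulnerability x area."""
    grid = asset.grid
    stock = np.asarray(require_raster(carbon_stock, grid, "carbon_stock"), dtype=np.float64)
    land_cover = require_raster(land_cover, grid, "land_cover")
    lut = np.full(256, np.nan)
    for cls, frac in vulnerability_frac.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"vulnerability for {LandCover(cls).name} outside [0, 1]")
        lut[int(cls)] = frac
    vuln = lut[land_cover]
    if np.isnan(vuln[asset.is_asset]).any():
        missing = np.unique(land_cover[asset.is_asset & np.isnan(vuln)])
        raise KeyError(f"no vulnerability fraction for classes {missing.tolist()}")
    cell_area_ha = grid.cell_area_km2 * 100.0
    values = np.where(asset.is_asset, stock * np.nan_to_num(vuln) * cell_area_ha, 0.0)
    return masked_layer("carbon_storage", values, asset, scale="global",
                        realm="land", units="tC at risk")


def drift_kernel(spec: GridSpec, direction: tuple[int, int] = (0, 1),
                 max_steps: int = 6, decay: float = 0.5,
                 recycled_fraction: float = 0.8) -> sparse.csr_matrix:
    """Directional transport kernel: each source sheds moisture downwind.

    Weights decay geometrically over ``max_steps`` hops in ``direction``;
    rows sum to ``recycled_fraction`` minus whatever leaves the grid, so the
    kernel is conservative by construction.
    """
    if not 0.0 <= recycled_fraction <= 1.0:
        raise ValueError("recycled_fraction must be in [0, 1]")
    dr, dc = direction
    raw = np.array([decay ** k for k in range(1, max_steps + 1)])
    weights = raw / raw.sum() * recycled_fraction
    n = spec.n_cells
    rows, cols, vals = [], [], []
    rr, cc = np.indices(spec.shape)
    src = (rr * spec.n_cols + cc).ravel()
    for k, w in enumerate(weights, start=1):
        tr = rr + dr * k
        tc = cc + dc * k
        ok = (tr >= 0) & (tr < spec.n_rows) & (tc >= 0) & (tc < spec.n_cols)
        rows.append(src[ok.ravel()])
        cols.append((tr * spec.n_cols + tc).ravel()[ok.ravel()])
        vals.append(np.full(int(ok.sum()), w))
    return sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()


def moisture_ncp(evapotranspiration: np.ndarray, transport_kernel: sparse.spmatrix,
                 rainfed_mask: np.ndarray, vegetation_frac: np.ndarray,
                 asset: AssetMask) -> NCPLayer:
    """Vegetation-regulated moisture delivered to rainfed productive land.

    ``NCP(s) = ET(s) x vegetation_frac(s) x sum over rainfed receptors of
    kernel(s, r)``.  Kernel rows must sum to at most 1.
    """
    grid = asset.grid
    et = np.asarray(require_raster(evapotranspiration, grid, "evapotranspiration"), dtype=np.float64)
    rainfed = np.asarray(require_raster(rainfed_mask, grid, "rainfed_mask"), dtype=bool)
    veg = np.asarray(require_raster(vegetation_frac, grid, "vegetation_frac"), dtype=np.float64)
    if (veg < 0).any() or (veg > 1).any():
        raise ValueError("vegetation_frac outside [0, 1]")
    kernel = sparse.csr_matrix(transport_kernel)
    if kernel.shape != (grid.n_cells, grid.n_cells):
        raise ValueError(f"kernel shape {kernel.shape} does not match grid")
    row_sums = np.asarray(kernel.sum(axis=1)).ravel()
    if (row_sums > 1.0 + 1e-9).any():
        raise ValueError("transport kernel row sums exceed 1 (mass not conserved)")
    delivered_frac = kernel @ rainfed.ravel().astype(np.float64)
    values = (et.ravel() * veg.ravel() * delivered_frac).reshape(grid.shape)
    return masked_layer("moisture_recycling", values, asset, scale="global",
                        realm="land", units="mm/yr delivered to rainfed land")
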