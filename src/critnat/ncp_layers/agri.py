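"""Pollination and livestock-fodder surfaces."""

from __future__ import annotations

import warnings

import numpy as np

from ..grids import require_raster
from ..synthkit.config import LandCover
from .assets import AssetMask, NCPLayer, masked_layer
from ._disc import neighborhood_sum

__all__ = ["pollination_ncp", "fodder_ncp", "rescale_to_index"]


def pollination_ncp(land_cover: np.ndarray, crop_production: np.ndarray,
                    dependency: np.ndarray, asset: AssetMask,
                    flight_radius_cells: float = 2.0,
                    population_equiv: float | None = None) -> NCPLayer:
    """Habitat sufficiency x crop pollination dependency, credited back to habitat.

    For each cropland cell the realized pollination-dependent production is
    ``production x dependency x sufficiency``, where sufficiency is the share
    of cells within flight range that are pollinator habitat.  The realized
    value is split equally among those habitat cells; a cropland cell with no
    habitat in range realizes nothing.
    """
    if flight_radius_cells < 1:
        raise ValueError("flight_radius_cells must be >= 1")
    grid = asset.grid
    land_cover = require_raster(land_cover, grid, "land_cover")
    production = np.asarray(require_raster(crop_production, grid, "crop_production"), dtype=np.float64)
    dependency = np.asarray(require_raster(dependency, grid, "dependency"), dtype=np.float64)

    cropland = land_cover == int(LandCover.CROPLAND)
    habitat = asset.is_asset.astype(np.float64)
    # the focal (farm) cell is not part of its own flight neighbourhood
    n_habitat = neighborhood_sum(habitat, flight_radius_cells, include_center=False)
    n_valid = neighborhood_sum(np.ones(grid.shape), flight_radius_cells, include_center=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        sufficiency = np.where(n_valid > 0, n_habitat / n_valid, 0.0)
    realized = np.where(cropland, production * dependency * sufficiency, 0.0)

    # equal split among in-range habitat cells, gathered by the same kernel
    per_habitat = np.where((n_habitat > 0) & cropland, realized / np.maximum(n_habitat, 1e-300), 0.0)
    credits = neighborhood_sum(per_habitat, flight_radius_cells, include_center=False) * habitat
    if population_equiv is not None:
        credits = credits * population_equiv
        units = "equivalent people fed/yr"
    else:
        units = "pollination-dependent production (t/yr)"
    return masked_layer("pollination", credits, asset, scale="country",
                        realm="land", units=units)


def rescale_to_index(values: np.ndarray, name: str = "layer") -> np.ndarray:
    """Max-normalize a non-negative surface to a 0-1 index."""
    peak = float(np.max(values)) if values.size else 0.0
    if peak <= 0:
        warnings.warn(f"{name}: all-zero surface, rescale skipped", stacklevel=2)
        return np.zeros_like(np.asarray(values, dtype=np.float64))
    return np.asarray(values, dtype=np.float64) / peak


def fodder_ncp(dry_matter_prod: np.ndarray, livestock_demand: np.ndarray,
               asset: AssetMask) -> NCPLayer:
    """Cell-wise min(supply, demand), rescaled to a 0-1 index.

    Where consumption exceeds productivity the gap is assumed met with feed,
    so the realized service is capped at supply.
    """
    grid = asset.grid
    supply = np.asarray(require_raster(dry_matter_prod, grid, "dry_matter_prod"), dtype=np.float64)
    demand = np.asarray(require_raster(livestock_demand, grid, "livestock_demand"), dtype=np.float64)
    if (supply < 0).any() or (demand < 0).any():
        raise ValueError("supply and demand must be non-negative")
    realized = np.where(asset.is_asset, np.minimum(supply, demand), 0.0)
    index = rescale_to_index(realized, "fodder")
    return masked_layer("fodder", index, asset, scale="country", realm="land",
                        units="index (0-1)")
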