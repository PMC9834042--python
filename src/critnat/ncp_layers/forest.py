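"""Timber (commercial + domestic) and fuelwood surfaces.

Commercial accessibility: within 6 h travel of a population centre of more
than 50,000 people and on slope gradients below 70% (strict).  Domestic
harvest happens where commercial harvest cannot; fuelwood may overlap both.
Sustainable harvest is the reciprocal of the years needed to develop the
standing stock at the annual sequestration rate.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..grids import require_raster
from ..travelgraph import TravelField, travel_time
from .assets import AssetMask, NCPLayer, masked_layer
from ._disc import neighborhood_sum
from .agri import rescale_to_index

__all__ = ["timber_fuelwood_ncp", "population_centres", "sustainable_fraction"]


def population_centres(land_cover_urban: np.ndarray, population: np.ndarray,
                       min_people: float = 50_000.0) -> np.ndarray:
    """Urban components whose summed population exceeds ``min_people``."""
    labels, n = ndimage.label(np.asarray(land_cover_urban, dtype=bool),
                              structure=np.ones((3, 3)))
    mask = np.zeros_like(labels, dtype=bool)
    if n == 0:
        return mask
    sums = ndimage.sum_labels(population, labels, index=np.arange(1, n + 1))
    for i, total in enumerate(sums, start=1):
        if total > min_people:
            mask |= labels == i
    return mask


def sustainable_fraction(carbon_stock: np.ndarray, sequestration_rate: np.ndarray) -> np.ndarray:
    """1 / years-to-develop-the-stock; zero where the rate (or stock) is zero."""
    stock = np.asarray(carbon_stock, dtype=np.float64)
    rate = np.asarray(sequestration_rate, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where((stock > 0) & (rate > 0), rate / stock, 0.0)
    return np.minimum(frac, 1.0)


def timber_fuelwood_ncp(carbon_stock: np.ndarray, tree_cover: np.ndarray,
                        sequestration_rate: np.ndarray,
                        travel_to_centres: TravelField | None,
                        slope_pct: np.ndarray, population: np.ndarray,
                        rural_mask: np.ndarray, rural_poor: np.ndarray,
                        asset: AssetMask, *,
                        max_travel_min: float = 360.0,
                        max_slope_pct: float = 70.0,
                        demand_radius_km: float = 10.0,
                        percap_domestic: float = 0.5,
                        percap_fuelwood: float = 0.2) -> dict[str, NCPLayer]:
    """Return the commercial timber, domestic timber and fuelwood layers.

    ``travel_to_centres`` is minutes to the nearest >50,000-person centre
    (``None`` when no centre exists, making nothing commercially accessible).
    Commercial and domestic layers are spatially mutually exclusive.
    """
    grid = asset.grid
    stock = np.asarray(require_raster(carbon_stock, grid, "carbon_stock"), dtype=np.float64)
    cover = np.asarray(require_raster(tree_cover, grid, "tree_cover"), dtype=np.float64)
    slope = np.asarray(require_raster(slope_pct, grid, "slope_pct"), dtype=np.float64)
    population = np.asarray(require_raster(population, grid, "population"), dtype=np.float64)
    rural_mask = np.asarray(require_raster(rural_mask, grid, "rural_mask"), dtype=bool)
    rural_poor = np.asarray(require_raster(rural_poor, grid, "rural_poor"), dtype=np.float64)
    if (slope < 0).any():
        raise ValueError("slope_pct must be non-negative")

    # potential sustainable supply, rural forest cells only
    frac = sustainable_fraction(stock, sequestration_rate)
    supply = stock * cover * frac * rural_mask * asset.is_asset

    if travel_to_centres is None:
        reachable = np.zeros(grid.shape, dtype=bool)
    else:
        reachable = travel_to_centres.minutes <= max_travel_min
    commercial_access = reachable & (slope < max_slope_pct)

    radius_cells = demand_radius_km / grid.cell_size_km
    pop_near = neighborhood_sum(population, radius_cells)
    poor_near = neighborhood_sum(rural_poor, radius_cells)

    commercial = np.where(commercial_access, supply, 0.0)
    domestic = np.where(~commercial_access, np.minimum(supply, percap_domestic * pop_near), 0.0)
    fuelwood = np.minimum(supply, percap_fuelwood * poor_near)

    return {
        "commercial_timber": masked_layer(
            "commercial_timber", rescale_to_index(commercial, "commercial_timber"),
            asset, scale="country", realm="land", units="index (0-1)"),
        "domestic_timber": masked_layer(
            "domestic_timber", rescale_to_index(domestic, "domestic_timber"),
            asset, scale="country", realm="land", units="index (0-1)"),
        "fuelwood": masked_layer(
            "fuelwood", rescale_to_index(fuelwood, "fuelwood"),
            asset, scale="country", realm="land", units="index (0-1)"),
    }


def combine_timber(commercial: NCPLayer, domestic: NCPLayer) -> NCPLayer:
    """Single timber layer from the two mutually exclusive components."""
    overlap = (commercial.values > 0) & (domestic.values > 0)
    if overlap.any():
        raise ValueError("commercial and domestic timber layers overlap")
    return masked_layer("timber", commercial.values + domestic.values,
                        commercial.asset, scale="country", realm="land",
                        units="index (0-1)")
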