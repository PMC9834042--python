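"""Water-quality retention and flood-regulation surfaces.

Retention uses a single-pass D8 interception scheme: each cell's exported
load walks its flow path, and every natural-asset cell en route keeps a
class-specific fraction of the mass arriving there.  This deliberately
simplified routing stands in for full nutrient/sediment delivery models;
mass is conserved exactly (exports = retained + delivered to outlets).
"""

from __future__ import annotations

import numpy as np

from ..grids import require_raster
from ..terrain_flow import DownstreamPopulation, FlowDirection
from ..synthkit.config import LandCover
from .assets import AssetMask, NCPLayer, masked_layer

__all__ = ["route_retention", "retention_ncp", "flood_ncp"]


def route_retention(loads: np.ndarray, flow: FlowDirection,
                    retention_eff: dict[LandCover, float],
                    land_cover: np.ndarray,
                    asset: AssetMask) -> tuple[np.ndarray, float]:
    """Route loads down the D8 network with interception at asset cells.

    Returns ``(retained, delivered)``: per-cell retained mass and the total
    mass reaching outlets.  ``sum(loads) == retained.sum() + delivered`` to
    machine precision.
    """
    grid = flow.grid
    loads = np.asarray(require_raster(loads, grid, "loads"), dtype=np.float64)
    land_cover = require_raster(land_cover, grid, "land_cover")
    if (loads < 0).any():
        raise ValueError("loads must be non-negative")
    eff_lut = np.zeros(256, dtype=np.float64)
    for cls, eff in retention_eff.items():
        if not 0.0 <= eff <= 1.0:
            raise ValueError(f"retention efficiency for {LandCover(cls).name} outside [0, 1]")
        eff_lut[int(cls)] = eff
    eff = np.where(asset.is_asset, eff_lut[land_cover], 0.0).ravel()

    dest = flow.downstream_flat()
    order = flow.topological_order()
    inflow = np.zeros(grid.n_cells, dtype=np.float64)
    retained = np.zeros(grid.n_cells, dtype=np.float64)
    delivered = 0.0
    for c in order:
        kept = eff[c] * inflow[c]
        retained[c] = kept
        outflow = loads.ravel()[c] + inflow[c] - kept
        d = dest[c]
        if d >= 0:
            inflow[d] += outflow
        else:
            delivered += outflow
    # mass routed into marine cells exits the domain there
    marine = ~flow.land.ravel()
    delivered += inflow[marine].sum()
    return retained.reshape(grid.shape), float(delivered)


def retention_ncp(loads: np.ndarray, flow: FlowDirection,
                  retention_eff: dict[LandCover, float],
                  land_cover: np.ndarray, asset: AssetMask,
                  downstream_pop: DownstreamPopulation,
                  variant: str) -> NCPLayer:
    """Retention on asset cells multiplied by the number of people downstream."""
    if variant not in ("nitrogen", "sediment"):
        raise ValueError("variant must be 'nitrogen' or 'sediment'")
    retained, _ = route_retention(loads, flow, retention_eff, land_cover, asset)
    values = retained * downstream_pop.people_downstream
    name = "nitrogen_retention" if variant == "nitrogen" else "sediment_retention"
    units = ("kg N retained x persons downstream" if variant == "nitrogen"
             else "t sediment retained x persons downstream")
    return masked_layer(name, values, asset, scale="country", realm="land", units=units)


def flood_ncp(wetland_storage: np.ndarray, canopy_storage: np.ndarray,
              soil_storage: np.ndarray, downstream_pop: DownstreamPopulation,
              asset: AssetMask) -> NCPLayer:
    """Green-storage index (mean of the three components) times people downstream."""
    grid = asset.grid
    comps = []
    for name, comp in (("wetland_storage", wetland_storage),
                       ("canopy_storage", canopy_storage),
                       ("soil_storage", soil_storage)):
        comp = np.asarray(require_raster(comp, grid, name), dtype=np.float64)
        if (comp < 0).any() or (comp > 1).any():
            raise ValueError(f"{name} outside [0, 1]")
        comps.append(comp)
    index = np.clip(np.mean(comps, axis=0), 0.0, 1.0)
    values = index * downstream_pop.people_downstream
    return masked_layer("flood_regulation", values, asset, scale="country",
                        realm="land", units="storage index x persons downstream")
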