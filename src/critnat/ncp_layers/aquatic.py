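"""Riverine fish disaggregation and the exogenous marine surfaces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ..grids import require_raster
from .assets import AssetMask, NCPLayer, masked_layer

__all__ = ["FishRegression", "fit_fish_regression", "riverine_fish_ncp",
           "marine_passthrough", "PREDICTORS"]

PREDICTORS = ("pop_density", "discharge", "wetland_pct")


@dataclass(frozen=True)
class FishRegression:
    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    r_squared_adj: float
    n_obs: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        pred = np.full(len(table), self.intercept, dtype=np.float64)
        for name, beta in self.coefficients.items():
            pred += beta * table[name].to_numpy(dtype=np.float64)
        return pred


def fit_fish_regression(table: pd.DataFrame) -> FishRegression:
    """OLS of basin catch on population density, discharge and wetland cover."""
    missing = [c for c in PREDICTORS + ("catch_t",) if c not in table.columns]
    if missing:
        raise ValueError(f"basin table missing columns: {missing}")
    if len(table) < 5:
        raise ValueError("need at least 5 basins to fit the regression")
    X = sm.add_constant(table.loc[:, list(PREDICTORS)].astype(float))
    y = table["catch_t"].astype(float)
    if not np.isfinite(X.to_numpy()).all() or not np.isfinite(y.to_numpy()).all():
        raise ValueError("non-finite predictors or catch")
    fit = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")
    return FishRegression(
        intercept=float(fit.params["const"]),
        coefficients={p: float(fit.params[p]) for p in PREDICTORS},
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        n_obs=int(fit.nobs))


def riverine_fish_ncp(regression: FishRegression, basin_table: pd.DataFrame,
                      basin_map: np.ndarray, freshwater_asset: np.ndarray,
                      region_id: np.ndarray, national_totals: dict[int, float],
                      asset: AssetMask) -> NCPLayer:
    """Disaggregate reported national catch onto freshwater habitat.

    Basin-level predictions (floored at zero) are rescaled within each region
    so they sum to the region's reported total, then spread uniformly over
    the basin's freshwater-asset cells as t/km2/yr.  Basins without any
    freshwater habitat drop out before rescaling.
    """
    grid = asset.grid
    basin_map = require_raster(basin_map, grid, "basin_map")
    freshwater = np.asarray(require_raster(freshwater_asset, grid, "freshwater_asset"), dtype=bool)
    region_id = require_raster(region_id, grid, "region_id")
    cell_area = grid.cell_area_km2

    pred = np.maximum(regression.predict(basin_table), 0.0)
    basin_ids = basin_table["basin_id"].to_numpy()
    basin_region = basin_table["region_id"].to_numpy()

    # freshwater cell count per basin
    fresh_cells = {int(b): np.nonzero((basin_map == b) & freshwater) for b in basin_ids}
    has_fresh = np.array([fresh_cells[int(b)][0].size > 0 for b in basin_ids])
    pred = np.where(has_fresh, pred, 0.0)

    values = np.zeros(grid.shape, dtype=np.float64)
    for region, reported in national_totals.items():
        sel = basin_region == region
        total_pred = pred[sel].sum()
        if total_pred <= 0:
            if reported > 0:
                raise ValueError(
                    f"region {region}: reported catch {reported} but zero predicted total")
            continue
        scale = reported / total_pred
        for b, p in zip(basin_ids[sel], pred[sel]):
            rows, cols = fresh_cells[int(b)]
            if rows.size == 0 or p <= 0:
                continue
            catch = p * scale                      # t/yr for this basin
            values[rows, cols] += catch / (rows.size * cell_area)
    return masked_layer("riverine_fish", values, asset, scale="country",
                        realm="land", units="t/km2/yr")


def marine_passthrough(layer: np.ndarray, asset: AssetMask, name: str) -> NCPLayer:
    """Mask an exogenous marine surface (catch or reef tourism) to marine assets."""
    if name not in ("marine_fish", "reef_tourism"):
        raise ValueError("name must be 'marine_fish' or 'reef_tourism'")
    layer = np.asarray(require_raster(layer, asset.grid, name), dtype=np.float64)
    if (layer < 0).any():
        raise ValueError(f"{name}: negative values")
    units = "t/km2/yr" if name == "marine_fish" else "tourism expenditure decile"
    return masked_layer(name, layer, asset, scale="country", realm="marine", units=units)
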