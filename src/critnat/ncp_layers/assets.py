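"""Natural-asset masking and the NCP layer container.

A natural asset is a natural or semi-natural ecosystem cell — forest,
grassland, wetland, sparse vegetation, inland water, or (for marine NCP)
the marine realm.  Cropland, urban, bare and ice are never assets.  Every
NCP surface is non-negative, finite, and identically zero off its asset
mask; the constructor enforces this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grids import GridSpec, require_raster
from ..synthkit.config import NATURAL_CLASSES, LandCover

__all__ = ["AssetMask", "NCPLayer", "LOCAL_NCP_NAMES", "GLOBAL_NCP_NAMES", "NCP_NAMES"]

_FORBIDDEN = {LandCover.CROPLAND, LandCover.URBAN, LandCover.BARE, LandCover.ICE}

LOCAL_NCP_NAMES = (
    "nitrogen_retention", "sediment_retention", "pollination", "fodder",
    "timber", "fuelwood", "flood_regulation", "nature_access",
    "riverine_fish", "marine_fish", "reef_tourism", "coastal_protection",
)
GLOBAL_NCP_NAMES = ("carbon_storage", "moisture_recycling")
NCP_NAMES = LOCAL_NCP_NAMES + GLOBAL_NCP_NAMES
# timber sub-layers are valid intermediates; "timber" is their union
_SUBLAYER_NAMES = ("commercial_timber", "domestic_timber")


@dataclass(frozen=True)
class AssetMask:
    grid: GridSpec
    is_asset: np.ndarray
    classes: frozenset = field(default_factory=lambda: frozenset(NATURAL_CLASSES))

    def __post_init__(self) -> None:
        require_raster(self.is_asset, self.grid, "is_asset")

    @classmethod
    def from_landcover(cls, land_cover: np.ndarray, spec: GridSpec,
                       classes=None) -> "AssetMask":
        """Build a mask from the land-cover raster for a set of asset classes.

        ``classes`` defaults to the terrestrial natural/semi-natural set; pass
        e.g. ``{LandCover.MARINE}`` for marine NCP or ``{LandCover.FOREST}``
        for timber.  Developed classes are rejected.
        """
        if classes is None:
            classes = NATURAL_CLASSES
        classes = frozenset(LandCover(c) for c in classes)
        bad = classes & _FORBIDDEN
        if bad:
            raise ValueError(f"classes can never be assets: {sorted(c.name for c in bad)}")
        land_cover = require_raster(land_cover, spec, "land_cover")
        mask = np.isin(land_cover, [int(c) for c in classes])
        return cls(grid=spec, is_asset=mask, classes=classes)


@dataclass(frozen=True)
class NCPLayer:
    """One named per-cell contribution surface, zeroed off its asset mask."""

    name: str
    values: np.ndarray
    scale: str                  # "country" or "global"
    realm: str                  # "land", "marine" or "both"
    units: str
    asset: AssetMask

    def __post_init__(self) -> None:
        if self.name not in NCP_NAMES + _SUBLAYER_NAMES:
            raise ValueError(f"unknown NCP name {self.name!r}")
        if self.scale not in ("country", "global"):
            raise ValueError(f"scale must be country|global, got {self.scale!r}")
        if self.realm not in ("land", "marine", "both"):
            raise ValueError(f"realm must be land|marine|both, got {self.realm!r}")
        values = require_raster(self.values, self.asset.grid, "values")
        if not np.isfinite(values).all():
            raise ValueError(f"{self.name}: non-finite values")
        if (values < 0).any():
            raise ValueError(f"{self.name}: negative values")
        if (values[~self.asset.is_asset] != 0).any():
            raise ValueError(f"{self.name}: non-zero values off the asset mask")

    @property
    def grid(self) -> GridSpec:
        return self.asset.grid

    @property
    def total(self) -> float:
        return float(self.values.sum())


def masked_layer(name: str, raw: np.ndarray, asset: AssetMask, *, scale: str,
                 realm: str, units: str) -> NCPLayer:
    """Zero *raw* off the asset mask and wrap it as a validated NCPLayer."""
    raw = require_raster(np.asarray(raw, dtype=np.float64), asset.grid, name)
    values = np.where(asset.is_asset, raw, 0.0)
    return NCPLayer(name=name, values=values, scale=scale, realm=realm,
                    units=units, asset=asset)
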