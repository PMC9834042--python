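"""Nature access: people within travel reach of natural habitat."""

from __future__ import annotations

import numpy as np

from ..grids import require_raster
from .assets import AssetMask, NCPLayer, masked_layer

__all__ = ["access_ncp"]


def access_ncp(pop_within: np.ndarray, asset: AssetMask) -> NCPLayer:
    """Population within the travel budget of each habitat cell (passthrough)."""
    pop_within = np.asarray(require_raster(pop_within, asset.grid, "pop_within"),
                            dtype=np.float64)
    if (pop_within < 0).any():
        raise ValueError("pop_within must be non-negative")
    return masked_layer("nature_access", pop_within, asset, scale="country",
                        realm="land", units="persons within travel budget")
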