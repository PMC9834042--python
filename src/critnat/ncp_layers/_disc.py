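"""Euclidean-disk neighbourhood sums shared by several NCP models."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["disk_kernel", "neighborhood_sum"]


def disk_kernel(radius_cells: float, include_center: bool = True) -> np.ndarray:
    """Boolean footprint of cells whose centre lies within ``radius_cells``."""
    r = int(np.floor(radius_cells))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    kernel = (yy ** 2 + xx ** 2) <= radius_cells ** 2
    if not include_center:
        kernel[r, r] = False
    return kernel


def neighborhood_sum(arr: np.ndarray, radius_cells: float,
                     include_center: bool = True) -> np.ndarray:
    """Sum of *arr* over the disk around each cell; off-grid contributes 0."""
    kernel = disk_kernel(radius_cells, include_center).astype(np.float64)
    return ndimage.convolve(np.asarray(arr, dtype=np.float64), kernel,
                            mode="constant", cval=0.0)
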