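"""Raster, vector and table I/O.

Rasters are single-band TIFFs (float32, or uint8 for categorical/boolean
layers) with a JSON sidecar carrying the synthetic equal-area registration
(2,000 m pixels by default), nodata convention (-9999 / 255) and dtype.
Region outlines go to GeoJSON built from cell boundaries.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from ..grids import GridSpec

__all__ = ["write_raster", "read_raster", "write_region_geojson",
           "write_json", "file_sha256"]

FLOAT_NODATA = -9999.0
BYTE_NODATA = 255


def _sidecar(spec: GridSpec, dtype: str, nodata) -> dict:
    size_m = spec.cell_size_km * 1000.0
    return {
        "crs": "synthetic equal-area, metres",
        "transform": [size_m, 0.0, 0.0, 0.0, -size_m, spec.n_rows * size_m],
        "n_rows": spec.n_rows,
        "n_cols": spec.n_cols,
        "cell_size_km": spec.cell_size_km,
        "dtype": dtype,
        "nodata": nodata,
    }


def write_raster(path: str | Path, arr: np.ndarray, spec: GridSpec,
                 nodata_mask: np.ndarray | None = None) -> Path:
    """Write a raster as TIFF + `.json` sidecar; dtype inferred from the data."""
    path = Path(path)
    arr = np.asarray(arr)
    if arr.dtype == bool or np.issubdtype(arr.dtype, np.unsignedinteger):
        out = arr.astype(np.uint8)
        nodata = BYTE_NODATA
    elif np.issubdtype(arr.dtype, np.integer):
        out = arr.astype(np.int32)
        nodata = -9999
    else:
        out = arr.astype(np.float32)
        nodata = FLOAT_NODATA
    if nodata_mask is not None:
        out = out.copy()
        out[nodata_mask] = nodata
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, out)
    sidecar = _sidecar(spec, str(out.dtype), nodata)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    arr = tifffile.imread(Path(path))
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        spec = GridSpec(meta["n_rows"], meta["n_cols"], meta["cell_size_km"])
    else:
        spec = GridSpec(arr.shape[0], arr.shape[1])
    return arr, spec


def write_region_geojson(path: str | Path, region_id: np.ndarray,
                         spec: GridSpec) -> Path:
    """Dissolve each region's cells into a (multi)polygon feature."""
    path = Path(path)
    size = spec.cell_size_km * 1000.0
    features = []
    for rid in np.unique(region_id):
        if rid <= 0:
            continue
        rows, cols = np.nonzero(region_id == rid)
        cells = [box(c * size, (spec.n_rows - r - 1) * size,
                     (c + 1) * size, (spec.n_rows - r) * size)
                 for r, c in zip(rows, cols)]
        geom = unary_union(cells)
        features.append({"type": "Feature",
                         "properties": {"region_id": int(rid)},
                         "geometry": mapping(geom)})
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
    return path


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
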