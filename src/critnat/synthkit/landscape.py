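"""Synthetic landscape generation.

One integer seed fans out to a named sub-stream per raster, so adding a new
raster never perturbs the others.  Land cover is produced by slicing ranked
smoothed random fields into the configured class proportions, with urban
pinned to population centres, cropland pulled toward them, and ice pushed to
high elevation.  Elevation is a smooth field plus a distance-to-coast ramp,
pit-filled so the drainage property holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
from scipy import ndimage

from ..grids import GridSpec, require_raster
from .. import terrain_flow
from .config import NATURAL_CLASSES, ConfigurationError, GeneratorConfig, LandCover

__all__ = ["LandscapeBundle", "make_landscape", "validate_bundle"]

# Fixed sub-stream ids per raster; append-only.
_STREAMS = {
    "coast": 0, "elevation": 1, "population": 2, "landcover": 3, "friction": 4,
    "crop": 5, "pollination": 6, "dmp": 7, "livestock": 8, "carbon": 9,
    "sequestration": 10, "evapotranspiration": 11, "fertilizer": 12,
    "erosion": 13, "regions": 14, "protected": 15,
}

REALM_LAND, REALM_EEZ = 0, 1


@dataclass
class LandscapeBundle:
    """The synthetic world: co-registered rasters plus region and realm maps."""

    grid: GridSpec
    land_cover: np.ndarray          # uint8 LandCover codes
    elevation_m: np.ndarray
    population: np.ndarray
    rural_poor: np.ndarray
    friction_min_per_km: np.ndarray
    crop_production: np.ndarray
    pollination_dependency: np.ndarray
    dry_matter_prod: np.ndarray
    livestock_demand: np.ndarray
    carbon_stock: np.ndarray
    sequestration_rate: np.ndarray
    evapotranspiration: np.ndarray
    fertilizer_load: np.ndarray
    erosion_load: np.ndarray
    region_id: np.ndarray           # int32, 0 = unassigned/overlapping claim
    realm: np.ndarray               # uint8, 0 = land, 1 = eez
    protected: np.ndarray           # bool

    @property
    def land(self) -> np.ndarray:
        return self.realm == REALM_LAND

    @property
    def marine(self) -> np.ndarray:
        return self.realm == REALM_EEZ

    def raster_items(self):
        for f in dataclass_fields(self):
            if f.name != "grid":
                yield f.name, getattr(self, f.name)

    def region_ids(self) -> list[int]:
        ids = np.unique(self.region_id)
        return [int(i) for i in ids if i > 0]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, normalized to zero mean / unit std."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = field.std()
    return (field - field.mean()) / (sd if sd > 0 else 1.0)


def make_landscape(config: GeneratorConfig, seed: int) -> LandscapeBundle:
    config.validate()
    spec = GridSpec(config.n_rows, config.n_cols, config.cell_size_km)
    shape = spec.shape
    sigma = config.smoothing_sigma

    # --- coastline / realm -------------------------------------------------
    rng = _rng(seed, "coast")
    xnorm = np.broadcast_to(np.linspace(0.0, 1.0, spec.n_cols), shape)
    coast_field = xnorm + 0.35 * _smooth_field(rng, shape, sigma)
    if config.marine_fraction > 0:
        marine = coast_field < np.quantile(coast_field, config.marine_fraction)
    else:
        marine = np.zeros(shape, dtype=bool)
    land = ~marine
    realm = np.where(marine, REALM_EEZ, REALM_LAND).astype(np.uint8)

    # --- elevation: noise + ramp away from the coast, then pit-filled ------
    rng = _rng(seed, "elevation")
    if marine.any():
        dist_coast = ndimage.distance_transform_edt(land)
    else:
        rr, cc = np.indices(shape)
        dist_coast = 1.0 + np.minimum.reduce(
            [rr, cc, spec.n_rows - 1 - rr, spec.n_cols - 1 - cc]).astype(float)
    elevation = (config.coast_ramp_m_per_cell * dist_coast
                 + config.elevation_relief_m * (_smooth_field(rng, shape, sigma) * 0.5 + 0.5))
    elevation[marine] = -10.0
    elevation[land] = np.maximum(elevation[land], 0.5)
    elevation = terrain_flow.fill_pits(elevation, marine, spec)

    # --- population: kernels at a few centres + low background ------------
    rng = _rng(seed, "population")
    land_idx = np.nonzero(land.ravel())[0]
    n_centres = min(config.n_population_centres, land_idx.size)
    centre_cells = rng.choice(land_idx, size=n_centres, replace=False)
    population = np.where(land, config.background_population, 0.0)
    rr, cc = np.indices(shape)
    for cell in centre_cells:
        r0, c0 = spec.rowcol(int(cell))
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        population += np.where(
            land, config.centre_peak_population * np.exp(-d2 / (2 * config.centre_sigma_cells ** 2)), 0.0)

    # --- land cover --------------------------------------------------------
    rng = _rng(seed, "landcover")
    props = config.class_proportions
    n_land = int(land.sum())
    counts = {cls: int(round(p * n_land)) for cls, p in props.items()}
    # fix rounding drift on the largest class
    drift = n_land - sum(counts.values())
    largest = max(counts, key=lambda c: counts[c])
    counts[largest] += drift

    land_cover = np.full(shape, int(LandCover.MARINE), dtype=np.uint8)
    unassigned = land.copy()

    def take_top(score: np.ndarray, cls: LandCover) -> None:
        k = counts.get(cls, 0)
        if k <= 0:
            return
        flat = np.where(unassigned.ravel(), score.ravel(), -np.inf)
        chosen = np.argsort(flat, kind="stable")[::-1][:k]
        land_cover.ravel()[chosen] = int(cls)
        unassigned.ravel()[chosen] = False

    dev_score = ndimage.gaussian_filter(population, 1.0) + 0.01 * _smooth_field(rng, shape, 1.0)
    take_top(dev_score, LandCover.URBAN)
    crop_score = ndimage.gaussian_filter(population, 3.0) + 0.3 * _smooth_field(rng, shape, sigma)
    take_top(crop_score, LandCover.CROPLAND)
    take_top(elevation + 0.1 * _smooth_field(rng, shape, 1.0), LandCover.ICE)
    # remaining classes: slice one ranked autocorrelated field into blobs
    blob = _smooth_field(rng, shape, sigma)
    rest = [LandCover.FOREST, LandCover.GRASSLAND, LandCover.WETLAND,
            LandCover.SPARSE, LandCover.INLAND_WATER, LandCover.BARE]
    rest_cells = np.nonzero(unassigned.ravel())[0]
    order = rest_cells[np.argsort(blob.ravel()[rest_cells], kind="stable")]
    pos = 0
    for cls in rest:
        k = counts.get(cls, 0)
        if cls is rest[-1]:
            k = order.size - pos  # absorb residual
        land_cover.ravel()[order[pos:pos + k]] = int(cls)
        pos += k

    urban = land_cover == int(LandCover.URBAN)
    population = _ensure_big_centre(population, urban, spec)
    rural_poor = np.where(urban, 0.0, config.rural_poor_fraction * population)

    # --- remaining surfaces -----------------------------------------------
    rng = _rng(seed, "friction")
    friction = config.base_friction_min_per_km * np.exp(0.4 * _smooth_field(rng, shape, sigma))
    friction = np.where(urban, friction * 0.5, friction)
    friction = np.where(marine, friction * 1.2, friction)
    friction = np.maximum(friction, 1.0)

    rng = _rng(seed, "crop")
    cropland = land_cover == int(LandCover.CROPLAND)
    crop_production = np.where(
        cropland, np.exp(3.0 + 0.5 * _smooth_field(rng, shape, sigma)), 0.0)

    rng = _rng(seed, "pollination")
    pollination = np.where(
        cropland, np.clip(0.5 + 0.25 * _smooth_field(rng, shape, sigma), 0.0, 1.0), 0.0)

    rng = _rng(seed, "dmp")
    veg_mult = np.select(
        [land_cover == int(LandCover.GRASSLAND), land_cover == int(LandCover.FOREST),
         land_cover == int(LandCover.CROPLAND), land_cover == int(LandCover.SPARSE),
         land_cover == int(LandCover.WETLAND)],
        [1.2, 1.0, 0.8, 0.5, 0.9], default=0.1)
    dmp = np.where(land, np.clip(4.0 + 2.0 * _smooth_field(rng, shape, sigma), 0.1, None) * veg_mult, 0.0)

    rng = _rng(seed, "livestock")
    livestock = np.where(land, np.clip(2.0 + 1.5 * _smooth_field(rng, shape, sigma), 0.0, None), 0.0)

    rng = _rng(seed, "carbon")
    carbon_base = _per_class(land_cover, {
        LandCover.FOREST: 120.0, LandCover.WETLAND: 90.0, LandCover.GRASSLAND: 40.0,
        LandCover.SPARSE: 20.0, LandCover.CROPLAND: 30.0, LandCover.URBAN: 10.0,
        LandCover.BARE: 2.0, LandCover.ICE: 0.0, LandCover.INLAND_WATER: 5.0,
        LandCover.MARINE: 0.0})
    carbon_stock = carbon_base * np.clip(1.0 + 0.3 * _smooth_field(rng, shape, sigma), 0.2, None)

    rng = _rng(seed, "sequestration")
    seq_base = _per_class(land_cover, {
        LandCover.FOREST: 2.5, LandCover.WETLAND: 1.5, LandCover.GRASSLAND: 1.0,
        LandCover.SPARSE: 0.5, LandCover.CROPLAND: 1.2, LandCover.URBAN: 0.2,
        LandCover.BARE: 0.05, LandCover.ICE: 0.0, LandCover.INLAND_WATER: 0.1,
        LandCover.MARINE: 0.0})
    sequestration = seq_base * np.clip(1.0 + 0.3 * _smooth_field(rng, shape, sigma), 0.1, None)

    rng = _rng(seed, "evapotranspiration")
    evapo = np.where(land, np.clip(600.0 + 300.0 * _smooth_field(rng, shape, sigma), 50.0, None), 0.0)

    rng = _rng(seed, "fertilizer")
    fertilizer = np.where(cropland, 2.0 * crop_production, 0.0)
    fertilizer += np.where(urban, 10.0, 0.0)
    fertilizer *= np.clip(1.0 + 0.2 * _smooth_field(rng, shape, sigma), 0.1, None)

    rng = _rng(seed, "erosion")
    slope = terrain_flow.slope_percent(elevation, spec)
    cover = _per_class(land_cover, {
        LandCover.FOREST: 0.9, LandCover.WETLAND: 0.8, LandCover.GRASSLAND: 0.6,
        LandCover.SPARSE: 0.3, LandCover.CROPLAND: 0.4, LandCover.URBAN: 0.7,
        LandCover.BARE: 0.05, LandCover.ICE: 0.9, LandCover.INLAND_WATER: 1.0,
        LandCover.MARINE: 1.0})
    erosion = np.where(land, slope * (1.0 - cover)
                       * np.clip(1.0 + 0.3 * _smooth_field(rng, shape, sigma), 0.1, None), 0.0)

    # --- regions: Voronoi over random seed points --------------------------
    rng = _rng(seed, "regions")
    k = config.n_regions
    seeds_r = rng.integers(0, spec.n_rows, size=k)
    seeds_c = rng.integers(0, spec.n_cols, size=k)
    d2 = (rr[None, :, :] - seeds_r[:, None, None]) ** 2 + (cc[None, :, :] - seeds_c[:, None, None]) ** 2
    region_id = (np.argmin(d2, axis=0) + 1).astype(np.int32)

    rng = _rng(seed, "protected")
    pfield = np.where(land, _smooth_field(rng, shape, sigma), -np.inf)
    n_prot = int(round(config.protected_fraction * n_land))
    protected = np.zeros(shape, dtype=bool)
    if n_prot > 0:
        top = np.argsort(pfield.ravel(), kind="stable")[::-1][:n_prot]
        protected.ravel()[top] = True

    bundle = LandscapeBundle(
        grid=spec, land_cover=land_cover, elevation_m=elevation,
        population=population, rural_poor=rural_poor,
        friction_min_per_km=friction, crop_production=crop_production,
        pollination_dependency=pollination, dry_matter_prod=dmp,
        livestock_demand=livestock, carbon_stock=carbon_stock,
        sequestration_rate=sequestration, evapotranspiration=evapo,
        fertilizer_load=fertilizer, erosion_load=erosion,
        region_id=region_id, realm=realm, protected=protected)
    validate_bundle(bundle)
    return bundle


def _per_class(land_cover: np.ndarray, table: dict[LandCover, float]) -> np.ndarray:
    lut = np.zeros(256, dtype=np.float64)
    for cls, v in table.items():
        lut[int(cls)] = v
    return lut[land_cover]


def _ensure_big_centre(population: np.ndarray, urban: np.ndarray, spec: GridSpec,
                       threshold: float = 50_000.0) -> np.ndarray:
    """Guarantee at least one urban component above the commercial-timber
    population-centre threshold, scaling the largest component if needed."""
    labels, n = ndimage.label(urban, structure=np.ones((3, 3)))
    if n == 0:
        return population
    sums = ndimage.sum_labels(population, labels, index=np.arange(1, n + 1))
    if sums.max() > threshold:
        return population
    biggest = int(np.argmax(sums)) + 1
    factor = (threshold * 1.05) / max(sums[biggest - 1], 1e-9)
    out = population.copy()
    out[labels == biggest] *= factor
    return out


def validate_bundle(bundle: LandscapeBundle) -> None:
    """Automated validator for every LandscapeBundle invariant."""
    spec = bundle.grid
    for name, arr in bundle.raster_items():
        require_raster(arr, spec, name)
        if np.issubdtype(np.asarray(arr).dtype, np.floating) and not np.isfinite(arr).all():
            raise AssertionError(f"{name}: non-finite values")
    marine_class = bundle.land_cover == int(LandCover.MARINE)
    if not np.array_equal(marine_class, bundle.marine):
        raise AssertionError("marine land-cover class must coincide with the eez realm")
    if (bundle.population[bundle.marine] != 0).any():
        raise AssertionError("population must be zero on marine cells")
    if (bundle.rural_poor > bundle.population + 1e-9).any():
        raise AssertionError("rural_poor exceeds population")
    if (bundle.crop_production > 0).any():
        if not (bundle.land_cover[bundle.crop_production > 0] == int(LandCover.CROPLAND)).all():
            raise AssertionError("crop production outside cropland")
    if not (bundle.friction_min_per_km > 0).all():
        raise AssertionError("friction must be positive")
    for name in ("population", "dry_matter_prod", "livestock_demand", "carbon_stock",
                 "sequestration_rate", "evapotranspiration", "fertilizer_load", "erosion_load"):
        if (getattr(bundle, name) < 0).any():
            raise AssertionError(f"{name} has negative values")
    dep = bundle.pollination_dependency
    if (dep < 0).any() or (dep > 1).any():
        raise AssertionError("pollination_dependency outside [0, 1]")
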