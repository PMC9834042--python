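"""Generator configuration and the land-cover legend."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum


class LandCover(IntEnum):
    """Land-cover legend; codes are stable and stored as uint8."""

    FOREST = 0
    GRASSLAND = 1
    WETLAND = 2
    SPARSE = 3
    CROPLAND = 4
    URBAN = 5
    BARE = 6
    ICE = 7
    INLAND_WATER = 8
    MARINE = 9


#: Natural / semi-natural classes plus inland water — the terrestrial
#: natural-asset set.  Cropland, urban, bare and ice are never assets.
NATURAL_CLASSES = frozenset(
    {LandCover.FOREST, LandCover.GRASSLAND, LandCover.WETLAND,
     LandCover.SPARSE, LandCover.INLAND_WATER}
)

_DEFAULT_PROPORTIONS = {
    LandCover.FOREST: 0.28,
    LandCover.GRASSLAND: 0.15,
    LandCover.WETLAND: 0.05,
    LandCover.SPARSE: 0.07,
    LandCover.INLAND_WATER: 0.05,
    LandCover.CROPLAND: 0.20,
    LandCover.URBAN: 0.05,
    LandCover.BARE: 0.12,
    LandCover.ICE: 0.03,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic world.

    ``class_proportions`` apply to land cells only (the marine class is
    controlled by ``marine_fraction``) and must sum to 1.
    """

    n_rows: int = 64
    n_cols: int = 64
    cell_size_km: float = 2.0
    marine_fraction: float = 0.20
    class_proportions: dict[LandCover, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    n_regions: int = 4
    n_population_centres: int = 3
    centre_peak_population: float = 30_000.0
    centre_sigma_cells: float = 1.5
    background_population: float = 4.0
    rural_poor_fraction: float = 0.3
    protected_fraction: float = 0.10
    smoothing_sigma: float = 2.0
    elevation_relief_m: float = 300.0
    coast_ramp_m_per_cell: float = 5.0
    base_friction_min_per_km: float = 30.0

    def validate(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ConfigurationError(
                f"grid must be at least 8x8, got {self.n_rows}x{self.n_cols}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ConfigurationError("class proportions must be non-negative")
        if LandCover.MARINE in self.class_proportions:
            raise ConfigurationError("marine share is set via marine_fraction")
        if not 0 <= self.marine_fraction < 1:
            raise ConfigurationError("marine_fraction must be in [0, 1)")
        if not 0 <= self.rural_poor_fraction <= 1:
            raise ConfigurationError("rural_poor_fraction must be in [0, 1]")
        if self.n_regions < 1:
            raise ConfigurationError("need at least one region")

    @property
    def natural_share(self) -> float:
        return sum(p for c, p in self.class_proportions.items() if c in NATURAL_CLASSES)
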