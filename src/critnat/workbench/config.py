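"""Run configuration: every fixed constant of the analysis, surfaced as a
named key with its default, loadable from YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ..synthkit.config import GeneratorConfig, LandCover

__all__ = ["NCPParams", "RunConfig", "load_config", "dump_config"]


@dataclass
class NCPParams:
    """Model constants for the 14 surfaces."""

    # travel / access
    access_max_hours: float = 1.0          # 6.0 for the sensitivity variant
    # retention efficiencies by class
    nitrogen_retention_eff: dict[LandCover, float] = field(default_factory=lambda: {
        LandCover.FOREST: 0.80, LandCover.WETLAND: 0.85, LandCover.GRASSLAND: 0.60,
        LandCover.SPARSE: 0.40, LandCover.INLAND_WATER: 0.50})
    sediment_retention_eff: dict[LandCover, float] = field(default_factory=lambda: {
        LandCover.FOREST: 0.85, LandCover.WETLAND: 0.75, LandCover.GRASSLAND: 0.65,
        LandCover.SPARSE: 0.35, LandCover.INLAND_WATER: 0.60})
    # pollination
    flight_radius_cells: float = 2.0
    # timber / fuelwood
    commercial_max_travel_min: float = 360.0
    commercial_max_slope_pct: float = 70.0
    centre_min_people: float = 50_000.0
    wood_demand_radius_km: float = 10.0
    percap_domestic_timber: float = 0.5
    percap_fuelwood: float = 0.2
    tree_cover: dict[LandCover, float] = field(default_factory=lambda: {
        LandCover.FOREST: 0.9, LandCover.SPARSE: 0.3, LandCover.WETLAND: 0.2})
    # flood
    floodplain_accum_threshold_cells: int = 25
    floodplain_buffer_km: float = 10.0
    storage_index: dict[str, dict[LandCover, float]] = field(default_factory=lambda: {
        "wetland": {LandCover.WETLAND: 1.0, LandCover.INLAND_WATER: 0.9,
                    LandCover.FOREST: 0.2, LandCover.GRASSLAND: 0.1},
        "canopy": {LandCover.FOREST: 0.9, LandCover.WETLAND: 0.4,
                   LandCover.GRASSLAND: 0.3, LandCover.SPARSE: 0.1},
        "soil": {LandCover.FOREST: 0.7, LandCover.GRASSLAND: 0.6,
                 LandCover.WETLAND: 0.8, LandCover.SPARSE: 0.3},
    })
    # coastal
    protective_distance_cells: float = 2.0
    coastal_elevation_cutoff_m: float = 10.0
    habitat_attenuation: float = 0.5
    # carbon
    carbon_vulnerability: dict[LandCover, float] = field(default_factory=lambda: {
        LandCover.FOREST: 0.5, LandCover.WETLAND: 0.7, LandCover.GRASSLAND: 0.3,
        LandCover.SPARSE: 0.2, LandCover.INLAND_WATER: 0.1})
    # moisture
    moisture_direction: tuple[int, int] = (0, 1)
    moisture_max_steps: int = 6
    moisture_decay: float = 0.5
    moisture_recycled_fraction: float = 0.8
    vegetation_frac: dict[LandCover, float] = field(default_factory=lambda: {
        LandCover.FOREST: 0.95, LandCover.WETLAND: 0.8, LandCover.GRASSLAND: 0.7,
        LandCover.SPARSE: 0.3, LandCover.CROPLAND: 0.5, LandCover.INLAND_WATER: 0.2})
    # riverine fish: coefficients used to synthesize the literature basin table
    fish_true_coefficients: tuple[float, float, float, float] = (5.0, 0.8, 0.04, 2.0)
    fish_noise_sd: float = 3.0
    fish_n_basins: int = 40
    fish_catch_per_capita_t: float = 0.02   # sets synthetic national totals


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    ncp: NCPParams = field(default_factory=NCPParams)
    targets_grid: list[float] = field(
        default_factory=lambda: [round(0.05 * k, 2) for k in range(1, 21)])
    main_target: float = 0.9
    solver_policy: str = "greedy"          # "exact" | "greedy" | "auto"
    exact_cell_cap: int = 5000
    n_species: int = 30
    n_languages: int = 12
    seed: int = 1
    output_dir: str = "critnat_run"

    def validate(self) -> None:
        self.generator.validate()
        if not all(0.0 <= t <= 1.0 for t in self.targets_grid):
            raise ValueError("targets_grid must lie in [0, 1]")
        if not 0.0 <= self.main_target <= 1.0:
            raise ValueError("main_target must lie in [0, 1]")
        if self.solver_policy not in ("exact", "greedy", "auto"):
            raise ValueError(f"unknown solver policy {self.solver_policy!r}")
        p = self.ncp
        for name in ("access_max_hours", "commercial_max_travel_min",
                     "commercial_max_slope_pct", "centre_min_people",
                     "wood_demand_radius_km", "coastal_elevation_cutoff_m",
                     "protective_distance_cells", "floodplain_buffer_km"):
            if getattr(p, name) <= 0:
                raise ValueError(f"ncp.{name} must be positive")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {(k.name.lower() if isinstance(k, LandCover) else k): _to_plain(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _class_dict(d: dict) -> dict[LandCover, float]:
    return {LandCover[k.upper()]: float(v) for k, v in d.items()}


def dump_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))
    return path


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gen_raw = raw.get("generator", {})
    if "class_proportions" in gen_raw:
        gen_raw["class_proportions"] = _class_dict(gen_raw["class_proportions"])
    generator = GeneratorConfig(**gen_raw)
    ncp_raw = raw.get("ncp", {})
    for key in ("nitrogen_retention_eff", "sediment_retention_eff", "tree_cover",
                "carbon_vulnerability", "vegetation_frac"):
        if key in ncp_raw:
            ncp_raw[key] = _class_dict(ncp_raw[key])
    if "storage_index" in ncp_raw:
        ncp_raw["storage_index"] = {k: _class_dict(v)
                                    for k, v in ncp_raw["storage_index"].items()}
    for key in ("moisture_direction", "fish_true_coefficients"):
        if key in ncp_raw:
            ncp_raw[key] = tuple(ncp_raw[key])
    ncp = NCPParams(**ncp_raw)
    rest = {k: v for k, v in raw.items() if k not in ("generator", "ncp")}
    config = RunConfig(generator=generator, ncp=ncp, **rest)
    config.validate()
    return config
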