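"""End-to-end orchestration: landscape -> NCP layers -> prioritization ->
beneficiaries -> overlaps, with all artifacts written to an output directory."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import beneficiaries as bn
from .. import overlaps as ov
from .. import prioritizer as pz
from .. import terrain_flow as tf
from .. import travelgraph as tg
from ..grids import GridSpec
from ..ncp_layers import (AssetMask, NCPLayer, access_ncp, carbon_ncp,
                          coastal_ncp, combine_timber, drift_kernel,
                          fit_fish_regression, flood_ncp, fodder_ncp,
                          marine_passthrough, moisture_ncp, pollination_ncp,
                          population_centres, retention_ncp, riverine_fish_ncp,
                          shore_mask, timber_fuelwood_ncp)
from ..synthkit import make_landscape, make_overlays
from ..synthkit.config import NATURAL_CLASSES, LandCover
from ..synthkit.landscape import LandscapeBundle, _smooth_field
from . import io as wio
from .config import RunConfig, dump_config

__all__ = ["PipelineContext", "compute_context", "compute_layers",
           "aggregate_ncp_display", "run_pipeline"]

# auxiliary sub-streams (seed fan-out continues past the synthkit ids)
_AUX_STREAMS = {"coastal_exposure": 40, "marine_fish": 41, "fish_basins": 42,
                "reef_tourism": 43}


def _aux_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, _AUX_STREAMS[name]])


def _class_lut(land_cover: np.ndarray, table: dict[LandCover, float],
               default: float = 0.0) -> np.ndarray:
    lut = np.full(256, default)
    for cls, v in table.items():
        lut[int(cls)] = v
    return lut[land_cover]


@dataclass
class PipelineContext:
    """Everything the downstream stages need, computed once."""

    config: RunConfig
    bundle: LandscapeBundle
    flow: tf.FlowDirection
    downstream_pop: tf.DownstreamPopulation
    floodplain: np.ndarray
    layers: dict[str, NCPLayer]
    fish_regression: object = None
    extras: dict = field(default_factory=dict)

    @property
    def grid(self) -> GridSpec:
        return self.bundle.grid


def compute_layers(bundle: LandscapeBundle, config: RunConfig
                   ) -> tuple[dict[str, NCPLayer], dict]:
    """All 14 surfaces for one landscape; returns (layers, intermediates)."""
    p = config.ncp
    seed = config.seed
    spec = bundle.grid
    lc = bundle.land_cover
    marine = bundle.marine

    flow = tf.d8_directions(bundle.elevation_m, marine, spec)
    downstream_pop = tf.downstream_population(flow, bundle.population)
    floodplain = tf.floodplain_mask(flow, p.floodplain_accum_threshold_cells,
                                    p.floodplain_buffer_km)

    asset_nat = AssetMask.from_landcover(lc, spec)  # natural/semi-natural + inland water
    asset_marine = AssetMask.from_landcover(lc, spec, classes={LandCover.MARINE})
    asset_both = AssetMask.from_landcover(lc, spec,
                                          classes=NATURAL_CLASSES | {LandCover.MARINE})
    asset_forest = AssetMask.from_landcover(lc, spec, classes={LandCover.FOREST})
    asset_graze = AssetMask.from_landcover(
        lc, spec, classes={LandCover.GRASSLAND, LandCover.SPARSE})

    layers: dict[str, NCPLayer] = {}

    layers["nitrogen_retention"] = retention_ncp(
        bundle.fertilizer_load, flow, p.nitrogen_retention_eff, lc, asset_nat,
        downstream_pop, "nitrogen")
    layers["sediment_retention"] = retention_ncp(
        bundle.erosion_load, flow, p.sediment_retention_eff, lc, asset_nat,
        downstream_pop, "sediment")
    layers["pollination"] = pollination_ncp(
        lc, bundle.crop_production, bundle.pollination_dependency, asset_nat,
        flight_radius_cells=p.flight_radius_cells)
    layers["fodder"] = fodder_ncp(bundle.dry_matter_prod, bundle.livestock_demand,
                                  asset_graze)

    urban = lc == int(LandCover.URBAN)
    centres = population_centres(urban, bundle.population, p.centre_min_people)
    travel_centres = (tg.travel_time(bundle.friction_min_per_km, centres, spec)
                      if centres.any() else None)
    slope = tf.slope_percent(bundle.elevation_m, spec)
    rural_mask = bundle.land & ~urban
    wood = timber_fuelwood_ncp(
        bundle.carbon_stock, _class_lut(lc, p.tree_cover), bundle.sequestration_rate,
        travel_centres, slope, bundle.population, rural_mask, bundle.rural_poor,
        asset_forest, max_travel_min=p.commercial_max_travel_min,
        max_slope_pct=p.commercial_max_slope_pct,
        demand_radius_km=p.wood_demand_radius_km,
        percap_domestic=p.percap_domestic_timber, percap_fuelwood=p.percap_fuelwood)
    layers["timber"] = combine_timber(wood["commercial_timber"], wood["domestic_timber"])
    layers["fuelwood"] = wood["fuelwood"]

    layers["flood_regulation"] = flood_ncp(
        _class_lut(lc, p.storage_index["wetland"]),
        _class_lut(lc, p.storage_index["canopy"]),
        _class_lut(lc, p.storage_index["soil"]),
        downstream_pop, asset_nat)

    pop_within = tg.population_within(
        bundle.friction_min_per_km, bundle.population, 60.0 * p.access_max_hours,
        asset_nat.is_asset, spec)
    layers["nature_access"] = access_ncp(pop_within, asset_nat)

    # riverine fish: fit a regression on a synthetic literature table, then
    # disaggregate per-region reported totals over the landscape's basins
    rng = _aux_rng(seed, "fish_basins")
    b0, b1, b2, b3 = p.fish_true_coefficients
    lit = pd.DataFrame({
        "pop_density": rng.uniform(1.0, 60.0, p.fish_n_basins),
        "discharge": rng.uniform(5.0, 400.0, p.fish_n_basins),
        "wetland_pct": rng.uniform(0.0, 30.0, p.fish_n_basins),
    })
    lit["catch_t"] = (b0 + b1 * lit.pop_density + b2 * lit.discharge
                      + b3 * lit.wetland_pct
                      + rng.normal(0.0, p.fish_noise_sd, p.fish_n_basins))
    regression = fit_fish_regression(lit)

    basin_map = tf.basin_labels(flow)
    accum = tf.flow_accumulation(flow)
    cell_area = spec.cell_area_km2
    freshwater = np.isin(lc, [int(LandCover.INLAND_WATER), int(LandCover.WETLAND)])
    rows = []
    for b in np.unique(basin_map[basin_map >= 0]):
        in_basin = basin_map == b
        n = int(in_basin.sum())
        rids, counts = np.unique(bundle.region_id[in_basin], return_counts=True)
        rows.append({
            "basin_id": int(b),
            "region_id": int(rids[np.argmax(counts)]),
            "has_freshwater": bool((in_basin & freshwater).any()),
            "pop_density": float(bundle.population[in_basin].sum()) / (n * cell_area),
            "discharge": float(accum[in_basin].max()),
            "wetland_pct": 100.0 * float((lc[in_basin] == int(LandCover.WETLAND)).sum()) / n,
        })
    basin_table = pd.DataFrame(rows)
    # a region only receives reported catch if some of its basins hold
    # freshwater habitat to spread it over
    fishable = set(basin_table.loc[basin_table.has_freshwater, "region_id"])
    national_totals = {
        rid: (p.fish_catch_per_capita_t
              * float(bundle.population[bundle.region_id == rid].sum())
              if rid in fishable else 0.0)
        for rid in bundle.region_ids()}
    layers["riverine_fish"] = riverine_fish_ncp(
        regression, basin_table, basin_map, freshwater, bundle.region_id,
        national_totals, asset_nat)

    # exogenous marine surfaces
    rng = _aux_rng(seed, "marine_fish")
    catch = np.where(marine, np.clip(2.0 + _smooth_field(rng, spec.shape, 2.0), 0.0, None), 0.0)
    layers["marine_fish"] = marine_passthrough(catch, asset_marine, "marine_fish")

    rng = _aux_rng(seed, "reef_tourism")
    fringe = marine & bn._within_km(bundle.land, 3 * spec.cell_size_km, spec)
    noise = _smooth_field(rng, spec.shape, 1.5)
    deciles = np.zeros(spec.shape)
    if fringe.any():
        ranks = noise[fringe].argsort().argsort()
        deciles[fringe] = 1 + (9 * ranks) // max(ranks.size - 1, 1)
    layers["reef_tourism"] = marine_passthrough(deciles, asset_marine, "reef_tourism")

    # coastal: synthetic exposure with/without habitat attenuation
    rng = _aux_rng(seed, "coastal_exposure")
    shore = shore_mask(bundle.land, marine)
    e_without = np.where(shore, np.clip(0.5 + 0.25 * _smooth_field(rng, spec.shape, 2.0),
                                        0.0, 1.0), 0.0)
    from ..ncp_layers._disc import neighborhood_sum
    n_hab = neighborhood_sum(asset_both.is_asset.astype(float), p.protective_distance_cells)
    atten = p.habitat_attenuation * np.clip(n_hab / 4.0, 0.0, 1.0)
    e_with = np.where(n_hab > 0, e_without * (1.0 - atten), e_without)
    layers["coastal_protection"] = coastal_ncp(
        e_with, e_without, shore, bundle.population, bundle.elevation_m, asset_both,
        protective_distance_cells=p.protective_distance_cells,
        elevation_cutoff_m=p.coastal_elevation_cutoff_m)

    layers["carbon_storage"] = carbon_ncp(bundle.carbon_stock, p.carbon_vulnerability,
                                          lc, asset_nat)
    kernel = drift_kernel(spec, p.moisture_direction, p.moisture_max_steps,
                          p.moisture_decay, p.moisture_recycled_fraction)
    rainfed = np.isin(lc, [int(LandCover.CROPLAND), int(LandCover.GRASSLAND),
                           int(LandCover.FOREST)])
    layers["moisture_recycling"] = moisture_ncp(
        bundle.evapotranspiration, kernel, rainfed,
        _class_lut(lc, p.vegetation_frac), asset_nat)

    extras = {"flow": flow, "downstream_pop": downstream_pop,
              "floodplain": floodplain, "regression": regression,
              "shore": shore, "slope": slope, "asset_nat": asset_nat,
              "asset_marine": asset_marine, "asset_both": asset_both}
    return layers, extras


def compute_context(config: RunConfig) -> PipelineContext:
    config.validate()
    bundle = make_landscape(config.generator, config.seed)
    layers, extras = compute_layers(bundle, config)
    return PipelineContext(
        config=config, bundle=bundle, flow=extras["flow"],
        downstream_pop=extras["downstream_pop"], floodplain=extras["floodplain"],
        layers=layers, fish_regression=extras["regression"], extras=extras)


def aggregate_ncp_display(layers: list[NCPLayer]) -> np.ndarray:
    """Display-only aggregate: sum of per-layer max-normalized surfaces."""
    if not layers:
        raise ValueError("need at least one layer")
    out = np.zeros(layers[0].grid.shape)
    for layer in layers:
        peak = layer.values.max()
        if peak > 0:
            out = out + layer.values / peak
    return out


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the full chain; write rasters, tables and a manifest.

    Returns the manifest dict (also written as ``manifest.json``).  Wall
    times live under ``timings`` so manifests from identical runs compare
    equal after dropping that key.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}, "timings": timings}

    def stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_
            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                return False
        return _T()

    try:
        with stage("simulate"):
            ctx = compute_context(config)
            overlays = make_overlays(ctx.bundle, config.n_species, config.n_languages,
                                     config.seed)
        spec = ctx.grid
        dump_config(config, out / "config.yaml")
        manifest["config_sha256"] = wio.file_sha256(out / "config.yaml")

        with stage("write_inputs"):
            for name, arr in ctx.bundle.raster_items():
                wio.write_raster(out / "landscape" / f"{name}.tif", arr, spec)
            wio.write_region_geojson(out / "regions.geojson", ctx.bundle.region_id, spec)

        with stage("ncp"):
            for name, layer in ctx.layers.items():
                wio.write_raster(out / "ncp" / f"{name}.tif", layer.values, spec)
                wio.write_json(out / "ncp" / f"{name}.json", {
                    "name": layer.name, "scale": layer.scale, "realm": layer.realm,
                    "units": layer.units,
                    "input_sha256": wio.file_sha256(out / "ncp" / f"{name}.tif")})
            local_layers = [ctx.layers[n] for n in
                            ("nitrogen_retention", "sediment_retention", "pollination",
                             "fodder", "timber", "fuelwood", "flood_regulation",
                             "nature_access", "riverine_fish", "marine_fish",
                             "reef_tourism", "coastal_protection")]
            global_layers = [ctx.layers["carbon_storage"], ctx.layers["moisture_recycling"]]
            display = aggregate_ncp_display(local_layers)
            wio.write_raster(out / "ncp" / "aggregate_display.tif", display, spec)

        with stage("prioritize"):
            local_problems = pz.build_problems(local_layers, ctx.bundle.region_id,
                                               ctx.bundle.realm, "country", spec)
            global_problems = pz.build_problems(global_layers, ctx.bundle.region_id,
                                                ctx.bundle.realm, "global", spec)
            policy, cap = config.solver_policy, config.exact_cell_cap
            local_solutions = [pz.solve(pr.with_targets(config.main_target), policy, cap)
                               for pr in local_problems]
            global_solutions = [pz.solve(pr.with_targets(config.main_target), policy, cap)
                                for pr in global_problems]
            for sols in (local_solutions, global_solutions):
                for s in sols:
                    if not pz.audit_solution(s):
                        raise pz.SolverError(
                            f"infeasible solution for region {s.problem.region_id}")
            local_land = np.zeros(spec.shape, dtype=bool)
            local_marine = np.zeros(spec.shape, dtype=bool)
            for s in local_solutions:
                m = s.selected_mask(spec)
                (local_land if s.problem.realm == "land" else local_marine)[m] = True
            global_land = np.zeros(spec.shape, dtype=bool)
            for s in global_solutions:
                global_land |= s.selected_mask(spec)
            wio.write_raster(out / "solutions" / "local_land.tif", local_land, spec)
            wio.write_raster(out / "solutions" / "local_marine.tif", local_marine, spec)
            wio.write_raster(out / "solutions" / "global_land.tif", global_land, spec)
            wio.write_json(out / "solutions" / "achieved.json", {
                f"{s.problem.realm}:{s.problem.region_id}": {
                    "solver": s.solver, "area_km2": s.area_km2,
                    "achieved": dict(zip(s.problem.ncp_names, s.achieved.tolist()))}
                for s in local_solutions + global_solutions})

        with stage("curve"):
            per_region, agg = pz.accumulation_curve(
                local_problems, config.targets_grid, policy, cap)
            agg.as_frame().to_csv(out / "accumulation_curve.csv", index=False)
            pd.concat([c.as_frame().assign(region=label)
                       for label, c in per_region.items()]
                      ).to_csv(out / "accumulation_curve_by_region.csv", index=False)
            _plot_curve(agg, out / "accumulation_curve.png")

        with stage("sensitivity"):
            sens = pz.drop_one_sensitivity(local_problems, config.main_target, policy, cap)
            sens.to_csv(out / "drop_one_sensitivity.csv", index=False)

        with stage("beneficiaries"):
            b = ctx.bundle
            critical = local_land | local_marine
            masks = {}
            for ncp in bn.DELINEABLE_NCP:
                masks[ncp] = bn.benefit_mask(
                    ncp, critical, spec, flow=ctx.flow,
                    friction=b.friction_min_per_km, floodplain=ctx.floodplain,
                    elevation_m=b.elevation_m, rural_poor=b.rural_poor,
                    max_minutes=60.0 * config.ncp.access_max_hours,
                    gather_radius_km=config.ncp.wood_demand_radius_km,
                    protective_distance_cells=config.ncp.protective_distance_cells,
                    elevation_cutoff_m=config.ncp.coastal_elevation_cutoff_m)
            report = bn.count_beneficiaries(masks, critical, b.population, spec)
            wio.write_json(out / "beneficiaries.json", report.as_dict())

        with stage("overlaps"):
            land_area = float(ctx.bundle.land.sum()) * spec.cell_area_km2
            partition = ov.partition_local_global(local_land, global_land,
                                                  land_area, spec.cell_area_km2)
            protected_share = (ov.mask_share(ctx.bundle.protected, local_land)
                               if local_land.any() else float("nan"))
            rule = ov.RepresentationRule()
            n_met, frac_met, sp_table, n_unach = ov.species_coverage(
                overlays, local_land | global_land, rule)
            n_lang, frac_lang = ov.language_coverage(overlays, local_land | global_land)
            sp_table.to_csv(out / "species_coverage.csv", index=False)
            wio.write_json(out / "overlaps.json", {
                "partition": partition, "protected_share_pct": protected_share,
                "species_met": n_met, "species_fraction_met": frac_met,
                "species_unachievable": n_unach,
                "languages_intersecting": n_lang, "language_fraction": frac_lang})

        manifest["stages"] = {
            "local_area_km2": sum(s.area_km2 for s in local_solutions),
            "local_land_cells": int(local_land.sum()),
            "local_marine_cells": int(local_marine.sum()),
            "global_land_cells": int(global_land.sum()),
            "union_beneficiaries": report.union_beneficiaries,
            "residents": report.residents,
            "population_total": report.population_total,
            "languages_intersecting": n_lang,
            "species_met": n_met,
        }
        for path in sorted(out.rglob("*")):
            if path.is_file() and path.suffix in (".tif", ".csv", ".json", ".geojson", ".yaml"):
                if path.name == "manifest.json":
                    continue
                manifest["outputs"][str(path.relative_to(out))] = wio.file_sha256(path)
        wio.write_json(out / "manifest.json", manifest)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc


def _plot_curve(curve, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    frame = curve.as_frame()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(100 * frame.area_fraction_of_assets, 100 * frame.target_level, marker="o")
    ax.set_xlabel("area selected (% of natural assets)")
    ax.set_ylabel("target level met for every NCP (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
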