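"""Per-surface unit tests: hand traces, mass conservation, regression recovery."""

import numpy as np
import pandas as pd
import pytest

from critnat import terrain_flow as tf
from critnat import travelgraph as tg
from critnat.grids import GridSpec
from critnat.ncp_layers import (AssetMask, access_ncp, carbon_ncp, coastal_ncp,
                                combine_timber, drift_kernel,
                                fit_fish_regression, flood_ncp, fodder_ncp,
                                marine_passthrough, moisture_ncp,
                                pollination_ncp, retention_ncp,
                                riverine_fish_ncp, route_retention, shore_mask,
                                sustainable_fraction, timber_fuelwood_ncp)
from critnat.ncp_layers.aquatic import FishRegression
from critnat.synthkit.config import LandCover

from conftest import random_dem

F, G, W, S, C, U, B, I, IW, M = (int(LandCover.FOREST), int(LandCover.GRASSLAND),
                                 int(LandCover.WETLAND), int(LandCover.SPARSE),
                                 int(LandCover.CROPLAND), int(LandCover.URBAN),
                                 int(LandCover.BARE), int(LandCover.ICE),
                                 int(LandCover.INLAND_WATER), int(LandCover.MARINE))


def line_flow(elev, marine=None):
    elev = np.asarray(elev, dtype=float)[None, :]
    spec = GridSpec(1, elev.shape[1])
    if marine is None:
        marine = np.zeros(spec.shape, bool)
    else:
        marine = np.asarray(marine, bool)[None, :]
    return tf.d8_directions(elev, marine, spec), spec


def brute_retention(loads, flow, eff_map, land_cover, asset):
    """Oracle: walk each source's path, intercepting at asset cells."""
    dest = flow.downstream_flat()
    eff = np.zeros(flow.grid.n_cells)
    for cls, e in eff_map.items():
        eff[(land_cover.ravel() == int(cls)) & asset.is_asset.ravel()] = e
    retained = np.zeros(flow.grid.n_cells)
    delivered = 0.0
    for s in range(flow.grid.n_cells):
        mass = loads.ravel()[s]
        if mass == 0 or not flow.land.ravel()[s]:
            continue
        d = dest[s]
        while d >= 0 and flow.land.ravel()[d]:
            kept = eff[d] * mass
            retained[d] += kept
            mass -= kept
            d = dest[d]
        delivered += mass
    return retained.reshape(flow.grid.shape), delivered


class TestRetention:
    def test_hand_trace(self):
        flow, spec = line_flow([3.0, 2.0, 1.0])
        lc = np.array([[B, F, B]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        dp = tf.downstream_population(flow, np.array([[0.0, 0.0, 7.0]]))
        layer = retention_ncp(np.array([[10.0, 0.0, 0.0]]), flow,
                              {LandCover.FOREST: 0.6}, lc, asset, dp, "nitrogen")
        np.testing.assert_allclose(layer.values, [[0.0, 42.0, 0.0]])

    def test_zero_efficiency_delivers_everything(self):
        flow, spec = line_flow([3.0, 2.0, 1.0])
        lc = np.array([[F, F, F]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        loads = np.array([[10.0, 5.0, 1.0]])
        retained, delivered = route_retention(loads, flow, {LandCover.FOREST: 0.0},
                                              lc, asset)
        assert (retained == 0).all()
        assert delivered == pytest.approx(16.0)

    def test_efficiency_out_of_range_raises(self):
        flow, spec = line_flow([3.0, 2.0, 1.0])
        lc = np.array([[F, F, F]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            route_retention(np.ones(spec.shape), flow, {LandCover.FOREST: 1.5},
                            lc, asset)

    @pytest.mark.parametrize("seed", range(10))
    def test_mass_conservation_and_oracle(self, seed):
        rng = np.random.default_rng(seed)
        elev, marine = random_dem(rng, 8, 8)
        spec = GridSpec(8, 8)
        flow = tf.d8_directions(tf.fill_pits(elev, marine, spec), marine, spec)
        lc = np.where(marine, M, rng.choice([F, G, B, C], (8, 8))).astype(np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        loads = np.where(~marine, rng.uniform(0, 10, (8, 8)), 0.0)
        eff = {LandCover.FOREST: 0.7, LandCover.GRASSLAND: 0.4}
        retained, delivered = route_retention(loads, flow, eff, lc, asset)
        assert retained.sum() + delivered == pytest.approx(loads.sum(), rel=1e-9)
        oracle_ret, oracle_dlv = brute_retention(loads, flow, eff, lc, asset)
        np.testing.assert_allclose(retained, oracle_ret, rtol=1e-9, atol=1e-12)
        assert delivered == pytest.approx(oracle_dlv, rel=1e-9)

    def test_monotone_in_population(self):
        flow, spec = line_flow([4.0, 3.0, 2.0, 1.0])
        lc = np.array([[B, F, W, B]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        loads = np.array([[8.0, 0.0, 0.0, 0.0]])
        eff = {LandCover.FOREST: 0.5, LandCover.WETLAND: 0.5}
        pop1 = np.array([[0.0, 0.0, 1.0, 5.0]])
        layer1 = retention_ncp(loads, flow, eff, lc, asset,
                               tf.downstream_population(flow, pop1), "sediment")
        layer2 = retention_ncp(loads, flow, eff, lc, asset,
                               tf.downstream_population(flow, pop1 * 2), "sediment")
        assert (layer2.values >= layer1.values).all()


class TestPollination:
    def test_hand_trace_two_habitat_cells(self):
        spec = GridSpec(1, 3)
        lc = np.array([[F, C, F]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        layer = pollination_ncp(lc, np.array([[0.0, 100.0, 0.0]]),
                                np.array([[0.0, 0.5, 0.0]]), asset,
                                flight_radius_cells=1)
        # both in-range cells natural -> sufficiency 1, realized 50, 25 each
        np.testing.assert_allclose(layer.values, [[25.0, 0.0, 25.0]])

    def test_zero_dependency(self, small_bundle):
        asset = AssetMask.from_landcover(small_bundle.land_cover, small_bundle.grid)
        layer = pollination_ncp(small_bundle.land_cover, small_bundle.crop_production,
                                np.zeros(small_bundle.grid.shape), asset)
        assert (layer.values == 0).all()

    def test_no_habitat_in_radius_no_credits(self):
        spec = GridSpec(1, 3)
        lc = np.array([[C, C, C]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        layer = pollination_ncp(lc, np.full(spec.shape, 10.0),
                                np.full(spec.shape, 0.8), asset,
                                flight_radius_cells=1)
        assert (layer.values == 0).all()

    def test_partial_sufficiency(self):
        # crop cell with one natural and one bare neighbour: sufficiency 1/2
        spec = GridSpec(1, 3)
        lc = np.array([[F, C, B]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        layer = pollination_ncp(lc, np.array([[0.0, 100.0, 0.0]]),
                                np.array([[0.0, 0.5, 0.0]]), asset,
                                flight_radius_cells=1)
        np.testing.assert_allclose(layer.values, [[25.0, 0.0, 0.0]])

    def test_population_equiv_scaling(self):
        spec = GridSpec(1, 3)
        lc = np.array([[F, C, F]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        base = pollination_ncp(lc, np.array([[0.0, 100.0, 0.0]]),
                               np.array([[0.0, 0.5, 0.0]]), asset, 1)
        scaled = pollination_ncp(lc, np.array([[0.0, 100.0, 0.0]]),
                                 np.array([[0.0, 0.5, 0.0]]), asset, 1,
                                 population_equiv=0.1)
        np.testing.assert_allclose(scaled.values, base.values * 0.1)


class TestFodder:
    def test_min_supply_demand(self):
        spec = GridSpec(1, 2)
        lc = np.array([[G, G]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec, classes={LandCover.GRASSLAND})
        layer = fodder_ncp(np.array([[5.0, 2.0]]), np.array([[3.0, 3.0]]), asset)
        # realized [3, 2], rescaled by max -> [1, 2/3]
        np.testing.assert_allclose(layer.values, [[1.0, 2.0 / 3.0]])

    def test_rescale_example(self):
        spec = GridSpec(1, 2)
        lc = np.array([[G, G]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec, classes={LandCover.GRASSLAND})
        layer = fodder_ncp(np.array([[3.0, 6.0]]), np.array([[99.0, 99.0]]), asset)
        np.testing.assert_allclose(layer.values, [[0.5, 1.0]])

    def test_all_zero_warns_and_zeroes(self):
        spec = GridSpec(1, 2)
        lc = np.array([[G, G]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec, classes={LandCover.GRASSLAND})
        with pytest.warns(UserWarning, match="all-zero"):
            layer = fodder_ncp(np.zeros(spec.shape), np.zeros(spec.shape), asset)
        assert (layer.values == 0).all()


class TestTimberFuelwood:
    @pytest.fixture
    def fixture(self):
        spec = GridSpec(1, 4)
        lc = np.array([[F, F, F, F]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec, classes={LandCover.FOREST})
        stock = np.full(spec.shape, 100.0)
        rate = np.full(spec.shape, 2.0)
        cover = np.full(spec.shape, 1.0)
        pop = np.full(spec.shape, 10.0)
        rural = np.ones(spec.shape, bool)
        poor = np.full(spec.shape, 5.0)
        return spec, asset, stock, rate, cover, pop, rural, poor

    def test_sustainable_fraction_reciprocal(self):
        assert sustainable_fraction(np.array([100.0]), np.array([2.0]))[0] == pytest.approx(0.02)
        assert sustainable_fraction(np.array([100.0]), np.array([0.0]))[0] == 0.0

    def test_travel_and_slope_cutoffs_exact(self, fixture):
        spec, asset, stock, rate, cover, pop, rural, poor = fixture
        minutes = np.array([[100.0, 360.0, 361.0, 100.0]])
        travel = tg.TravelField(grid=spec, minutes=minutes,
                                sources=np.zeros(spec.shape, bool))
        slope = np.array([[10.0, 10.0, 10.0, 70.0]])  # last: exactly 70 -> excluded
        wood = timber_fuelwood_ncp(stock, cover, rate, travel, slope, pop,
                                   rural, poor, asset)
        com = wood["commercial_timber"].values[0]
        assert com[0] > 0 and com[1] > 0      # 360 min exactly is within 6 h
        assert com[2] == 0                    # 361 min is out
        assert com[3] == 0                    # slope 70 exactly is out
        dom = wood["domestic_timber"].values[0]
        assert dom[2] > 0 and dom[3] > 0      # commercial-inaccessible
        assert dom[0] == 0 and dom[1] == 0    # mutual exclusivity
        assert (wood["fuelwood"].values >= 0).all()

    def test_no_centre_means_no_commercial(self, fixture):
        spec, asset, stock, rate, cover, pop, rural, poor = fixture
        wood = timber_fuelwood_ncp(stock, cover, rate, None,
                                   np.zeros(spec.shape), pop, rural, poor, asset)
        assert (wood["commercial_timber"].values == 0).all()
        assert (wood["domestic_timber"].values > 0).all()

    def test_combined_layer(self, fixture):
        spec, asset, stock, rate, cover, pop, rural, poor = fixture
        minutes = np.array([[100.0, 100.0, 900.0, 900.0]])
        travel = tg.TravelField(grid=spec, minutes=minutes,
                                sources=np.zeros(spec.shape, bool))
        wood = timber_fuelwood_ncp(stock, cover, rate, travel,
                                   np.zeros(spec.shape), pop, rural, poor, asset)
        timber = combine_timber(wood["commercial_timber"], wood["domestic_timber"])
        np.testing.assert_allclose(
            timber.values,
            wood["commercial_timber"].values + wood["domestic_timber"].values)

    def test_negative_slope_raises(self, fixture):
        spec, asset, stock, rate, cover, pop, rural, poor = fixture
        with pytest.raises(ValueError, match="slope"):
            timber_fuelwood_ncp(stock, cover, rate, None,
                                np.full(spec.shape, -1.0), pop, rural, poor, asset)


class TestFlood:
    def test_hand_trace(self):
        flow, spec = line_flow([3.0, 2.0, 1.0])
        lc = np.array([[W, B, B]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        dp = tf.DownstreamPopulation(grid=spec, people_downstream=np.array([[10.0, 0.0, 0.0]]))
        layer = flood_ncp(np.array([[0.6, 0, 0]]), np.array([[0.3, 0, 0]]),
                          np.array([[0.6, 0, 0]]), dp, asset)
        assert layer.values[0, 0] == pytest.approx(5.0)  # mean 0.5 x 10

    def test_zero_downstream_zero_value(self):
        flow, spec = line_flow([3.0, 2.0, 1.0])
        lc = np.array([[W, W, W]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        dp = tf.DownstreamPopulation(grid=spec, people_downstream=np.zeros(spec.shape))
        layer = flood_ncp(*(np.full(spec.shape, 1.0),) * 3, dp, asset)
        assert (layer.values == 0).all()

    def test_unit_components_pass_population_through(self):
        spec = GridSpec(1, 2)
        lc = np.array([[W, W]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        dp = tf.DownstreamPopulation(grid=spec, people_downstream=np.array([[7.0, 3.0]]))
        layer = flood_ncp(*(np.ones(spec.shape),) * 3, dp, asset)
        np.testing.assert_allclose(layer.values, [[7.0, 3.0]])

    def test_out_of_range_component_raises(self):
        spec = GridSpec(1, 2)
        lc = np.array([[W, W]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        dp = tf.DownstreamPopulation(grid=spec, people_downstream=np.ones(spec.shape))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            flood_ncp(np.full(spec.shape, 1.2), np.ones(spec.shape),
                      np.ones(spec.shape), dp, asset)


class TestAccess:
    def test_passthrough_and_mask(self):
        spec = GridSpec(1, 2)
        lc = np.array([[F, C]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        layer = access_ncp(np.array([[12.0, 99.0]]), asset)
        np.testing.assert_allclose(layer.values, [[12.0, 0.0]])

    def test_monotone_in_budget(self, small_bundle):
        asset = AssetMask.from_landcover(small_bundle.land_cover, small_bundle.grid)
        kw = dict(targets=asset.is_asset, spec=small_bundle.grid)
        p60 = tg.population_within(small_bundle.friction_min_per_km,
                                   small_bundle.population, 60.0, **kw)
        p120 = tg.population_within(small_bundle.friction_min_per_km,
                                    small_bundle.population, 120.0, **kw)
        a60 = access_ncp(p60, asset)
        a120 = access_ncp(p120, asset)
        assert (a120.values >= a60.values - 1e-9).all()


class TestFishRegression:
    @staticmethod
    def synth_table(rng, n, coefs=(2.0, 0.5, 0.03, 1.5), noise=0.0):
        b0, b1, b2, b3 = coefs
        t = pd.DataFrame({
            "pop_density": rng.uniform(1, 80, n),
            "discharge": rng.uniform(1, 500, n),
            "wetland_pct": rng.uniform(0, 40, n),
        })
        t["catch_t"] = (b0 + b1 * t.pop_density + b2 * t.discharge
                        + b3 * t.wetland_pct + rng.normal(0, noise, n))
        return t

    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        fit = fit_fish_regression(self.synth_table(rng, 30))
        assert fit.intercept == pytest.approx(2.0, abs=1e-8)
        assert fit.coefficients["pop_density"] == pytest.approx(0.5, abs=1e-8)
        assert fit.coefficients["discharge"] == pytest.approx(0.03, abs=1e-8)
        assert fit.coefficients["wetland_pct"] == pytest.approx(1.5, abs=1e-8)

    def test_simulation_bias_within_two_se(self):
        # 500 replicates at n=40 with noise: mean estimate close to truth
        rng = np.random.default_rng(42)
        coefs = np.array([2.0, 0.5, 0.03, 1.5])
        estimates = np.empty((500, 4))
        for k in range(500):
            fit = fit_fish_regression(self.synth_table(rng, 40, tuple(coefs), noise=5.0))
            estimates[k] = [fit.intercept, fit.coefficients["pop_density"],
                            fit.coefficients["discharge"], fit.coefficients["wetland_pct"]]
        mean = estimates.mean(axis=0)
        se_of_mean = estimates.std(axis=0, ddof=1) / np.sqrt(500)
        assert (np.abs(mean - coefs) <= 2 * se_of_mean + 1e-12).all()

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(3)
        fit = fit_fish_regression(self.synth_table(rng, 40, noise=20.0))
        expected = 1 - (1 - fit.r_squared) * (40 - 1) / (40 - 3 - 1)
        assert fit.r_squared_adj == pytest.approx(expected, abs=1e-12)
        # frozen arithmetic check of the formula itself
        assert 1 - 0.3 * 39 / 36 == pytest.approx(0.675)

    def test_too_few_rows_raises(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="at least 5"):
            fit_fish_regression(self.synth_table(rng, 4))

    def test_singular_design_raises(self):
        t = pd.DataFrame({
            "pop_density": [1.0] * 8, "discharge": [2.0] * 8,
            "wetland_pct": [3.0] * 8, "catch_t": [1.0] * 8})
        with pytest.raises(ValueError, match="singular"):
            fit_fish_regression(t)


class TestRiverineFish:
    @pytest.fixture
    def setup(self):
        spec = GridSpec(1, 4)
        lc = np.array([[IW, IW, IW, IW]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        fresh = np.ones(spec.shape, bool)
        basin_map = np.array([[0, 0, 1, 1]])
        region = np.array([[1, 1, 1, 1]], np.int32)
        return spec, asset, fresh, basin_map, region

    @staticmethod
    def reg(intercept=0.0, pd_=1.0, q=0.0, w=0.0):
        return FishRegression(intercept=intercept,
                              coefficients={"pop_density": pd_, "discharge": q,
                                            "wetland_pct": w},
                              r_squared=1.0, r_squared_adj=1.0, n_obs=40)

    def test_single_basin_gets_regional_total(self):
        spec = GridSpec(1, 2)
        lc = np.array([[IW, IW]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        table = pd.DataFrame({"basin_id": [0], "region_id": [1],
                              "pop_density": [5.0], "discharge": [0.0],
                              "wetland_pct": [0.0]})
        layer = riverine_fish_ncp(self.reg(), table, np.zeros(spec.shape, int),
                                  np.ones(spec.shape, bool),
                                  np.ones(spec.shape, np.int32), {1: 120.0}, asset)
        # 120 t over 2 cells x 4 km2
        assert layer.values.sum() * spec.cell_area_km2 == pytest.approx(120.0)

    def test_two_basins_split_proportionally(self, setup):
        spec, asset, fresh, basin_map, region = setup
        table = pd.DataFrame({"basin_id": [0, 1], "region_id": [1, 1],
                              "pop_density": [2.0, 1.0], "discharge": [0, 0],
                              "wetland_pct": [0, 0]})
        layer = riverine_fish_ncp(self.reg(), table, basin_map, fresh, region,
                                  {1: 90.0}, asset)
        basin0 = layer.values[0, :2].sum() * spec.cell_area_km2
        basin1 = layer.values[0, 2:].sum() * spec.cell_area_km2
        assert basin0 == pytest.approx(60.0)
        assert basin1 == pytest.approx(30.0)

    def test_negative_prediction_floored(self, setup):
        spec, asset, fresh, basin_map, region = setup
        table = pd.DataFrame({"basin_id": [0, 1], "region_id": [1, 1],
                              "pop_density": [-5.0, 1.0], "discharge": [0, 0],
                              "wetland_pct": [0, 0]})
        layer = riverine_fish_ncp(self.reg(), table, basin_map, fresh, region,
                                  {1: 50.0}, asset)
        assert (layer.values[0, :2] == 0).all()
        assert layer.values[0, 2:].sum() * spec.cell_area_km2 == pytest.approx(50.0)

    def test_zero_prediction_with_reported_catch_raises(self, setup):
        spec, asset, fresh, basin_map, region = setup
        table = pd.DataFrame({"basin_id": [0, 1], "region_id": [1, 1],
                              "pop_density": [0.0, 0.0], "discharge": [0, 0],
                              "wetland_pct": [0, 0]})
        with pytest.raises(ValueError, match="zero predicted"):
            riverine_fish_ncp(self.reg(), table, basin_map, fresh, region,
                              {1: 50.0}, asset)


class TestMarinePassthrough:
    def test_passthrough_and_mask(self):
        spec = GridSpec(1, 2)
        lc = np.array([[M, F]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec, classes={LandCover.MARINE})
        layer = marine_passthrough(np.array([[3.2, 5.0]]), asset, "marine_fish")
        np.testing.assert_allclose(layer.values, [[3.2, 0.0]])

    def test_bookkeeping(self):
        spec = GridSpec(1, 3)
        lc = np.array([[M, M, F]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec, classes={LandCover.MARINE})
        raw = np.array([[1.0, 2.0, 4.0]])
        layer = marine_passthrough(raw, asset, "reef_tourism")
        assert raw.sum() - layer.values.sum() == pytest.approx(4.0)


class TestCoastal:
    def test_hand_trace_split_between_two_habitat_cells(self):
        spec = GridSpec(1, 4)
        # [marine-habitat, shore, habitat, bare]; population 40 on the shore, low-lying
        lc = np.array([[M, B, F, B]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec,
                                         classes={LandCover.MARINE, LandCover.FOREST})
        shore = np.array([[False, True, False, False]])
        e_without = np.array([[0.0, 0.8, 0.0, 0.0]])
        e_with = np.array([[0.0, 0.3, 0.0, 0.0]])
        pop = np.array([[0.0, 40.0, 0.0, 0.0]])
        elev = np.array([[-5.0, 2.0, 3.0, 4.0]])
        layer = coastal_ncp(e_with, e_without, shore, pop, elev, asset,
                            protective_distance_cells=1.0)
        # risk reduced 0.5 x 40 people = 20, split between the 2 in-range habitat cells
        np.testing.assert_allclose(layer.values, [[10.0, 0.0, 10.0, 0.0]])

    def test_population_above_cutoff_excluded(self):
        spec = GridSpec(1, 3)
        lc = np.array([[M, B, F]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec,
                                         classes={LandCover.MARINE, LandCover.FOREST})
        shore = np.array([[False, True, False]])
        layer = coastal_ncp(np.array([[0, 0.3, 0]]), np.array([[0, 0.8, 0]]),
                            shore, np.array([[0.0, 40.0, 0.0]]),
                            np.array([[-5.0, 12.0, 3.0]]), asset,
                            protective_distance_cells=1.0)
        assert (layer.values == 0).all()

    def test_exposure_order_violation_raises(self):
        spec = GridSpec(1, 2)
        lc = np.array([[M, B]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec, classes={LandCover.MARINE})
        shore = np.array([[False, True]])
        with pytest.raises(ValueError, match="exceeds"):
            coastal_ncp(np.array([[0.0, 0.9]]), np.array([[0.0, 0.5]]), shore,
                        np.zeros(spec.shape), np.zeros(spec.shape), asset)

    def test_shore_mask(self):
        land = np.array([[True, True, False]])
        marine = ~land
        np.testing.assert_array_equal(shore_mask(land, marine),
                                      [[False, True, False]])


class TestCarbon:
    def test_product(self):
        spec = GridSpec(1, 1, cell_size_km=2.0)  # 400 ha cell
        lc = np.full(spec.shape, F, np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        layer = carbon_ncp(np.array([[120.0]]), {LandCover.FOREST: 0.5}, lc, asset)
        assert layer.values[0, 0] == pytest.approx(24_000.0)
        assert layer.scale == "global"

    def test_zero_vulnerability(self):
        spec = GridSpec(1, 1)
        lc = np.full(spec.shape, F, np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        layer = carbon_ncp(np.array([[120.0]]), {LandCover.FOREST: 0.0}, lc, asset)
        assert (layer.values == 0).all()

    def test_missing_class_raises(self):
        spec = GridSpec(1, 2)
        lc = np.array([[F, W]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        with pytest.raises(KeyError):
            carbon_ncp(np.ones(spec.shape), {LandCover.FOREST: 0.5}, lc, asset)

    def test_bounded_by_stock_times_area(self, small_bundle):
        asset = AssetMask.from_landcover(small_bundle.land_cover, small_bundle.grid)
        vuln = {c: 1.0 for c in (LandCover.FOREST, LandCover.GRASSLAND,
                                 LandCover.WETLAND, LandCover.SPARSE,
                                 LandCover.INLAND_WATER)}
        layer = carbon_ncp(small_bundle.carbon_stock, vuln,
                           small_bundle.land_cover, asset)
        cap = small_bundle.carbon_stock.sum() * small_bundle.grid.cell_area_km2 * 100
        assert layer.values.sum() <= cap + 1e-6


class TestMoisture:
    def test_identity_kernel(self):
        from scipy import sparse
        spec = GridSpec(2, 2)
        lc = np.full(spec.shape, F, np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        et = np.array([[100.0, 200.0], [300.0, 400.0]])
        veg = np.full(spec.shape, 0.5)
        layer = moisture_ncp(et, sparse.identity(4), np.ones(spec.shape, bool),
                             veg, asset)
        np.testing.assert_allclose(layer.values, et * 0.5)

    def test_empty_rainfed_mask(self):
        from scipy import sparse
        spec = GridSpec(2, 2)
        lc = np.full(spec.shape, F, np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        layer = moisture_ncp(np.full(spec.shape, 100.0), sparse.identity(4),
                             np.zeros(spec.shape, bool), np.ones(spec.shape), asset)
        assert (layer.values == 0).all()

    def test_conservation_random_kernel(self):
        from scipy import sparse
        rng = np.random.default_rng(5)
        spec = GridSpec(4, 4)
        lc = np.full(spec.shape, F, np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        raw = rng.random((16, 16))
        kernel = sparse.csr_matrix(raw / raw.sum(axis=1, keepdims=True) * 0.9)
        et = rng.uniform(100, 500, spec.shape)
        veg = rng.uniform(0, 1, spec.shape)
        layer = moisture_ncp(et, kernel, np.ones(spec.shape, bool), veg, asset)
        assert layer.values.sum() <= (et * veg).sum() + 1e-9
        # equality when rows sum to exactly 1 and every cell is a receptor
        kernel1 = sparse.csr_matrix(raw / raw.sum(axis=1, keepdims=True))
        layer1 = moisture_ncp(et, kernel1, np.ones(spec.shape, bool), veg, asset)
        assert layer1.values.sum() == pytest.approx((et * veg).sum(), rel=1e-9)

    def test_row_sum_violation_raises(self):
        from scipy import sparse
        spec = GridSpec(2, 2)
        lc = np.full(spec.shape, F, np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        with pytest.raises(ValueError, match="row sums"):
            moisture_ncp(np.ones(spec.shape), sparse.identity(4) * 1.5,
                         np.ones(spec.shape, bool), np.ones(spec.shape), asset)

    def test_drift_kernel_conservative(self):
        spec = GridSpec(5, 5)
        kernel = drift_kernel(spec)
        sums = np.asarray(kernel.sum(axis=1)).ravel()
        assert (sums <= 0.8 + 1e-12).all()


class TestLayerContracts:
    """Every one of the 14 surfaces on a full synthetic landscape."""

    def test_all_layers_nonneg_finite_masked(self, small_context):
        assert len(small_context.layers) == 14
        for name, layer in small_context.layers.items():
            assert (layer.values >= 0).all(), name
            assert np.isfinite(layer.values).all(), name
            assert (layer.values[~layer.asset.is_asset] == 0).all(), name

    def test_scales_and_realms(self, small_context):
        layers = small_context.layers
        assert layers["carbon_storage"].scale == "global"
        assert layers["moisture_recycling"].scale == "global"
        assert sum(1 for l in layers.values() if l.scale == "country") == 12
        assert layers["marine_fish"].realm == "marine"
        assert layers["coastal_protection"].realm == "both"

    def test_fish_region_relabel_covariance(self):
        # relabelling region ids (with totals relabelled alongside) leaves the
        # disaggregated surface unchanged — region enters only via the rescale
        spec = GridSpec(1, 4)
        lc = np.array([[IW, IW, IW, IW]], np.uint8)
        asset = AssetMask.from_landcover(lc, spec)
        basin_map = np.array([[0, 0, 1, 1]])
        reg = TestRiverineFish.reg()
        table = pd.DataFrame({"basin_id": [0, 1], "region_id": [1, 2],
                              "pop_density": [2.0, 1.0], "discharge": [0, 0],
                              "wetland_pct": [0, 0]})
        region_a = np.array([[1, 1, 2, 2]], np.int32)
        layer_a = riverine_fish_ncp(reg, table, basin_map, np.ones(spec.shape, bool),
                                    region_a, {1: 10.0, 2: 20.0}, asset)
        table_b = table.assign(region_id=[7, 3])
        region_b = np.array([[7, 7, 3, 3]], np.int32)
        layer_b = riverine_fish_ncp(reg, table_b, basin_map, np.ones(spec.shape, bool),
                                    region_b, {7: 10.0, 3: 20.0}, asset)
        np.testing.assert_allclose(layer_a.values, layer_b.values)
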