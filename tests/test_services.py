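import numpy as np
import pytest

from luces.grid import LandCoverGrid, Raster, RasterStack
from luces.services import (
    DEFAULT_CARBON_DENSITY,
    ErosionParams,
    WaterYieldParams,
    assess_all,
    carbon_stock,
    carbon_stock_from_areas,
    d8_flow,
    ls_factor,
    soil_budget,
    water_yield,
)
from luces.study import COMPOSITIONS

from conftest import random_landcover


def climate_stack(shape, p=500.0, et0=800.0, awc=250.0):
    return RasterStack({
        "precipitation": Raster(np.full(shape, p)),
        "et0": Raster(np.full(shape, et0)),
        "awc": Raster(np.full(shape, awc)),
    })


UNIT_KC = {k: 1.25 for k in DEFAULT_CARBON_DENSITY}


class TestWaterYield:
    def test_budyko_worked_cell(self):
        """P=500, ET0=800, Kc=1.25, AWC=250, Z=1: TPE=1000, R=2, w=1.75,
        TAE/P = 4.5/5 = 0.9, so Y = 50 mm."""
        grid = LandCoverGrid(np.full((3, 3), 3))  # forest (vegetated)
        res = water_yield(climate_stack((3, 3)), grid, WaterYieldParams(kc=UNIT_KC, z=1.0))
        assert np.allclose(res.rasters["water_yield_mm"], 50.0)
        assert np.allclose(res.rasters["tae_mm"], 450.0)
        # 50 mm over 9 cells of 900 m²
        assert res.totals["WY_m3"] == pytest.approx(50.0 * 9 * 900 / 1000)

    def test_non_vegetated_clamp_gives_zero_yield(self):
        grid = LandCoverGrid(np.full((3, 3), 7))  # open water
        res = water_yield(climate_stack((3, 3)), grid, WaterYieldParams(kc=UNIT_KC, z=1.0))
        assert np.allclose(res.rasters["tae_mm"], 500.0)  # min(1000, 500) = P
        assert np.allclose(res.rasters["water_yield_mm"], 0.0)

    def test_wet_limit_yield_approaches_precipitation(self):
        grid = LandCoverGrid(np.full((3, 3), 3))
        stack = climate_stack((3, 3), p=1e6, et0=800.0, awc=250.0)
        res = water_yield(stack, grid, WaterYieldParams(kc=UNIT_KC, z=1.0))
        assert np.all(res.rasters["tae_mm"] / 1e6 < 0.01)
        assert np.allclose(res.rasters["water_yield_mm"], 1e6, rtol=0.01)

    def test_nonpositive_precipitation_names_the_cell(self):
        stack = climate_stack((3, 3))
        stack["precipitation"].values[1, 2] = 0.0
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            water_yield(stack, LandCoverGrid(np.full((3, 3), 3)), WaterYieldParams())

    def test_negative_awc_rejected(self):
        stack = climate_stack((3, 3), awc=-1.0)
        with pytest.raises(ValueError, match="water content"):
            water_yield(stack, LandCoverGrid(np.full((3, 3), 3)), WaterYieldParams())

    def test_evapotranspiration_bounded_by_precipitation(self):
        """0 ≤ TAE ≤ P on random climates for every class."""
        rng = np.random.default_rng(8)
        shape = (40, 40)
        stack = RasterStack({
            "precipitation": Raster(rng.uniform(200, 1200, shape)),
            "et0": Raster(rng.uniform(500, 1500, shape)),
            "awc": Raster(rng.uniform(50, 400, shape)),
        })
        grid = random_landcover(9, shape=shape)
        res = water_yield(stack, grid, WaterYieldParams())
        tae = res.rasters["tae_mm"]
        assert np.all(tae >= 0)
        assert np.all(tae <= stack["precipitation"].values + 1e-9)

    def test_total_yield_monotone_nonincreasing_in_z(self, lucc_small, terrain_small):
        stack = RasterStack({
            "precipitation": terrain_small["precipitation"],
            "et0": terrain_small["et0"],
            "awc": terrain_small["awc"],
        })
        totals = [
            water_yield(stack, lucc_small, WaterYieldParams(z=z)).totals["WY_m3"]
            for z in (1.0, 5.0, 9.0, 20.0)
        ]
        assert all(a >= b - 1e-6 for a, b in zip(totals, totals[1:]))


class TestLSFactor:
    def test_flat_dem_gives_zero(self):
        assert np.allclose(ls_factor(Raster(np.full((6, 6), 100.0))), 0.0)

    def test_single_cell_catchment_on_tilted_plane(self):
        # plane rising 1 m per 30 m cell northward; row 0 cells receive no flow
        rows = np.arange(12)[::-1].astype(float)
        dem = Raster(np.tile(rows[:, None], (1, 12)), cell_size=30.0)
        ls = ls_factor(dem)
        _, acc = d8_flow(dem.values, 30.0)
        assert np.all(acc[0, :] == 1)
        # hand evaluation: edge-replicated Horn slope on row 0 is
        # arctan(1/60); A_f = 1
        theta = np.arctan(1.0 / 60.0)
        expected = (30.0 / 22.13) ** 0.4 * (np.sin(theta) / 0.0896) ** 1.3
        assert np.allclose(ls[0, 1:-1], expected, rtol=1e-9)

    def test_monotone_in_flow_accumulation_at_fixed_slope(self):
        # down a uniform plane, accumulation grows along each column
        rows = np.arange(15)[::-1].astype(float)
        dem = Raster(np.tile(rows[:, None], (1, 9)), cell_size=30.0)
        ls = ls_factor(dem)
        interior = ls[1:-1, 4]
        assert np.all(np.diff(interior) > 0)

    def test_d8_ties_resolved_deterministically(self):
        rng = np.random.default_rng(3)
        dem = rng.random((10, 10))
        r1, a1 = d8_flow(dem, 30.0)
        r2, a2 = d8_flow(dem, 30.0)
        assert np.array_equal(r1, r2) and np.array_equal(a1, a2)


def erosion_stack(shape, dem, r=100.0, k=0.3):
    return RasterStack({
        "dem": Raster(dem, cell_size=30.0),
        "erosivity": Raster(np.full(shape, r), cell_size=30.0),
        "erodibility": Raster(np.full(shape, k), cell_size=30.0),
    })


class TestSoilBudget:
    def test_direct_substitution_single_cell(self):
        """R=100, K=0.3, LS=2, C=0.1, P=0.5, no incoming sediment:
        USLE=60, RUSLE=3, SEDRET=57 t/ha."""
        shape = (3, 3)
        stack = erosion_stack(shape, np.full(shape, 10.0))  # flat: no routing
        grid = LandCoverGrid(np.full(shape, 1), cell_size=30.0)
        params = ErosionParams(
            c_factor={**{k: 0.0 for k in DEFAULT_CARBON_DENSITY}, "CL": 0.1},
            p_factor={**{k: 1.0 for k in DEFAULT_CARBON_DENSITY}, "CL": 0.5},
            retention_efficiency={k: 0.0 for k in DEFAULT_CARBON_DENSITY},
        )
        res = soil_budget(stack, grid, params, ls=np.full(shape, 2.0))
        assert np.allclose(res.rasters["usle_t_ha"], 60.0)
        assert np.allclose(res.rasters["rusle_t_ha"], 3.0)
        assert np.allclose(res.rasters["sedret_t_ha"], 57.0)

    def test_bare_practice_collapse_sedret_equals_sed(self):
        """With C = P = 1 everywhere, RUSLE = USLE so SEDRET = SED cellwise."""
        rng = np.random.default_rng(5)
        shape = (15, 15)
        stack = erosion_stack(shape, rng.random(shape) * 50)
        grid = random_landcover(12, shape=shape)
        params = ErosionParams(
            c_factor={k: 1.0 for k in DEFAULT_CARBON_DENSITY},
            p_factor={k: 1.0 for k in DEFAULT_CARBON_DENSITY},
        )
        res = soil_budget(stack, grid, params)
        assert np.allclose(res.rasters["sedret_t_ha"], res.rasters["sed_t_ha"])

    def test_zero_retention_sums_to_potential_minus_actual(self):
        rng = np.random.default_rng(6)
        shape = (12, 12)
        stack = erosion_stack(shape, rng.random(shape) * 80)
        grid = random_landcover(13, shape=shape)
        params = ErosionParams(retention_efficiency={k: 0.0 for k in DEFAULT_CARBON_DENSITY})
        res = soil_budget(stack, grid, params)
        diff = res.rasters["usle_t_ha"] - res.rasters["rusle_t_ha"]
        assert np.nansum(res.rasters["sedret_t_ha"]) == pytest.approx(np.nansum(diff))

    def test_three_cell_cascade_hand_traced(self):
        """Linear 3-cell slope, retention efficiency 0.5: the middle cell
        intercepts half the top cell's export; the bottom cell intercepts
        half of (its upslope neighbour's own loss + pass-through)."""
        dem = np.array([[2.0, 1.0, 0.0]])
        stack = erosion_stack((1, 3), dem, r=1.0, k=1.0)
        grid = LandCoverGrid(np.full((1, 3), 1), cell_size=30.0)
        params = ErosionParams(
            c_factor={**{k: 0.0 for k in DEFAULT_CARBON_DENSITY}, "CL": 0.5},
            p_factor={**{k: 1.0 for k in DEFAULT_CARBON_DENSITY}, "CL": 1.0},
            retention_efficiency={**{k: 0.0 for k in DEFAULT_CARBON_DENSITY}, "CL": 0.5},
        )
        ls = np.array([[2.0, 2.0, 2.0]])
        res = soil_budget(stack, grid, params, ls=ls)
        rusle = res.rasters["rusle_t_ha"][0]
        assert np.allclose(rusle, 1.0)  # R·K·LS·C·P = 1·1·2·0.5·1
        sed = res.rasters["sed_t_ha"][0]
        # cell 0 exports 1.0 -> cell 1 intercepts 0.5, passes 0.5 + its own 1.0
        # cell 2 intercepts 0.5 · 1.5 = 0.75
        assert sed[0] == pytest.approx(0.0)
        assert sed[1] == pytest.approx(0.5)
        assert sed[2] == pytest.approx(0.75)

    def test_out_of_range_factor_rejected(self):
        with pytest.raises(ValueError, match="must be in"):
            ErosionParams(c_factor={**{k: 0.0 for k in DEFAULT_CARBON_DENSITY}, "CL": 1.5})


class TestCarbonStock:
    @pytest.mark.parametrize(
        "scenario, printed",
        [("2014", 1713.53), ("scenario_1", 1707.39), ("scenario_2", 1707.53)],
    )
    def test_published_compositions(self, scenario, printed):
        """District compositions × published densities; the 2014 value
        recomputes to 1713.53 from the rounded printed areas."""
        total = carbon_stock_from_areas(COMPOSITIONS[scenario])
        assert round(total / 1e4, 2) == printed

    def test_open_water_landscape_stores_nothing(self):
        grid = LandCoverGrid(np.full((5, 5), 7))
        assert carbon_stock(grid).totals["CS_t"] == 0.0

    def test_linear_in_area(self):
        base = dict(COMPOSITIONS["2014"])
        doubled = {k: 2 * v for k, v in base.items()}
        assert carbon_stock_from_areas(doubled) == pytest.approx(
            2 * carbon_stock_from_areas(base)
        )

    def test_arrangement_invariance(self):
        grid = random_landcover(14)
        rng = np.random.default_rng(0)
        shuffled = LandCoverGrid(
            grid.values.ravel()[rng.permutation(grid.values.size)].reshape(grid.shape)
        )
        assert carbon_stock(grid).totals["CS_t"] == pytest.approx(
            carbon_stock(shuffled).totals["CS_t"]
        )

    def test_raster_and_composition_routes_agree(self):
        grid = random_landcover(15)
        from luces.grid import class_areas

        areas = class_areas(grid).set_index("class_label")["area_km2"]
        assert carbon_stock(grid).totals["CS_t"] == pytest.approx(
            carbon_stock_from_areas(areas)
        )

    def test_missing_density_rejected(self):
        grid = LandCoverGrid(np.full((2, 2), 3))
        with pytest.raises(KeyError, match="FL"):
            carbon_stock(grid, densities={"CL": 30.96})

    def test_scenario_carbon_ordering(self):
        """2014 stores the most carbon; the optimized 2030 structure keeps
        slightly more than the business-as-usual projection."""
        cs = {s: carbon_stock_from_areas(COMPOSITIONS[s]) for s in COMPOSITIONS}
        assert cs["2014"] > cs["scenario_2"] > cs["scenario_1"]


class TestAssessAll:
    def test_merges_all_layers_and_totals(self, lucc_small, terrain_small):
        res = assess_all(terrain_small, lucc_small)
        assert {"WY_m3", "SLO_t", "SC_t", "CS_t"} <= set(res.totals)
        assert {"water_yield_mm", "usle_t_ha", "rusle_t_ha", "sedret_t_ha",
                "carbon_t_ha"} <= set(res.rasters)
        assert all(np.isfinite(v) for v in res.totals.values())
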