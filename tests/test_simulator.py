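import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epicens import DataError, generate_world, make_preset
from epicens.config import ConfigurationError, scurve_from_anchors
from epicens.simulator import (
    PAR_FRACTION,
    PLANT_N_FRACTION,
    PLANT_P_FRACTION,
    MAX_INTERCEPTION,
    SCENARIOS,
    WATER_REGIMES,
    SoilState,
    _moisture_index,
    _oxygen_factors,
    auto_fertilize,
    auto_irrigate,
    compute_phu,
    end_of_year_soil_update,
    extraterrestrial_radiation,
    hargreaves_pet,
    heat_units,
    nutrient_step,
    run_ensemble,
    simulate_season,
    water_balance_step,
)
from epicens.world import DAYS_PER_YEAR


def make_soil(rng=None, n_layers=3, wet=0.75):
    rng = rng or np.random.default_rng(0)
    th = rng.uniform(0.2, 0.5, n_layers)
    fc = rng.uniform(0.25, 0.35, n_layers) * th * 1000
    wp = fc * rng.uniform(0.4, 0.6, n_layers)
    return SoilState(
        thickness=th,
        field_capacity=fc,
        wilting_point=wp,
        ksat=rng.uniform(5, 80, n_layers),
        storage=wp + wet * (fc - wp),
        organic_n=rng.uniform(500, 2000, n_layers),
        mineral_n=rng.uniform(5, 30, n_layers),
        labile_p=rng.uniform(5, 30, n_layers),
    )


class TestHeatUnits:
    def test_at_base_zero(self):
        assert heat_units(10.0, 10.0, t_base=10.0, t_opt=25.0) == 0.0

    def test_direct_value(self):
        # mean (18+30)/2 = 24; 24 - 8 = 16 (below the 30-8 cap)
        assert heat_units(18.0, 30.0, t_base=8.0, t_opt=30.0) == pytest.approx(16.0)

    def test_cap_above_optimum(self):
        assert heat_units(30.0, 40.0, t_base=8.0, t_opt=25.0) == pytest.approx(17.0)

    def test_never_negative(self):
        assert heat_units(-20.0, -10.0, t_base=8.0, t_opt=25.0) == 0.0

    def test_tmax_below_tmin_rejected(self):
        with pytest.raises(DataError):
            heat_units(20.0, 10.0, 8.0, 25.0)

    @given(
        st.floats(-30, 30), st.floats(0, 20),
        st.floats(0, 12), st.floats(13, 35),
    )
    def test_bounds(self, tmin, dtr, t_base, t_opt):
        hu = heat_units(tmin, tmin + dtr, t_base, t_opt)
        assert 0.0 <= hu <= t_opt - t_base + 1e-12


class TestComputePhu:
    def test_constant_climatology(self):
        clim = np.full(DAYS_PER_YEAR, 18.0)
        # 100-day season at 10 degC above base
        assert compute_phu(clim, 1, 100, t_base=8.0, t_opt=30.0) == pytest.approx(1000.0)

    def test_wrap(self):
        clim = np.arange(DAYS_PER_YEAR, dtype=float) / 30.0 + 5.0
        wrapped = compute_phu(clim, 350, 20, t_base=0.0, t_opt=40.0)
        manual = sum(
            min(max(clim[d - 1] - 0.0, 0.0), 40.0)
            for d in list(range(350, 361)) + list(range(1, 21))
        )
        assert wrapped == pytest.approx(manual)

    def test_sinusoid_matches_loop_oracle(self):
        doy = np.arange(1, DAYS_PER_YEAR + 1)
        clim = 15.0 + 10.0 * np.sin(2 * np.pi * doy / DAYS_PER_YEAR)
        got = compute_phu(clim, 90, 240, t_base=8.0, t_opt=25.0)
        expected = 0.0
        for d in range(90, 241):
            hu = clim[d - 1] - 8.0
            expected += min(max(hu, 0.0), 17.0)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_bad_dates_rejected(self):
        clim = np.full(DAYS_PER_YEAR, 18.0)
        with pytest.raises(ConfigurationError):
            compute_phu(clim, 0, 100, 8.0, 25.0)


class TestHargreaves:
    def test_zero_range_zero_pet(self):
        assert hargreaves_pet(20.0, 20.0, 10.0, 100, 0.0023, 0.5) == 0.0

    def test_textbook_oracle(self):
        # independent textbook coding of Hargreaves at the equator
        lat, doy, tmin, tmax = 0.0, 90, 20.0, 30.0
        ang = 2 * np.pi * doy / 360.0
        dr = 1 + 0.033 * np.cos(ang)
        decl = 0.409 * np.sin(ang - 1.39)
        ws = np.arccos(np.clip(-np.tan(0.0) * np.tan(decl), -1, 1))
        ra = (24 * 60 / np.pi) * 0.0820 * dr * (
            ws * np.sin(0.0) * np.sin(decl) + np.cos(0.0) * np.cos(decl) * np.sin(ws)
        )
        expected = 0.0023 * 0.408 * ra * ((tmin + tmax) / 2 + 17.8) * np.sqrt(tmax - tmin)
        got = hargreaves_pet(tmin, tmax, lat, doy, 0.0023, 0.5)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_linear_in_lin_coeff(self):
        a = hargreaves_pet(20.0, 30.0, 40.0, 180, 0.0023, 0.5)
        b = hargreaves_pet(20.0, 30.0, 40.0, 180, 0.0032, 0.5)
        assert b == pytest.approx(a * 0.0032 / 0.0023, rel=1e-12)

    @given(st.floats(-60, 60), st.integers(1, 360), st.floats(-20, 35),
           st.floats(0, 20))
    @settings(max_examples=50)
    def test_nonnegative(self, lat, doy, tmin, dtr):
        assert hargreaves_pet(tmin, tmin + dtr, lat, doy) >= 0.0

    def test_ra_nonnegative_everywhere(self):
        lats = np.linspace(-89, 89, 50)
        doys = np.arange(1, 361)
        ra = extraterrestrial_radiation(lats[:, None], doys[None, :])
        assert np.all(ra >= 0)


class TestWaterBalance:
    def test_no_extractable_water(self, iiasa):
        soil = make_soil(wet=0.0)
        new, runoff, perc, aet, ws = water_balance_step(
            soil, 0.0, 0.0, 5.0, 0.5, iiasa.coeff_w
        )
        assert aet == 0.0
        assert ws == 0.0

    def test_full_storage_no_stress(self, iiasa):
        soil = make_soil(wet=1.0)
        _, _, _, _, ws = water_balance_step(soil, 0.0, 0.0, 4.0, 0.8, iiasa.coeff_w)
        assert ws == pytest.approx(1.0)

    def test_mass_balance_random_forcing(self, iiasa):
        rng = np.random.default_rng(42)
        soil = make_soil(rng)
        total_in = total_out = 0.0
        start = soil.storage.sum()
        for _ in range(90):
            precip = rng.exponential(3.0) * (rng.random() < 0.4)
            irr = rng.uniform(0, 10) * (rng.random() < 0.1)
            pet = rng.uniform(0, 8)
            lai = rng.uniform(0, 0.85)
            soil, runoff, perc, aet, ws = water_balance_step(
                soil, precip, irr, pet, lai, iiasa.coeff_w
            )
            total_in += precip + irr
            total_out += runoff + perc + aet
        end = soil.storage.sum()
        assert end - start == pytest.approx(total_in - total_out, abs=1e-9)

    def test_stress_in_unit_interval(self, iiasa):
        rng = np.random.default_rng(3)
        soil = make_soil(rng)
        for _ in range(200):
            soil, _, _, _, ws = water_balance_step(
                soil, rng.exponential(2.0), 0.0, rng.uniform(0, 9),
                rng.uniform(0, 0.85), iiasa.coeff_w
            )
            assert 0.0 <= ws <= 1.0

    def test_runoff_bounded_by_precip(self, iiasa):
        soil = make_soil(wet=1.0)
        _, runoff, _, _, _ = water_balance_step(soil, 50.0, 0.0, 5.0, 0.5,
                                                iiasa.coeff_w)
        assert 0.0 <= runoff <= 50.0


class TestNutrientStep:
    def test_no_demand_no_stress(self, iiasa):
        soil = make_soil()
        _, n_sup, p_sup, ns, ps = nutrient_step(soil, 0.5, 0.5, 0.0, 0.0,
                                                iiasa.coeff_n)
        assert ns == 1.0 and ps == 1.0
        assert n_sup == 0.0 and p_sup == 0.0

    def test_no_supply_full_stress(self, iiasa):
        soil = make_soil()
        soil.mineral_n[:] = 0.0
        soil.organic_n[:] = 0.0
        soil.labile_p[:] = 0.0
        _, _, _, ns, ps = nutrient_step(soil, 0.5, 0.5, 5.0, 1.0, iiasa.coeff_n)
        assert ns == 0.0 and ps == 0.0

    def test_single_step_closed_form(self, gepic):
        cn = gepic.coeff_n
        soil = make_soil(n_layers=2)
        o2 = _oxygen_factors(soil, cn)
        tf, mf = 0.6, 0.4
        from epicens.simulator import BASE_MINERALIZATION
        rate = cn.microbial_decay * BASE_MINERALIZATION * mf * tf * o2
        exp_mineralized = rate * soil.organic_n
        exp_min_after = soil.mineral_n + exp_mineralized
        exp_vol = cn.n_volatilization * exp_min_after[0]
        exp_min_after = exp_min_after.copy()
        exp_min_after[0] -= exp_vol
        demand = 2.0
        exp_supply = min(demand, exp_min_after.sum())
        new, n_sup, p_sup, ns, ps = nutrient_step(soil, tf, mf, demand, 0.5, cn)
        np.testing.assert_allclose(new.organic_n, soil.organic_n - exp_mineralized,
                                   rtol=1e-12)
        assert n_sup == pytest.approx(exp_supply, rel=1e-12)
        assert ns == pytest.approx(exp_supply / demand, rel=1e-12)

    def test_mass_conservation(self, iiasa):
        rng = np.random.default_rng(17)
        soil = make_soil(rng)
        for _ in range(50):
            before = soil.organic_n.sum() + soil.mineral_n.sum()
            soil, n_sup, _, _, _, fluxes = nutrient_step(
                soil, rng.uniform(0, 1), rng.uniform(0, 1),
                rng.uniform(0, 5), rng.uniform(0, 1), iiasa.coeff_n,
                return_fluxes=True,
            )
            after = soil.organic_n.sum() + soil.mineral_n.sum()
            losses = fluxes["volatilized"] + fluxes["denitrified"] + n_sup
            assert before - after == pytest.approx(losses, abs=1e-9)

    def test_pools_never_negative(self, iiasa):
        rng = np.random.default_rng(23)
        soil = make_soil(rng)
        for _ in range(300):
            soil, *_ = nutrient_step(soil, rng.uniform(0, 1), rng.uniform(0, 1),
                                     rng.uniform(0, 20), rng.uniform(0, 5),
                                     iiasa.coeff_n)
            assert np.all(soil.mineral_n >= 0)
            assert np.all(soil.organic_n >= 0)
            assert np.all(soil.labile_p >= 0)


class TestAutoManagement:
    def test_no_stress_no_irrigation(self, iiasa):
        assert auto_irrigate(1.0, 100.0, iiasa.manage) == 0.0

    def test_application_capped_by_maximum(self):
        manage = make_preset("boku").manage  # max single application 50 mm
        assert auto_irrigate(0.5, 300.0, manage) == pytest.approx(50.0)

    def test_application_capped_by_deficit(self, iiasa):
        assert auto_irrigate(0.5, 30.0, iiasa.manage) == pytest.approx(30.0)

    def test_suffn_applies_whenever_triggered(self, iiasa):
        applied = auto_fertilize(0.5, 0.0, iiasa.manage, "harm-suffN")
        assert applied > 0.0

    def test_budget_exhausted(self, iiasa):
        assert auto_fertilize(0.5, 0.0, iiasa.manage, "fullharm") == 0.0

    def test_fixed_timing_no_triggered_application(self):
        manage = make_preset("pepic").manage
        assert manage.fixed_timing
        assert auto_fertilize(0.1, 100.0, manage, "fullharm") == 0.0


class TestEndOfYearUpdate:
    def test_static_resets_om_keeps_mineral(self, iiasa):
        init = make_soil()
        state = init.copy()
        state.organic_n[:] = 1.0
        state.mineral_n[:] = 99.0
        state.storage[:] = init.storage * 0.5
        out = end_of_year_soil_update(state, init, iiasa.soil_p, 1)
        np.testing.assert_array_equal(out.organic_n, init.organic_n)
        np.testing.assert_array_equal(out.mineral_n, state.mineral_n)
        np.testing.assert_array_equal(out.storage, state.storage)

    def test_dynamic_zero_rate_identity(self, gepic):
        block = copy.deepcopy(gepic.soil_p)
        block.topsoil_loss_rate = 0.0
        state = make_soil()
        out = end_of_year_soil_update(state, state, block, 1)
        for name in vars(state):
            np.testing.assert_array_equal(getattr(out, name), getattr(state, name))

    def test_dynamic_geometric_shrink(self, gepic):
        block = copy.deepcopy(gepic.soil_p)
        block.topsoil_loss_rate = 0.01
        state = make_soil()
        top0 = state.thickness[0]
        k = 7
        for year in range(k):
            state = end_of_year_soil_update(state, state, block, year)
        assert state.thickness[0] == pytest.approx(top0 * (1 - 0.01) ** k, rel=1e-12)


# ---------------------------------------------------------------------------
# season-level behavior

def make_flat_cell(n_years=2, tmean=25.0, dtr=10.0, srad=20.0, precip=4.0,
                   water_capacity=2000.0):
    """Hand-built cell with constant weather and a deep, wet soil."""
    from epicens.world import GridCellEnv

    n_days = n_years * DAYS_PER_YEAR
    L = 3
    fc = np.full(L, water_capacity / L + 40.0)
    wp = np.full(L, 40.0)
    return GridCellEnv(
        cell_id=0,
        lat=42.0,
        country_id=0,
        climate_region="temperate",
        mean_annual_precip=precip * DAYS_PER_YEAR,
        tmin=np.full(n_days, tmean - dtr / 2),
        tmax=np.full(n_days, tmean + dtr / 2),
        srad=np.full(n_days, srad),
        precip=np.full(n_days, precip),
        layer_thickness=np.full(L, 0.5),
        field_capacity=fc,
        wilting_point=wp,
        ksat=np.full(L, 50.0),
        organic_n=np.full(L, 1500.0),
        mineral_n=np.full(L, 30.0),
        labile_p=np.full(L, 30.0),
        n_rate=150.0,
        p_rate=25.0,
        area_rainfed=500.0,
        area_irrigated=100.0,
        planting_doy=60,
        harvest_doy=240,
        phu=1500.0,
    )


class TestSimulateSeason:
    @pytest.fixture()
    def world(self):
        return generate_world(4, 2, 12, seed=21)

    def test_stress_free_limit(self):
        # constant weather at the cultivar optimum, huge water store, and
        # sufficient nutrients: every stress factor is 1, so HI_a = hi_max
        # and yield = biomass * hi_max
        cfg = make_preset("iiasa")
        cell = make_flat_cell()
        pars = cfg.cult.cultivars[1]  # temperate -> cultivar 1, t_opt 25
        res, _ = simulate_season(cell, cfg, "harm-suffN", "rainfed")
        assert res.hi_actual == pytest.approx(pars.hi_max, abs=1e-12)
        assert res.yield_t_ha == pytest.approx(
            res.aboveground_biomass * pars.hi_max, rel=1e-12
        )
        assert sum(res.stress_days.values()) == 0

    def test_no_radiation_no_yield(self, iiasa):
        cell = make_flat_cell(srad=0.0)
        res, _ = simulate_season(cell, iiasa, "fullharm", "rainfed")
        assert res.aboveground_biomass == 0.0
        assert res.yield_t_ha == 0.0

    def test_hi_within_cultivar_range(self, world):
        for name in ("iiasa", "gepic", "pepic"):
            cfg = make_preset(name)
            for i in range(world.n_cells):
                cid = res_cultivar(world, cfg, i)
                pars = cfg.cult.cultivars[cid]
                res, _ = simulate_season(world.cell(i), cfg, "fullharm", "rainfed")
                assert pars.hi_min - 1e-9 <= res.hi_actual <= pars.hi_max + 1e-9

    def test_stress_days_bounded(self, world, iiasa):
        res, _ = simulate_season(world.cell(1), iiasa, "fullharm", "rainfed")
        season_len = DAYS_PER_YEAR
        for count in res.stress_days.values():
            assert 0 <= count <= season_len

    def test_fixed_timing_applies_full_rate_at_planting(self, world):
        pepic = make_preset("pepic")
        res, _ = simulate_season(world.cell(0), pepic, "fullharm", "rainfed")
        assert res.applied_n == pytest.approx(world.cell(0).n_rate)


def res_cultivar(world, cfg, i):
    return cfg.cult.cultivar_for_cell(
        str(world.climate_region[i]), world.country_dev[int(world.country_id[i])]
    )


class TestIndependentLoopOracle:
    """A second, scalar coding of the daily loop must agree to 1e-9."""

    def test_oracle_agreement(self):
        world = generate_world(3, 1, 12, seed=33)
        cfg = make_preset("iiasa")  # static soil, transient, no fixed timing
        i = 0
        cell = world.cell(i)
        dev = world.country_dev[int(world.country_id[i])]
        res, _ = simulate_season(cell, cfg, "fullharm", "rainfed", country_dev=dev)
        oracle = self._oracle(cell, cfg, dev)
        assert res.yield_t_ha == pytest.approx(oracle.yield_t_ha, abs=1e-9)
        assert res.aboveground_biomass == pytest.approx(
            oracle.aboveground_biomass, abs=1e-9
        )
        assert res.hi_actual == pytest.approx(oracle.hi_actual, abs=1e-9)
        assert res.stress_days == oracle.stress_days

    @staticmethod
    def _oracle(cell, cfg, dev):
        from epicens.simulator import SeasonResult

        cult_id = cfg.cult.cultivar_for_cell(cell.climate_region, dev)
        pars = cfg.cult.cultivars[cult_id]
        n_years = len(cell.tmin) // DAYS_PER_YEAR
        tmean = (cell.tmin + cell.tmax) / 2.0
        clim = tmean.reshape(n_years, DAYS_PER_YEAR).mean(axis=0)
        phu = max(
            compute_phu(clim, cell.planting_doy, cell.harvest_doy,
                        pars.t_base, pars.t_opt),
            1.0,
        )
        soil = SoilState(
            thickness=cell.layer_thickness.copy(),
            field_capacity=cell.field_capacity.copy(),
            wilting_point=cell.wilting_point.copy(),
            ksat=cell.ksat.copy(),
            storage=cell.wilting_point
            + 0.75 * (cell.field_capacity - cell.wilting_point),
            organic_n=cell.organic_n.copy(),
            mineral_n=cell.mineral_n.copy(),
            labile_p=cell.labile_p.copy(),
        )
        init_soil = soil.copy()
        o2 = _oxygen_factors(soil, cfg.coeff_n)
        growing = False
        hu = biomass = wsi_sum = wsi_n = 0.0
        budget = applied_n = 0.0
        prev_ws = prev_ns = 1.0
        sd = {"water": 0, "nitrogen": 0, "phosphorus": 0, "temperature": 0}
        order = ["water", "nitrogen", "phosphorus", "temperature"]
        for d in range(len(cell.tmin)):
            doy = d % DAYS_PER_YEAR + 1
            if doy == cell.planting_doy and not growing:
                growing = True
                hu = biomass = wsi_sum = wsi_n = 0.0
                budget = cell.n_rate
                applied_n = 0.0
                prev_ws = prev_ns = 1.0
                sd = dict.fromkeys(sd, 0)
                soil.labile_p[0] += cell.p_rate
            hui = min(max(hu / phu, 0.0), 1.0)
            lai = (
                MAX_INTERCEPTION / (1.0 + np.exp(-8.0 * (hui - 0.35)))
                if growing
                else 0.0
            )
            pet = hargreaves_pet(
                cell.tmin[d], cell.tmax[d], cell.lat, doy,
                cfg.coeff_w.hargreaves_lin, cfg.coeff_w.hargreaves_exp,
            )
            soil, _, _, _, ws = water_balance_step(
                soil, cell.precip[d], 0.0, pet, lai, cfg.coeff_w
            )
            dbp = (
                pars.rue * cfg.manage.row_spacing_factor * PAR_FRACTION
                * lai * cell.srad[d] * 0.01
            )
            demand_n = PLANT_N_FRACTION * dbp * 1000.0 if growing else 0.0
            demand_p = PLANT_P_FRACTION * dbp * 1000.0 if growing else 0.0
            fert = auto_fertilize(prev_ns, budget, cfg.manage, "fullharm")
            fert = fert if growing else 0.0
            soil.mineral_n[1] += fert
            budget = max(budget - fert, 0.0)
            applied_n += fert
            smi = float(_moisture_index(soil))
            mf = scurve_from_anchors(smi, *cfg.coeff_n.moisture_fn_anchors)
            tf = min(max(tmean[d] / 35.0, 0.0), 1.0)
            soil, _, _, ns, ps = nutrient_step(
                soil, tf, mf, demand_n, demand_p, cfg.coeff_n, oxygen_factor=o2
            )
            ts = min(
                max(2.0 * (tmean[d] - pars.t_base) / (pars.t_opt - pars.t_base), 0.0),
                1.0,
            )
            stresses = [float(ws), float(ns), float(ps), float(ts)]
            s_min = min(stresses)
            if growing and s_min < 1.0:
                sd[order[int(np.argmin(stresses))]] += 1
            if growing:
                biomass += dbp * s_min
                hu += heat_units(cell.tmin[d], cell.tmax[d], pars.t_base, pars.t_opt)
                if hui >= cfg.cult.hi_sensitive_fraction:
                    wsi_sum += 1.0 - float(ws)
                    wsi_n += 1
            prev_ws, prev_ns = float(ws), float(ns)
            if growing and (hu >= phu or doy == cell.harvest_doy):
                wsi = min(max(wsi_sum / max(wsi_n, 1.0), 0.0), 1.0)
                hi_a = pars.hi_max - (pars.hi_max - pars.hi_min) * wsi
                return SeasonResult(
                    yield_t_ha=biomass * hi_a,
                    aboveground_biomass=biomass,
                    hi_actual=hi_a,
                    stress_days=sd,
                    applied_irrigation=0.0,
                    applied_n=applied_n,
                )
            if doy == DAYS_PER_YEAR:
                soil = end_of_year_soil_update(soil, init_soil, cfg.soil_p,
                                               d // DAYS_PER_YEAR)
        raise AssertionError("no season completed")


class TestRunEnsemble:
    def test_single_cell_composition(self, iiasa):
        world = generate_world(1, 1, 12, seed=8)
        cube = run_ensemble(world, [iiasa], scenarios=["fullharm"],
                            water_regimes=["rainfed"])
        res, _ = simulate_season(world.cell(0), iiasa, "fullharm", "rainfed",
                                 country_dev=world.country_dev[0])
        harvest_year = int(cube["year"].values[np.isfinite(
            cube.values[0, 0, 0, :, 0])][0])
        got = float(cube.sel(year=harvest_year).values[0, 0, 0, 0])
        assert got == pytest.approx(res.yield_t_ha, abs=1e-12)

    def test_config_order_independence(self, small_world, iiasa, gepic):
        c1 = run_ensemble(small_world, [iiasa, gepic], scenarios=["fullharm"],
                          water_regimes=["rainfed"])
        c2 = run_ensemble(small_world, [gepic, iiasa], scenarios=["fullharm"],
                          water_regimes=["rainfed"])
        np.testing.assert_array_equal(
            c1.sel(config="iiasa").values, c2.sel(config="iiasa").values
        )
        np.testing.assert_array_equal(
            c1.sel(config="gepic").values, c2.sel(config="gepic").values
        )

    def test_year1_flagged_invalid(self, small_cube):
        assert not bool(small_cube["year_valid"].sel(year=1))
        assert bool(small_cube["year_valid"].sel(year=2))

    def test_suffn_irrigated_dominates_fullharm_rainfed(self, small_cube):
        a = small_cube.sel(scenario="harm-suffN", water="irrigated").values
        b = small_cube.sel(scenario="fullharm", water="rainfed").values
        ok = np.isfinite(a) & np.isfinite(b)
        assert np.all(a[ok] >= b[ok] - 1e-9)

    def test_irrigated_dominates_rainfed_with_sufficient_nutrients(self, small_cube):
        a = small_cube.sel(scenario="harm-suffN", water="irrigated").values
        b = small_cube.sel(scenario="harm-suffN", water="rainfed").values
        ok = np.isfinite(a) & np.isfinite(b)
        assert np.all(a[ok] >= b[ok] - 1e-9)

    def test_yield_monotone_in_n_rate(self, iiasa):
        # same world with scaled fertilizer rates, P stress disabled
        base = generate_world(6, 2, 12, seed=14)
        lo = copy.deepcopy(base)
        hi = copy.deepcopy(base)
        lo.n_rate = base.n_rate * 0.3
        hi.n_rate = base.n_rate * 1.0
        cube_lo = run_ensemble(lo, [iiasa], scenarios=["fullharm"],
                               water_regimes=["rainfed"], disable_p_stress=True)
        cube_hi = run_ensemble(hi, [iiasa], scenarios=["fullharm"],
                               water_regimes=["rainfed"], disable_p_stress=True)
        a, b = cube_hi.values, cube_lo.values
        ok = np.isfinite(a) & np.isfinite(b)
        assert np.all(a[ok] >= b[ok] - 1e-9)

    def test_nonnegative_yields(self, small_cube):
        vals = small_cube.values
        assert np.all(vals[np.isfinite(vals)] >= 0.0)

    def test_unknown_scenario_rejected(self, small_world, iiasa):
        with pytest.raises(ConfigurationError):
            run_ensemble(small_world, [iiasa], scenarios=["weird"])

    def test_scenario_water_axes(self, small_cube):
        assert set(SCENARIOS) >= set(small_cube["scenario"].values)
        assert list(small_cube["water"].values) == list(WATER_REGIMES)
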