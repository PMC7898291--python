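"""Column stepping: composition against unit operations, conservation,
determinism, spin-up behaviour and the mass-balance audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import soildoc as sd
from soildoc import column, synthetic
from soildoc.doc_dynamics import (
    doc_decomposition,
    doc_production,
    sorption_coefficient,
    sorption_partition,
    vertical_diffusion,
)
from soildoc.errors import ConvergenceError, ForcingError, MisalignedSeriesError
from soildoc.soil_carbon import RateModifiers, step_soc_pools


def _compose_one_step(state, forcing, params, index=0):
    """Hand-chain the public unit operations in the documented order."""
    grid = state.grid
    dt = forcing.dt
    dt_days = dt / 86400.0
    t = forcing.t_soil[index]
    s = forcing.sat_frac[index]
    water = forcing.water[index]
    soil = params.soil()

    ft = sd.rate_modifier_temperature(t, params.q10, params.t_ref)
    mods = RateModifiers(
        f_temp=ft,
        f_moist=sd.rate_modifier_moisture(s, soil.s_wilt, soil.s_opt),
        f_veg=float(sd.rate_modifier_vegetation(forcing.veg_cover[index])),
    )
    mod = mods.combined

    pools, co2_soc, _ = step_soc_pools(
        state.soc, float(forcing.litter[index]), mods, soil, dt, params.dpm_fraction)
    soc = pools.stocks.copy()

    dis = state.doc.dissolved.copy()
    ads = state.doc.adsorbed.copy()
    class_of = {0: 0, 1: 1, 2: 0, 3: 1}  # DPM,BIO -> labile; RPM,HUM -> recalcitrant
    for p in range(4):
        for layer in range(grid.n_layers):
            fp = doc_production(soc[p, layer], params.kp, mod[layer], dt_days)
            soc[p, layer] -= fp
            dis[class_of[p], layer] += fp

    kd = sorption_coefficient(params.ph, params.clay,
                              params.sorb_a0, params.sorb_a1, params.sorb_a2)
    dis, ads = sorption_partition(dis + ads, kd)

    kdoc = (params.kdoc_labile, params.kdoc_recalcitrant)
    for c in range(2):
        for layer in range(grid.n_layers):
            dec, to_soc, _ = doc_decomposition(dis[c, layer], kdoc[c], ft[layer],
                                               params.cue, dt_days)
            dis[c, layer] -= dec
            soc[3, layer] += to_soc

    for c in range(2):
        conc = 1000.0 * dis[c] / water
        flux = vertical_diffusion(conc, params.d_coeff, grid, dt)
        dis[c, :-1] -= flux
        dis[c, 1:] += flux

    smask = grid.bottoms <= 0.35 + 1e-12
    f_surf = min(forcing.surf_runoff[index] / water[smask].sum(), 1.0)
    f_deep = min((forcing.sub_runoff[index] + forcing.drainage[index])
                 / water[~smask].sum(), 1.0)
    frac = np.where(smask, f_surf, f_deep)
    dis = dis * (1.0 - frac)
    return soc, dis, ads


def test_single_step_equals_composition_of_unit_operations(small_state, params):
    forcing = synthetic.constant_forcing(3, dt=1800.0, litter=0.5,
                                         surf_runoff=0.3, sub_runoff=0.4, drainage=0.2)
    expected_soc, expected_dis, expected_ads = _compose_one_step(small_state, forcing, params)
    new, fx = column.step_column(small_state, forcing, params, 0)
    np.testing.assert_allclose(new.soc.stocks, expected_soc, rtol=1e-12)
    np.testing.assert_allclose(new.doc.dissolved, expected_dis, rtol=1e-12)
    np.testing.assert_allclose(new.doc.adsorbed, expected_ads, rtol=1e-12)


def test_empty_column_with_zero_inputs_stays_empty(params):
    state = column.SoilColumnState.zeros()
    forcing = synthetic.constant_forcing(2, litter=0.0, surf_runoff=0.0,
                                         sub_runoff=0.0, drainage=0.0)
    new, fx = column.step_column(state, forcing, params, 0)
    assert new.total_carbon == 0.0
    assert fx["residual"] == pytest.approx(0.0, abs=1e-15)


def test_step_closure_residual_is_tiny(small_state, params):
    forcing = synthetic.constant_forcing(2, dt=1800.0, litter=1.0,
                                         surf_runoff=0.5, sub_runoff=0.5, drainage=0.3)
    _, fx = column.step_column(small_state, forcing, params, 0)
    throughput = 1.0 + fx["co2_soc"] + fx["co2_doc"] + fx["leach"].sum()
    assert abs(fx["residual"]) < 1e-8 * throughput


def test_run_simulation_is_deterministic(small_state, params):
    forcing = synthetic.generate_forcing(
        synthetic.default_scenario("temperate", years=1, seed=4))
    r1 = column.run_simulation(small_state, forcing, params)
    r2 = column.run_simulation(small_state, forcing, params)
    np.testing.assert_array_equal(r1.states.total, r2.states.total)
    np.testing.assert_array_equal(r1.fluxes.leach, r2.fluxes.leach)
    np.testing.assert_array_equal(r1.final_state.soc.stocks, r2.final_state.soc.stocks)


def test_zero_step_run_returns_initial_state(small_state, params, grid):
    forcing = synthetic.constant_forcing(1, litter=1.0).subset(0, 0)
    res = column.run_simulation(small_state, forcing, params)
    assert len(res.fluxes) == 0
    np.testing.assert_array_equal(res.final_state.soc.stocks, small_state.soc.stocks)


def test_forcing_layer_mismatch_rejected(small_state, params):
    bad = synthetic.constant_forcing(2, grid=sd.LayerGrid((0.0, 1.0, 3.0)))
    with pytest.raises(ForcingError):
        column.step_column(small_state, bad, params, 0)


def test_doubling_runoff_does_not_reduce_annual_leaching(params, fast_spinup):
    cycle = synthetic.constant_forcing(365, litter=400.0 / 365.0)
    leached = []
    for factor in (1.0, 2.0):
        state = column.accelerated_spinup(
            column.SoilColumnState.zeros(), cycle.scale_runoff(factor), params, fast_spinup)
        res = column.run_simulation(state, cycle.scale_runoff(factor), params)
        leached.append(res.fluxes.totals()["leached"])
    assert leached[1] >= leached[0]


@given(
    t=st.lists(st.floats(210.0, 330.0), min_size=8, max_size=8),
    sat=st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
    water=st.lists(st.floats(0.0, 80.0), min_size=8, max_size=8),
    runoff=st.lists(st.floats(0.0, 150.0), min_size=6, max_size=6),
    litter=st.floats(0.0, 50.0),
)
@settings(max_examples=25, deadline=None)
def test_stocks_never_negative_under_adversarial_forcing(t, sat, water, runoff, litter):
    grid = sd.LayerGrid()
    params = sd.default_params("temperate")
    n = 2
    forcing = sd.ForcingSeries(
        start=np.datetime64("2000-01-01"),
        dt=1800.0,
        t_soil=np.array(t).reshape(n, 4),
        water=np.array(water).reshape(n, 4),
        sat_frac=np.array(sat).reshape(n, 4),
        surf_runoff=np.array(runoff[:2]),
        sub_runoff=np.array(runoff[2:4]),
        drainage=np.array(runoff[4:6]),
        litter=np.full(n, litter),
        veg_cover=np.full(n, 0.5),
    )
    state = column.SoilColumnState(
        soc=sd.SocPools(np.full((4, 4), 50.0), grid=grid),
        doc=sd.DocPools(np.full((2, 4), 5.0), np.full((2, 4), 2.0), grid),
    )
    res = column.run_simulation(state, forcing, params)
    assert np.all(res.states.soc_pools >= 0)
    assert np.all(res.states.doc_dissolved >= -1e-12)
    assert np.all(res.states.doc_adsorbed >= -1e-12)
    rep = column.mass_balance_report(res.fluxes, res.states)
    assert rep.flagged_steps.size == 0


class TestSpinup:
    def test_factors_from_printed_rates(self):
        f = column.spinup_factors(np.array([3.2e-7, 9.6e-9, 2.1e-8, 6.4e-10]))
        np.testing.assert_array_equal(f, [1.0, 33.0, 15.0, 500.0])

    def test_equal_rates_reduce_to_direct(self):
        f = column.spinup_factors(np.full(4, 1e-8))
        np.testing.assert_array_equal(f, np.ones(4))

    def test_accelerated_matches_direct_within_tolerance(self, params):
        cycle = synthetic.constant_forcing(365, litter=400.0 / 365.0)
        cfg_dir = column.SpinupConfig(mode="direct", tol=1e-6, max_cycles=5000)
        cfg_acc = column.SpinupConfig(mode="accelerated", tol=1e-6, max_cycles=5000)
        direct = column.accelerated_spinup(column.SoilColumnState.zeros(), cycle, params, cfg_dir)
        accel = column.accelerated_spinup(column.SoilColumnState.zeros(), cycle, params, cfg_acc)
        for pool, ref in direct.soc.per_pool.items():
            assert accel.soc.per_pool[pool] == pytest.approx(ref, rel=0.05)
        assert accel.doc.total == pytest.approx(direct.doc.total, rel=0.05)

    def test_non_convergence_raises_with_drift(self, params):
        cycle = synthetic.constant_forcing(10, litter=1.0)
        cfg = column.SpinupConfig(mode="direct", tol=1e-12, max_cycles=2)
        with pytest.raises(ConvergenceError, match="drift"):
            column.accelerated_spinup(column.SoilColumnState.zeros(), cycle, params, cfg)


class TestMassBalanceReport:
    def _run(self, params):
        forcing = synthetic.generate_forcing(
            synthetic.default_scenario("temperate", years=1, seed=9))
        state = column.SoilColumnState(
            soc=sd.SocPools(np.full((4, 4), 20.0)),
            doc=sd.DocPools(np.full((2, 4), 2.0), np.full((2, 4), 1.0), sd.LayerGrid()),
        )
        return column.run_simulation(state, forcing, params)

    def test_valid_run_closes(self, params):
        res = self._run(params)
        rep = column.mass_balance_report(res.fluxes, res.states)
        assert rep.ok
        assert rep.cumulative_relative < 1e-6

    def test_corrupted_step_is_flagged(self, params):
        res = self._run(params)
        res.fluxes.litter[123] += 5.0  # corrupt one step's bookkeeping
        rep = column.mass_balance_report(res.fluxes, res.states)
        assert 123 in rep.flagged_steps

    def test_no_leaching_run_stores_litter_minus_co2_exactly(self, params):
        forcing = synthetic.constant_forcing(30, litter=2.0, surf_runoff=0.0,
                                             sub_runoff=0.0, drainage=0.0)
        state = column.SoilColumnState.zeros()
        res = column.run_simulation(state, forcing, params)
        assert res.fluxes.totals()["leached"] == 0.0
        stored = res.states.total[-1] - res.states.total[0]
        expected = res.fluxes.litter.sum() - res.fluxes.co2_total.sum()
        assert stored == pytest.approx(expected, abs=1e-10)

    def test_misaligned_series_rejected(self, params):
        res = self._run(params)
        truncated = column.StateSeries(
            times=res.states.times[:-1],
            soc_pools=res.states.soc_pools[:-1],
            doc_dissolved=res.states.doc_dissolved[:-1],
            doc_adsorbed=res.states.doc_adsorbed[:-1],
            total=res.states.total[:-1],
            conc_surface=res.states.conc_surface[:-1],
            conc_sub=res.states.conc_sub[:-1],
        )
        with pytest.raises(MisalignedSeriesError):
            column.mass_balance_report(res.fluxes, truncated)


def test_annualised_fluxes_scale(params):
    forcing = synthetic.constant_forcing(730, litter=1.0)
    state = column.SoilColumnState.zeros()
    res = column.run_simulation(state, forcing, params)
    ann = res.annual_fluxes()
    assert ann["litter"] == pytest.approx(365.0, rel=1e-6)
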