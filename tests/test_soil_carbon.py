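"""Solid-pool kinetics: rate modifiers, depth profile, RothC stepping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import soildoc as sd
from soildoc.errors import ConfigurationError, InvalidInputError
from soildoc.soil_carbon import (
    DEFAULT_POOL_RATES,
    POOL_NAMES,
    RateModifiers,
    respired_fraction,
    step_soc_pools,
    vertical_fractions,
)


@pytest.mark.parametrize(
    "t, q10, t_ref, expected",
    [
        (298.15, 2.0, 298.15, 1.0),   # unity at the reference point
        (308.15, 2.0, 298.15, 2.0),   # one decade step doubles
        (288.15, 2.0, 298.15, 0.5),   # and halves symmetrically
        (303.15, 3.0, 298.15, 3.0 ** 0.5),
    ],
)
def test_temperature_modifier_q10(t, q10, t_ref, expected):
    assert sd.rate_modifier_temperature(t, q10, t_ref) == pytest.approx(expected)


def test_temperature_modifier_monotone_and_errors():
    temps = np.linspace(250.0, 320.0, 50)
    vals = sd.rate_modifier_temperature(temps, 2.0, 298.15)
    assert np.all(np.diff(vals) > 0)
    with pytest.raises(InvalidInputError):
        sd.rate_modifier_temperature(-1.0)


@pytest.mark.parametrize(
    "s, expected",
    [
        (0.7, 1.0),          # optimum
        (0.2, 0.2),          # wilting floor
        (0.45, 0.6),         # midpoint of the linear ramp
        (0.05, 0.2),         # below wilting stays floored
        (0.95, 1.0),         # supra-optimal clamps to 1
    ],
)
def test_moisture_modifier_ramp(s, expected):
    assert sd.rate_modifier_moisture(s, 0.2, 0.7) == pytest.approx(expected)


def test_moisture_modifier_config_error():
    with pytest.raises(ConfigurationError):
        sd.rate_modifier_moisture(0.5, 0.7, 0.2)


@pytest.mark.parametrize("cover, expected", [(0.0, 1.0), (1.0, 0.6), (0.5, 0.8)])
def test_vegetation_modifier_linear(cover, expected):
    assert sd.rate_modifier_vegetation(cover) == pytest.approx(expected)


def test_vegetation_modifier_rejects_out_of_range():
    with pytest.raises(InvalidInputError):
        sd.rate_modifier_vegetation(1.2)


class TestVerticalDistribution:
    def test_closed_form_top_layer(self, grid):
        # (1 - e^{-0.2}) / (1 - e^{-6}) for z* = 0.5 m on the default grid
        frac = vertical_fractions(0.5, grid)
        assert frac[0] == pytest.approx(0.1817, abs=2e-4)

    def test_uniform_limit_for_huge_zstar(self, grid):
        frac = vertical_fractions(1e6, grid)
        assert frac[0] == pytest.approx(0.10 / 3.0, rel=1e-3)

    def test_distribution_is_conservative_and_normalised(self, grid):
        out = sd.distribute_vertically(123.45, 0.35, grid)
        assert out.sum() == pytest.approx(123.45, abs=1e-12)
        assert np.all(out >= 0)

    def test_per_pool_vector_totals(self, grid):
        totals = np.array([10.0, 20.0, 0.0, 5.0])
        out = sd.distribute_vertically(totals, 0.35, grid)
        assert out.shape == (4, grid.n_layers)
        np.testing.assert_allclose(out.sum(axis=1), totals, atol=1e-12)

    @given(z=st.floats(0.05, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_density_decreases_with_depth(self, z):
        grid = sd.LayerGrid()
        frac = vertical_fractions(z, grid)
        density = frac / grid.thickness
        assert np.all(np.diff(density) <= 1e-15)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_total_rejected(self, grid):
        with pytest.raises(InvalidInputError):
            sd.distribute_vertically(-1.0, 0.35, grid)


def test_respired_fraction_clay_formula():
    # x = 1.67 (1.85 + 1.60 e^{-0.0786 * 23.4}) => beta ~ 0.2215
    beta = 1.0 - respired_fraction(0.234)
    assert beta == pytest.approx(0.2215, abs=2e-4)
    # more clay -> more returned to BIO+HUM, less respired
    assert respired_fraction(0.40) < respired_fraction(0.05)


class TestStepSocPools:
    def _modifiers(self, grid, value=1.0):
        ones = np.full(grid.n_layers, value)
        return RateModifiers(f_temp=ones, f_moist=np.ones(grid.n_layers), f_veg=1.0)

    def test_zero_modifiers_give_litter_only(self, grid, soil):
        pools = sd.SocPools(np.full((4, 4), 25.0), grid=grid)
        new, co2, dec = step_soc_pools(pools, 10.0, self._modifiers(grid, 0.0), soil, 1800.0)
        assert co2 == 0.0
        assert dec.sum() == 0.0
        assert new.total == pytest.approx(pools.total + 10.0)

    def test_tiny_dt_limit(self, grid, soil):
        pools = sd.SocPools(np.full((4, 4), 25.0), grid=grid)
        new, co2, _ = step_soc_pools(pools, 0.0, self._modifiers(grid), soil, 1e-6)
        assert new.total == pytest.approx(pools.total, rel=1e-9)
        assert co2 == pytest.approx(0.0, abs=1e-6)

    def test_mass_conservation(self, grid, soil):
        pools = sd.SocPools(np.full((4, 4), 100.0), grid=grid)
        litter = 3.0
        new, co2, _ = step_soc_pools(pools, litter, self._modifiers(grid), soil, 86400.0)
        assert new.total - pools.total == pytest.approx(litter - co2, abs=1e-9)

    def test_pool_loss_ordering_follows_rates(self, grid, soil):
        pools = sd.SocPools(np.full((4, 4), 100.0), grid=grid)
        _, _, dec = step_soc_pools(pools, 0.0, self._modifiers(grid), soil, 86400.0)
        loss = {n: dec[i].sum() for i, n in enumerate(POOL_NAMES)}
        assert loss["DPM"] == max(loss.values())
        assert loss["HUM"] == min(loss.values())
        # full ordering mirrors the basal rates
        rate_order = np.argsort(DEFAULT_POOL_RATES)[::-1]
        losses = np.array([dec[i].sum() for i in range(4)])
        assert list(np.argsort(losses)[::-1]) == list(rate_order)

    def test_negative_litter_rejected(self, grid, soil):
        pools = sd.SocPools.zeros(grid)
        with pytest.raises(InvalidInputError):
            step_soc_pools(pools, -1.0, self._modifiers(grid), soil, 1800.0)

    @given(
        stocks=st.lists(st.floats(0.0, 1e4), min_size=16, max_size=16),
        mod=st.floats(0.0, 3.0),
        dt=st.floats(1.0, 1e6),
    )
    @settings(max_examples=40, deadline=None)
    def test_conservation_and_positivity_fuzz(self, stocks, mod, dt):
        grid = sd.LayerGrid()
        soil = sd.SoilProperties()
        pools = sd.SocPools(np.array(stocks).reshape(4, 4), grid=grid)
        ones = np.full(4, mod)
        mods = RateModifiers(f_temp=ones, f_moist=np.ones(4), f_veg=1.0)
        new, co2, _ = step_soc_pools(pools, 1.0, mods, soil, dt)
        assert np.all(new.stocks >= 0)
        throughput = pools.total + 1.0
        assert abs((new.total - pools.total) - (1.0 - co2)) <= 1e-8 * max(throughput, 1.0)


def test_socpools_invariants(grid):
    with pytest.raises(InvalidInputError):
        sd.SocPools(-np.ones((4, 4)), grid=grid)
    with pytest.raises(ConfigurationError):
        sd.SocPools(np.ones((4, 4)), rates=np.array([1e-9, 9.6e-9, 2.1e-8, 6.4e-10]), grid=grid)


def test_layer_grid_contract():
    g = sd.LayerGrid()
    assert g.n_layers == 4
    assert g.boundaries == (0.0, 0.10, 0.35, 1.00, 3.00)
    assert g.thickness.sum() == pytest.approx(3.0)
    assert g.surface_layers == slice(0, 2)
    with pytest.raises(ConfigurationError):
        sd.LayerGrid((0.0, 0.5, 0.2))
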