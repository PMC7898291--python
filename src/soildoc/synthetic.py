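"""Synthetic forcing scenarios and observation generators.

Real applications drive the column with site meteorology and hydrology;
for testing, calibration rehearsal and worked examples this module
fabricates statistically plausible stand-ins: seasonal-sinusoid soil
temperature with AR(1) weather noise damped and lagged with depth, AR(1)
soil moisture, Poisson-arrival gamma-sized precipitation events split
into surface runoff / sub-surface runoff / drainage, and a seasonal
litterfall cycle.  Observation sets are produced by running the
simulator with known "truth" parameters and applying multiplicative
lognormal noise, which makes parameter-recovery experiments possible.

All randomness flows through explicit seeds; the same scenario always
yields bit-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import column
from .calibration import ObservationSet
from .errors import ConfigurationError, InvalidInputError
from .forcing import ForcingSeries
from .params import BIOMES, BiomeParams
from .soil_carbon import LayerGrid

__all__ = [
    "SyntheticScenario",
    "default_scenario",
    "generate_forcing",
    "site_forcings",
    "generate_observations",
    "constant_forcing",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Statistical recipe for one biome's synthetic drivers.

    Temperatures in K, water in kg H₂O m⁻², litter and NPP in
    g C m⁻² yr⁻¹.  ``runoff_split`` is the (surface, sub-surface,
    drainage) partition of event water and must sum to 1.
    """

    biome: str = "temperate"
    years: int = 3
    seed: int = 0
    dt: float = 86400.0

    # temperature
    t_mean: float = 283.0
    t_seasonal_amp: float = 9.0
    t_noise_sd: float = 1.5
    t_ar1: float = 0.8
    t_damping_depth: float = 2.0   # m, annual wave e-folding
    t_peak_doy: int = 200

    # moisture
    s_mean: float = 0.55
    s_ar1: float = 0.9
    s_noise_sd: float = 0.04
    porosity: float = 0.45

    # precipitation events -> water export
    event_rate_per_day: float = 0.30
    event_mean_kg: float = 2.7
    event_shape: float = 1.5
    runoff_split: tuple[float, float, float] = (0.25, 0.45, 0.30)

    # carbon input
    litter_annual: float = 400.0
    litter_seasonal_amp: float = 0.4
    litter_peak_doy: int = 280
    veg_cover: float = 0.85
    npp_annual: float = 600.0

    # observation sampling
    obs_sigma: float = 0.2
    n_sites: int = 20
    n_dates: int = 12

    # site-to-site spread
    site_litter_spread: float = 0.15   # lognormal sigma
    site_temp_spread: float = 1.0      # K, normal
    site_runoff_spread: float = 0.2    # lognormal sigma

    def __post_init__(self) -> None:
        if self.years < 1 or self.n_sites < 1:
            raise ConfigurationError("years and n_sites must be >= 1")
        if self.n_dates < 2:
            raise ConfigurationError("each site needs at least two sampling dates")
        if not 0.0 <= self.t_ar1 < 1.0 or not 0.0 <= self.s_ar1 < 1.0:
            raise ConfigurationError("AR(1) coefficients must lie in [0, 1)")
        if abs(sum(self.runoff_split) - 1.0) > 1e-9:
            raise ConfigurationError("runoff_split must sum to 1")
        for name in ("t_noise_sd", "s_noise_sd", "event_rate_per_day",
                     "event_mean_kg", "obs_sigma", "litter_annual", "npp_annual"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def replace(self, **changes) -> "SyntheticScenario":
        return replace(self, **changes)


# Overland (surface) flow is a minor pathway under intact vegetation; most
# export leaves via interflow and drainage, hence the small first split entry.
_BIOME_SCENARIOS: dict[str, dict] = {
    "boreal": dict(t_mean=276.0, t_seasonal_amp=12.0, litter_annual=250.0,
                   event_rate_per_day=0.25, event_mean_kg=2.7,
                   runoff_split=(0.15, 0.45, 0.40), s_mean=0.60,
                   npp_annual=350.0, veg_cover=0.80),
    "temperate": dict(t_mean=283.0, t_seasonal_amp=9.0, litter_annual=400.0,
                      event_rate_per_day=0.30, event_mean_kg=2.8,
                      runoff_split=(0.08, 0.52, 0.40), s_mean=0.55,
                      npp_annual=600.0, veg_cover=0.85),
    "tropical": dict(t_mean=299.0, t_seasonal_amp=2.0, litter_annual=900.0,
                     event_rate_per_day=0.55, event_mean_kg=6.0,
                     runoff_split=(0.08, 0.52, 0.40), s_mean=0.65,
                     npp_annual=1100.0, veg_cover=0.95),
    "grass": dict(t_mean=285.0, t_seasonal_amp=11.0, litter_annual=350.0,
                  event_rate_per_day=0.28, event_mean_kg=2.0,
                  runoff_split=(0.15, 0.45, 0.40), s_mean=0.50,
                  npp_annual=500.0, veg_cover=0.70),
}


def default_scenario(biome: str, **overrides) -> SyntheticScenario:
    """The shipped scenario of one of the four calibration biomes."""
    if biome not in _BIOME_SCENARIOS:
        raise ConfigurationError(f"unknown biome {biome!r}; known: {sorted(BIOMES)}")
    kw = dict(_BIOME_SCENARIOS[biome])
    kw.update(overrides)
    return SyntheticScenario(biome=biome, **kw)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(max(1.0 - rho ** 2, 1e-12)), n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    out, _ = lfilter([1.0], [1.0, -rho], innov, zi=[0.0])
    return out


def generate_forcing(
    scenario: SyntheticScenario,
    site: int = 0,
    grid: LayerGrid | None = None,
    start: np.datetime64 = np.datetime64("2000-01-01", "s"),
) -> ForcingSeries:
    """Seed-deterministic forcing for one synthetic site.

    Per-layer temperature is the seasonal wave damped by
    ``exp(-z/zd)`` and phase-lagged by ``z/zd`` radians; moisture is an
    AR(1) walk around the scenario mean, smoother at depth; event water
    is split by ``runoff_split``.
    """
    grid = grid or LayerGrid()
    rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, site)))
    steps_per_day = int(round(86400.0 / scenario.dt))
    if abs(steps_per_day * scenario.dt - 86400.0) > 1e-6:
        raise ConfigurationError("dt must divide one day")
    n = scenario.years * 365 * steps_per_day
    day = np.arange(n) / steps_per_day
    z = grid.midpoints

    t_off = rng.normal(0.0, scenario.site_temp_spread)
    damp = np.exp(-z / scenario.t_damping_depth)
    phase = 2.0 * np.pi * (day[:, None] - scenario.t_peak_doy) / 365.0 - (z / scenario.t_damping_depth)[None, :]
    noise = _ar1(rng, n, scenario.t_ar1, scenario.t_noise_sd)
    t_soil = (scenario.t_mean + t_off
              + scenario.t_seasonal_amp * damp[None, :] * np.cos(phase)
              + noise[:, None] * damp[None, :])

    sat = np.empty((n, grid.n_layers))
    for i in range(grid.n_layers):
        sd_i = scenario.s_noise_sd * np.exp(-z[i] / 1.5)
        sat[:, i] = np.clip(scenario.s_mean + _ar1(rng, n, scenario.s_ar1, sd_i), 0.05, 0.98)
    water = sat * scenario.porosity * grid.thickness[None, :] * 1000.0

    r_scale = float(np.exp(rng.normal(0.0, scenario.site_runoff_spread)))
    n_events = rng.poisson(scenario.event_rate_per_day / steps_per_day, n)
    scale = scenario.event_mean_kg / scenario.event_shape if scenario.event_shape > 0 else 0.0
    event_water = np.where(
        n_events > 0,
        rng.gamma(np.maximum(n_events, 1) * scenario.event_shape, scale, n), 0.0,
    ) * r_scale
    if scenario.event_rate_per_day == 0.0:
        event_water = np.zeros(n)
    f_sr, f_ssr, f_dr = scenario.runoff_split
    surf_runoff, sub_runoff, drainage = (event_water * f for f in (f_sr, f_ssr, f_dr))

    l_scale = float(np.exp(rng.normal(0.0, scenario.site_litter_spread)))
    shape = 1.0 + scenario.litter_seasonal_amp * np.cos(
        2.0 * np.pi * (day - scenario.litter_peak_doy) / 365.0)
    shape = np.maximum(shape, 0.0)
    per_year = shape.reshape(scenario.years, -1)
    per_year = per_year / per_year.sum(axis=1, keepdims=True)
    litter = per_year.reshape(-1) * scenario.litter_annual * l_scale

    return ForcingSeries(
        start=start,
        dt=scenario.dt,
        t_soil=t_soil,
        water=water,
        sat_frac=sat,
        surf_runoff=surf_runoff,
        sub_runoff=sub_runoff,
        drainage=drainage,
        litter=litter,
        veg_cover=np.full(n, scenario.veg_cover),
        npp=np.full(n, scenario.npp_annual),
    )


def site_forcings(scenario: SyntheticScenario, grid: LayerGrid | None = None) -> dict[str, ForcingSeries]:
    """One forcing per synthetic site, keyed 'site00', 'site01', ..."""
    return {f"site{i:02d}": generate_forcing(scenario, site=i, grid=grid)
            for i in range(scenario.n_sites)}


def generate_observations(
    truth_params: BiomeParams,
    forcing_per_site: Mapping[str, ForcingSeries],
    scenario: SyntheticScenario,
    grid: LayerGrid | None = None,
    spinup: column.SpinupConfig | None = None,
) -> ObservationSet:
    """Noisy surface-soil DOC observations from a known-truth simulation.

    Runs every site to quasi-equilibrium with ``truth_params``, samples
    the surface (0–35 cm) concentration on ``n_dates`` seeded calendar
    days per site, and applies multiplicative lognormal noise
    ``exp(N(0, sigma^2))``.  With ``obs_sigma = 0`` the observations equal
    the simulated concentrations exactly.
    """
    if scenario.obs_sigma < 0:
        raise InvalidInputError("observation noise sigma must be non-negative")
    sites = sorted(forcing_per_site)
    forcings = [forcing_per_site[s] for s in sites]
    spinup = spinup or column.SpinupConfig(mode="direct", tol=1e-3, max_cycles=400)
    times, conc, _ = column.simulate_sites(truth_params, forcings, grid=grid, spinup=spinup)

    rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, 986533)))
    steps_per_day = int(round(86400.0 / scenario.dt))
    n_days = len(times) // steps_per_day
    rows = []
    for b, s in enumerate(sites):
        days = np.sort(rng.choice(n_days, size=scenario.n_dates, replace=False))
        for d in days:
            sel = slice(d * steps_per_day, (d + 1) * steps_per_day)
            value = float(conc[b, sel].mean())
            noisy = value * float(np.exp(rng.normal(0.0, scenario.obs_sigma))) \
                if scenario.obs_sigma > 0 else value
            rows.append({
                "site_id": s,
                "biome": scenario.biome,
                "depth_class": "surface",
                "date": times[d * steps_per_day].normalize(),
                "doc_mg_per_l": noisy,
            })
    return ObservationSet(pd.DataFrame(rows))


def constant_forcing(
    n_steps: int,
    dt: float = 86400.0,
    t_soil: float | np.ndarray = 288.15,
    sat_frac: float | np.ndarray = 0.6,
    surf_runoff: float = 0.1,
    sub_runoff: float = 0.15,
    drainage: float = 0.1,
    litter: float = 1.0,
    veg_cover: float = 0.85,
    porosity: float = 0.45,
    npp: float | None = None,
    grid: LayerGrid | None = None,
    start: np.datetime64 = np.datetime64("2000-01-01", "s"),
) -> ForcingSeries:
    """Time-invariant forcing — the workhorse of analytic steady-state tests.

    Scalars broadcast over steps and layers; water is derived from the
    saturation fraction and porosity.  ``litter`` and the water exports
    are per step.
    """
    grid = grid or LayerGrid()
    L = grid.n_layers
    t = np.broadcast_to(np.asarray(t_soil, dtype=float), (L,))
    s = np.broadcast_to(np.asarray(sat_frac, dtype=float), (L,))
    water = s * porosity * grid.thickness * 1000.0
    ones = np.ones(n_steps)
    return ForcingSeries(
        start=start,
        dt=dt,
        t_soil=np.tile(t, (n_steps, 1)),
        water=np.tile(water, (n_steps, 1)),
        sat_frac=np.tile(s, (n_steps, 1)),
        surf_runoff=ones * surf_runoff,
        sub_runoff=ones * sub_runoff,
        drainage=ones * drainage,
        litter=ones * litter,
        veg_cover=ones * veg_cover,
        npp=None if npp is None else ones * npp,
    )
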