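"""RothC-style soil organic carbon pools on a four-layer column.

The solid-phase carbon is held in the four classic RothC pools — DPM
(decomposable plant material), RPM (resistant plant material), BIO
(microbial biomass) and HUM (humus) — each decaying at a basal first-order
rate scaled by dimensionless environmental rate modifiers for temperature
(Q10 response), soil moisture (piecewise-linear between wilting point and
optimum) and vegetation cover (linear, bare soil fastest).  Carbon is
distributed over the soil layers with an exponential decline in depth
controlled by an e-folding length ``z*``.

Stocks are in g C m⁻², rates in s⁻¹, depths in m throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "POOL_NAMES",
    "DEFAULT_POOL_RATES",
    "DEFAULT_BOUNDARIES",
    "LayerGrid",
    "SocPools",
    "RateModifiers",
    "SoilProperties",
    "rate_modifier_temperature",
    "rate_modifier_moisture",
    "rate_modifier_vegetation",
    "combined_rate_modifier",
    "distribute_vertically",
    "respired_fraction",
    "step_soc_pools",
]

#: RothC pool order used everywhere in the package.
POOL_NAMES = ("DPM", "RPM", "BIO", "HUM")

#: Basal decomposition rates, s⁻¹, in POOL_NAMES order.  DPM is the fastest.
DEFAULT_POOL_RATES = np.array([3.2e-7, 9.6e-9, 2.1e-8, 6.4e-10])

#: Layer boundaries of the default column, m: 0–10, 10–35, 35–100, 100–300 cm.
DEFAULT_BOUNDARIES = (0.0, 0.10, 0.35, 1.00, 3.00)

#: Fraction of the BIO+HUM return flux credited to BIO (RothC convention).
BIO_RETURN_FRACTION = 0.46

#: Moisture rate-modifier floor at/below the wilting point.
MOISTURE_FLOOR = 0.2

#: Vegetation rate modifier under full cover (bare soil = 1).
VEGETATION_FLOOR = 0.6


@dataclass(frozen=True)
class LayerGrid:
    """Vertical discretisation of the soil column.

    Layers are indexed top-down.  The default grid has four layers with
    boundaries at 0, 0.10, 0.35, 1.00 and 3.00 m.
    """

    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ConfigurationError("grid needs at least two boundaries")
        if not np.all(np.diff(b) > 0):
            raise ConfigurationError("layer boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", tuple(float(x) for x in b))

    @property
    def n_layers(self) -> int:
        return len(self.boundaries) - 1

    @property
    def tops(self) -> np.ndarray:
        return np.asarray(self.boundaries[:-1])

    @property
    def bottoms(self) -> np.ndarray:
        return np.asarray(self.boundaries[1:])

    @property
    def thickness(self) -> np.ndarray:
        return self.bottoms - self.tops

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.tops + self.bottoms)

    @property
    def interface_spacing(self) -> np.ndarray:
        """Midpoint-to-midpoint distance across each internal interface, m."""
        return np.diff(self.midpoints)

    @property
    def total_depth(self) -> float:
        return self.boundaries[-1] - self.boundaries[0]

    @property
    def surface_layers(self) -> slice:
        """Layers whose bottom is within the 0–35 cm 'surface soil' band."""
        n = int(np.searchsorted(self.bottoms, 0.35 + 1e-12))
        return slice(0, max(n, 1))


def default_grid() -> LayerGrid:
    return LayerGrid()


@dataclass
class SocPools:
    """Per-layer stocks of the four RothC pools.

    ``stocks`` has shape ``(4, n_layers)`` (pool-major) in g C m⁻².
    """

    stocks: np.ndarray
    rates: np.ndarray = field(default_factory=lambda: DEFAULT_POOL_RATES.copy())
    grid: LayerGrid = field(default_factory=LayerGrid)

    def __post_init__(self) -> None:
        self.stocks = np.array(self.stocks, dtype=float)
        self.rates = np.array(self.rates, dtype=float)
        if self.stocks.shape != (len(POOL_NAMES), self.grid.n_layers):
            raise InvalidInputError(
                f"stocks must have shape (4, {self.grid.n_layers}), "
                f"got {self.stocks.shape}"
            )
        if np.any(self.stocks < 0):
            raise InvalidInputError("SOC stocks must be non-negative")
        if np.any(self.rates <= 0):
            raise ConfigurationError("pool decomposition rates must be positive")
        if self.rates[0] < self.rates.max():
            raise ConfigurationError("DPM must have the largest basal rate")

    @classmethod
    def zeros(cls, grid: LayerGrid | None = None, rates: np.ndarray | None = None) -> "SocPools":
        grid = grid or LayerGrid()
        kwargs = {} if rates is None else {"rates": np.asarray(rates, dtype=float)}
        return cls(np.zeros((len(POOL_NAMES), grid.n_layers)), grid=grid, **kwargs)

    @property
    def total(self) -> float:
        return float(self.stocks.sum())

    @property
    def per_pool(self) -> dict[str, float]:
        return {n: float(self.stocks[i].sum()) for i, n in enumerate(POOL_NAMES)}

    def copy(self) -> "SocPools":
        return SocPools(self.stocks.copy(), self.rates.copy(), self.grid)


@dataclass
class RateModifiers:
    """Per-layer dimensionless rate modifiers and their product."""

    f_temp: np.ndarray
    f_moist: np.ndarray
    f_veg: float
    q10: float = 2.0
    t_ref: float = 298.15

    def __post_init__(self) -> None:
        self.f_temp = np.atleast_1d(np.asarray(self.f_temp, dtype=float))
        self.f_moist = np.atleast_1d(np.asarray(self.f_moist, dtype=float))
        if np.any(self.f_temp < 0) or np.any(self.f_moist < 0) or self.f_veg < 0:
            raise InvalidInputError("rate modifiers must be non-negative")

    @property
    def combined(self) -> np.ndarray:
        return self.f_temp * self.f_moist * self.f_veg


@dataclass(frozen=True)
class SoilProperties:
    """Static physical soil properties of a column."""

    clay: float = 0.20
    silt: float = 0.35
    ph: float = 5.5
    zstar: float = 0.35
    s_wilt: float = 0.15
    s_opt: float = 0.70

    def __post_init__(self) -> None:
        for name in ("clay", "silt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} fraction must be in [0, 1], got {v}")
        if self.zstar <= 0:
            raise ConfigurationError("e-folding depth z* must be positive")
        if not self.s_wilt < self.s_opt:
            raise ConfigurationError("wilting point must be below the optimum")


def rate_modifier_temperature(t_kelvin, q10: float = 2.0, t_ref: float = 298.15):
    """Q10 temperature rate modifier, 1 at the reference temperature.

    ``q10 ** ((T - t_ref) / 10)`` — doubles (for q10 = 2) per 10 K warming.
    """
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t <= 0):
        raise InvalidInputError("temperature must be positive (kelvin)")
    out = q10 ** ((t - t_ref) / 10.0)
    return float(out) if np.isscalar(t_kelvin) else out


def rate_modifier_moisture(s, s_wilt: float, s_opt: float):
    """Moisture rate modifier on fraction-of-saturation ``s``.

    0.2 at or below the wilting point, rising linearly to 1.0 at the
    optimum, clamped to [0.2, 1] (supra-optimal moisture is not penalised).
    """
    if s_wilt >= s_opt:
        raise ConfigurationError("s_wilt must be < s_opt")
    sv = np.asarray(s, dtype=float)
    ramp = MOISTURE_FLOOR + (1.0 - MOISTURE_FLOOR) * (sv - s_wilt) / (s_opt - s_wilt)
    out = np.clip(ramp, MOISTURE_FLOOR, 1.0)
    return float(out) if np.isscalar(s) else out


def rate_modifier_vegetation(veg_cover):
    """Vegetation rate modifier: 1 on bare soil, 0.6 under full cover."""
    v = np.asarray(veg_cover, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise InvalidInputError("vegetation cover must be in [0, 1]")
    out = 1.0 - (1.0 - VEGETATION_FLOOR) * v
    return float(out) if np.isscalar(veg_cover) else out


def combined_rate_modifier(
    t_kelvin: np.ndarray,
    s: np.ndarray,
    veg_cover: float,
    soil: SoilProperties,
    q10: float = 2.0,
    t_ref: float = 298.15,
) -> RateModifiers:
    """Assemble per-layer modifiers from forcing and soil properties."""
    return RateModifiers(
        f_temp=rate_modifier_temperature(t_kelvin, q10, t_ref),
        f_moist=rate_modifier_moisture(s, soil.s_wilt, soil.s_opt),
        f_veg=float(rate_modifier_vegetation(veg_cover)),
        q10=q10,
        t_ref=t_ref,
    )


def vertical_fractions(z_star: float, grid: LayerGrid) -> np.ndarray:
    """Layer fractions of an exponentially declining profile, summing to 1.

    fraction_i = (exp(-z_top/z*) - exp(-z_bot/z*)) / (1 - exp(-z_max/z*)).
    """
    if z_star <= 0:
        raise InvalidInputError("z_star must be positive")
    top, bot = grid.tops, grid.bottoms
    z_max = grid.boundaries[-1]
    denom = 1.0 - np.exp(-z_max / z_star)
    if denom < 1e-12:
        # z* far larger than the column: uniform-in-depth limit.
        return grid.thickness / grid.total_depth
    frac = (np.exp(-top / z_star) - np.exp(-bot / z_star)) / denom
    return frac


def distribute_vertically(total, z_star: float, grid: LayerGrid) -> np.ndarray:
    """Spread a column-total stock over layers by the exponential profile.

    ``total`` may be a scalar or a vector of per-pool totals; the result
    gains a trailing layer axis and sums back to the input exactly.
    """
    tot = np.asarray(total, dtype=float)
    if np.any(tot < 0):
        raise InvalidInputError("total stock must be non-negative")
    frac = vertical_fractions(z_star, grid)
    frac = frac / frac.sum()  # exact unit sum against float rounding
    return tot[..., None] * frac


def respired_fraction(clay: float) -> float:
    """RothC respired fraction (1 - beta) of decomposed carbon.

    beta = 1 / (1 + x) with x = 1.67 (1.85 + 1.60 exp(-0.0786 clay%)),
    the RothC CO2/(BIO+HUM) partition as a function of clay content.
    Returns 1 - beta, i.e. the CO2 share.
    """
    x = 1.67 * (1.85 + 1.60 * np.exp(-0.0786 * clay * 100.0))
    beta = 1.0 / (1.0 + x)
    return float(1.0 - beta)


def step_soc_pools(
    pools: SocPools,
    litter_in: float,
    modifiers: RateModifiers,
    soil: SoilProperties,
    dt: float,
    dpm_fraction: float = 0.25,
) -> tuple[SocPools, float, np.ndarray]:
    """Advance the RothC pools one time step.

    Each pool loses ``stock * (1 - exp(-k_n * modifier_i * dt))``; of the
    decomposed carbon a clay-dependent fraction is respired as CO2 and the
    remainder returns to BIO and HUM (46:54).  Litter input is split
    DPM:RPM by ``dpm_fraction`` and distributed over layers with the
    exponential depth profile.

    Returns ``(new_pools, co2_flux, decomposition per pool-layer)``.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    if litter_in < 0:
        raise InvalidInputError("litter input must be non-negative")

    mod = modifiers.combined
    if mod.shape != (pools.grid.n_layers,):
        raise InvalidInputError(
            f"modifiers must be per-layer ({pools.grid.n_layers},), got {mod.shape}"
        )

    stocks = pools.stocks.copy()
    frac = -np.expm1(-pools.rates[:, None] * mod[None, :] * dt)
    decomposed = stocks * frac
    stocks -= decomposed

    co2_share = respired_fraction(soil.clay)
    dec_per_layer = decomposed.sum(axis=0)
    co2 = co2_share * dec_per_layer
    returned = (1.0 - co2_share) * dec_per_layer
    stocks[POOL_NAMES.index("BIO")] += BIO_RETURN_FRACTION * returned
    stocks[POOL_NAMES.index("HUM")] += (1.0 - BIO_RETURN_FRACTION) * returned

    litter_profile = vertical_fractions(soil.zstar, pools.grid)
    stocks[POOL_NAMES.index("DPM")] += dpm_fraction * litter_in * litter_profile
    stocks[POOL_NAMES.index("RPM")] += (1.0 - dpm_fraction) * litter_in * litter_profile

    new = SocPools(stocks, pools.rates.copy(), pools.grid)
    return new, float(co2.sum()), decomposed
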