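"""Dissolved organic carbon process kinetics.

Five first-order processes move carbon through the two DOC classes
(labile, fed by the DPM and BIO pools; recalcitrant, fed by RPM and HUM):

* production — extraction from a solid pool, ``S (1 - exp(-K_p m dt))``
  with K_p a basal rate in day⁻¹ and m the combined rate modifier;
* decomposition — ``S (1 - exp(-(dt / K_DOC) F_T))`` where K_DOC is a
  turnover time in days and F_T the temperature-only modifier; a CUE
  fraction of the decomposed mass returns to the humus pool, the rest is
  respired as CO2;
* sorption — instantaneous linear-isotherm partition between a mobile
  dissolved and an inert adsorbed phase, ``dissolved = total / (1 + Kd)``
  with ``log10 Kd = a0 + a1 pH + a2 clay``;
* vertical diffusion — Fickian exchange of dissolved DOC between layer
  midpoints, zero-flux at the top and bottom of the column;
* leaching — advective export, ``S min(Roff / TS, 1)``: surface runoff
  drains the two layers above 35 cm, sub-surface runoff plus drainage the
  layers below.

Stocks in g C m⁻², water in kg H₂O m⁻² (1 kg ≡ 1 L), concentrations in
mg C L⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateWaterStateError, InvalidInputError
from .soil_carbon import LayerGrid

__all__ = [
    "DOC_CLASSES",
    "POOL_TO_CLASS",
    "CLASS_MATRIX",
    "DocPools",
    "DocKinetics",
    "WaterState",
    "doc_production",
    "doc_decomposition",
    "sorption_coefficient",
    "sorption_partition",
    "vertical_diffusion",
    "doc_leaching",
    "doc_concentration",
]

#: DOC class order used throughout.
DOC_CLASSES = ("labile", "recalcitrant")

#: Source solid pool -> DOC class (DPM, BIO -> labile; RPM, HUM -> recalcitrant).
POOL_TO_CLASS = {"DPM": "labile", "BIO": "labile", "RPM": "recalcitrant", "HUM": "recalcitrant"}

#: (2, 4) routing matrix: class c receives pool p iff CLASS_MATRIX[c, p] == 1.
CLASS_MATRIX = np.array([[1.0, 0.0, 1.0, 0.0],
                         [0.0, 1.0, 0.0, 1.0]])


@dataclass
class DocPools:
    """Per-layer dissolved and adsorbed stocks of the two DOC classes.

    Both arrays have shape ``(2, n_layers)`` in g C m⁻².  Adsorbed DOC is
    inert and immobile: it is never decomposed, diffused or leached.
    """

    dissolved: np.ndarray
    adsorbed: np.ndarray
    grid: LayerGrid = field(default_factory=LayerGrid)

    def __post_init__(self) -> None:
        self.dissolved = np.array(self.dissolved, dtype=float)
        self.adsorbed = np.array(self.adsorbed, dtype=float)
        shape = (len(DOC_CLASSES), self.grid.n_layers)
        for name, arr in (("dissolved", self.dissolved), ("adsorbed", self.adsorbed)):
            if arr.shape != shape:
                raise InvalidInputError(f"{name} must have shape {shape}, got {arr.shape}")
            if np.any(arr < 0):
                raise InvalidInputError(f"{name} DOC stocks must be non-negative")

    @classmethod
    def zeros(cls, grid: LayerGrid | None = None) -> "DocPools":
        grid = grid or LayerGrid()
        shape = (len(DOC_CLASSES), grid.n_layers)
        return cls(np.zeros(shape), np.zeros(shape), grid)

    @property
    def total(self) -> float:
        return float(self.dissolved.sum() + self.adsorbed.sum())

    def copy(self) -> "DocPools":
        return DocPools(self.dissolved.copy(), self.adsorbed.copy(), self.grid)


@dataclass(frozen=True)
class DocKinetics:
    """Kinetic and physical DOC parameters.

    kp            basal DOC production rate, day⁻¹ (applied to every pool)
    kdoc_labile   labile DOC turnover time, days
    kdoc_recalcitrant
                  recalcitrant DOC turnover time, days
    cue           carbon use efficiency of DOC decomposition, fraction
    sorb_a0/a1/a2 linear-isotherm coefficients: log10 Kd = a0 + a1 pH + a2 clay
    d_coeff       molecular diffusion coefficient of DOC, m² s⁻¹
    """

    kp: float = 1.0
    kdoc_labile: float = 600.0
    kdoc_recalcitrant: float = 600.0
    cue: float = 0.5
    sorb_a0: float = 0.0
    sorb_a1: float = -0.1
    sorb_a2: float = 1.5
    d_coeff: float = 1.06e-9

    def __post_init__(self) -> None:
        if self.kp <= 0:
            raise ConfigurationError("kp must be positive")
        if self.kdoc_labile <= 0 or self.kdoc_recalcitrant <= 0:
            raise ConfigurationError("K_DOC turnover times must be positive")
        if not 0.0 <= self.cue <= 1.0:
            raise ConfigurationError("CUE must be in [0, 1]")
        if self.d_coeff < 0:
            raise ConfigurationError("diffusion coefficient must be non-negative")

    @property
    def kdoc(self) -> np.ndarray:
        """Turnover times in DOC_CLASSES order, days."""
        return np.array([self.kdoc_labile, self.kdoc_recalcitrant])


@dataclass
class WaterState:
    """Per-layer soil water and the water fluxes of one step, kg H₂O m⁻²."""

    layer_water: np.ndarray
    surf_runoff: float = 0.0
    sub_runoff: float = 0.0
    drainage: float = 0.0

    def __post_init__(self) -> None:
        self.layer_water = np.atleast_1d(np.asarray(self.layer_water, dtype=float))
        if np.any(self.layer_water < 0):
            raise InvalidInputError("layer water must be non-negative")
        for name in ("surf_runoff", "sub_runoff", "drainage"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")


def doc_production(soc_stock, kp: float, modifier, dt_days: float):
    """DOC mass extracted from a solid pool in one step, g C m⁻².

    ``stock * (1 - exp(-kp * modifier * dt))``; never exceeds the stock.
    The caller debits the source pool and credits the matching DOC class.
    """
    stock = np.asarray(soc_stock, dtype=float)
    if np.any(stock < 0):
        raise InvalidInputError("SOC stock must be non-negative")
    if kp < 0 or dt_days < 0 or np.any(np.asarray(modifier) < 0):
        raise InvalidInputError("kp, modifier and dt must be non-negative")
    out = stock * -np.expm1(-kp * np.asarray(modifier, dtype=float) * dt_days)
    return float(out) if out.ndim == 0 else out


def doc_decomposition(doc_stock, kdoc: float, ft, cue: float, dt_days: float):
    """Decompose dissolved DOC; split the loss by carbon use efficiency.

    ``decomposed = stock * (1 - exp(-(dt / kdoc) * ft))`` with ``kdoc`` a
    turnover time in days.  Returns ``(decomposed, to_soc, to_co2)`` with
    ``to_soc = cue * decomposed`` (credited to humus by the column stepper)
    and ``to_soc + to_co2 == decomposed`` exactly.
    """
    if kdoc <= 0:
        raise ConfigurationError("kdoc must be a positive turnover time (days)")
    if not 0.0 <= cue <= 1.0:
        raise ConfigurationError("CUE must be in [0, 1]")
    stock = np.asarray(doc_stock, dtype=float)
    if np.any(stock < 0):
        raise InvalidInputError("DOC stock must be non-negative")
    decomposed = stock * -np.expm1(-(dt_days / kdoc) * np.asarray(ft, dtype=float))
    to_soc = cue * decomposed
    to_co2 = decomposed - to_soc
    if decomposed.ndim == 0:
        return float(decomposed), float(to_soc), float(to_co2)
    return decomposed, to_soc, to_co2


def sorption_coefficient(ph: float, clay: float,
                         a0: float = 0.0, a1: float = -0.1, a2: float = 1.5) -> float:
    """Dimensionless linear-isotherm partition coefficient Kd.

    ``log10 Kd = a0 + a1 * pH + a2 * clay_fraction``.
    """
    return float(10.0 ** (a0 + a1 * ph + a2 * clay))


def sorption_partition(total_doc, kd: float):
    """Equilibrium split of total DOC into (dissolved, adsorbed).

    ``dissolved = total / (1 + kd)``; the two parts sum to the input exactly.
    """
    if kd < 0:
        raise InvalidInputError("kd must be non-negative")
    total = np.asarray(total_doc, dtype=float)
    if np.any(total < 0):
        raise InvalidInputError("total DOC must be non-negative")
    dissolved = total / (1.0 + kd)
    adsorbed = total - dissolved
    if total.ndim == 0:
        return float(dissolved), float(adsorbed)
    return dissolved, adsorbed


def vertical_diffusion(conc_profile, d_coeff: float, grid: LayerGrid, dt: float):
    """Fickian interface fluxes over one step, g C m⁻², positive downward.

    ``flux = D * (C_i - C_{i+1}) / dz_mid * dt`` per internal interface
    (1 mg C L⁻¹ ≡ 1 g C m⁻³), zero-flux boundaries.  The explicit update is
    stable for the package's default step; callers needing large steps get
    sub-stepping in the column engine.
    """
    conc = np.asarray(conc_profile, dtype=float)
    if conc.shape[-1] != grid.n_layers:
        raise InvalidInputError("concentration profile must be per-layer")
    if grid.n_layers < 2:
        return np.zeros(conc.shape[:-1] + (0,))
    dz = grid.interface_spacing
    return d_coeff * (conc[..., :-1] - conc[..., 1:]) / dz * dt


def doc_leaching(doc_dissolved, roff: float, ts: float):
    """Advective DOC export of one step, g C m⁻².

    ``stock * min(roff / ts, 1)`` — the leached fraction is the fraction of
    the layer's water exported this step, capped at the whole stock.
    """
    if roff < 0:
        raise InvalidInputError("runoff must be non-negative")
    stock = np.asarray(doc_dissolved, dtype=float)
    if np.any(stock < 0):
        raise InvalidInputError("DOC stock must be non-negative")
    if roff == 0:
        out = np.zeros_like(stock)
        return float(out) if out.ndim == 0 else out
    if ts <= 0:
        raise DegenerateWaterStateError("runoff with no soil water in the layer")
    out = stock * min(roff / ts, 1.0)
    return float(out) if out.ndim == 0 else out


def doc_concentration(doc_dissolved, water):
    """Concentration in mg C L⁻¹ from stock (g C m⁻²) and water (kg m⁻²).

    1 kg of water occupies 1 L, so ``conc = 1000 * stock / water``.
    """
    stock = np.asarray(doc_dissolved, dtype=float)
    w = np.asarray(water, dtype=float)
    if np.any(w <= 0):
        raise DegenerateWaterStateError("concentration requested with no water")
    out = 1000.0 * stock / w
    return float(out) if out.ndim == 0 else out
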