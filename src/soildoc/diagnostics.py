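"""Turnover diagnostics and carbon-budget bookkeeping.

Three first-order time constants summarise a simulated column or region:

* ``K_prod``  — annual DOC production per unit SOC stock, yr⁻¹;
* ``K_dec``   — annual DOC decomposition per unit DOC stock, yr⁻¹;
* ``K_leach`` — annual DOC leaching per unit DOC stock, yr⁻¹;

with the DOC residence time ``τ_DOC = 1 / (K_dec + K_leach)`` and, near
steady state, ``DOC ≈ SOC · K_prod / (K_dec + K_leach)``.

The budget side aggregates regional stocks and fluxes into a
:class:`BudgetSummary` with the ecosystem-exchange identities
``NEP = NPP − Rh``, ``NEE = −NEP``, ``NBP = NEE − E_LUC`` and the export
ratios DOC_LCE/NPP and DOC_LCE/NEP (in percent).  Heterotrophic
respiration Rh is assembled from the simulated SOC- and DOC-derived CO2
fluxes; NPP and E_LUC are supplied numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MisalignedSeriesError

__all__ = [
    "TurnoverDiagnostics",
    "BudgetSummary",
    "turnover_rates",
    "steady_state_doc",
    "budget_summary",
    "running_mean",
    "relative_change",
]


@dataclass(frozen=True)
class TurnoverDiagnostics:
    """First-order DOC time constants, yr⁻¹ (τ in years).

    ``tau_doc`` is NaN when both loss rates are zero (undefined).
    """

    k_prod: float
    k_dec: float
    k_leach: float

    def __post_init__(self) -> None:
        for name in ("k_prod", "k_dec", "k_leach"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    @property
    def tau_doc(self) -> float:
        denom = self.k_dec + self.k_leach
        return 1.0 / denom if denom > 0 else float("nan")

    @property
    def tau_doc_days(self) -> float:
        return self.tau_doc * 365.0


def turnover_rates(
    annual_production: float,
    annual_decomposition: float,
    annual_leaching: float,
    soc_stock: float,
    doc_stock: float,
) -> TurnoverDiagnostics:
    """Diagnose K_prod, K_dec, K_leach from annual fluxes and mean stocks.

    Fluxes in g C m⁻² yr⁻¹ (or any mass/yr), stocks in the same mass
    unit.  A zero stock with a non-zero flux leaves that rate NaN
    (undefined) rather than raising.
    """
    def ratio(flux: float, stock: float) -> float:
        if flux < 0 or stock < 0:
            raise InvalidInputError("fluxes and stocks must be non-negative")
        if stock == 0:
            return 0.0 if flux == 0 else float("nan")
        return flux / stock

    return TurnoverDiagnostics(
        k_prod=ratio(annual_production, soc_stock),
        k_dec=ratio(annual_decomposition, doc_stock),
        k_leach=ratio(annual_leaching, doc_stock),
    )


def steady_state_doc(soc_stock: float, diag: TurnoverDiagnostics) -> float:
    """Near-steady-state DOC stock: SOC · K_prod / (K_dec + K_leach)."""
    denom = diag.k_dec + diag.k_leach
    if not denom > 0:
        raise InvalidInputError("K_dec + K_leach must be positive for a steady state")
    if soc_stock < 0:
        raise InvalidInputError("SOC stock must be non-negative")
    return soc_stock * diag.k_prod / denom


@dataclass
class BudgetSummary:
    """Regional + global carbon budget table.

    ``table`` rows are regions plus a ``global`` row that is the exact
    sum over regions for every extensive quantity; ratio columns are
    computed from the (unrounded) summed components.
    """

    table: pd.DataFrame

    def region(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def global_row(self) -> pd.Series:
        return self.table.loc["global"]


def budget_summary(
    regions: dict[str, dict[str, float]],
    closure_tol: float = 1e-6,
) -> BudgetSummary:
    """Assemble the budget table from per-region aggregates.

    Each region supplies (consistent mass/yr units throughout):
    ``production``, ``doc_co2``, ``soc_return``, ``leached``,
    ``doc_stock``, ``delta_doc_stock``, ``npp``, ``soc_co2`` and
    optionally ``e_luc`` (default 0).

    Derived per region and for the global sum: Rh = soc_co2 + doc_co2,
    NEP = NPP − Rh, NEE = −NEP, NBP = NEE − E_LUC, leached share of
    production (%), DOC_LCE/NPP (%) and DOC_LCE/NEP (%, only when
    NEP > 0).  Raises when a region's DOC budget fails to close:
    production = doc_co2 + soc_return + leached + Δstock.
    """
    if not regions:
        raise InvalidInputError("need at least one region")
    required = {"production", "doc_co2", "soc_return", "leached",
                "doc_stock", "delta_doc_stock", "npp", "soc_co2"}
    rows = {}
    for name, agg in regions.items():
        missing = required - set(agg)
        if missing:
            raise MisalignedSeriesError(
                f"region {name!r} missing budget entries: {sorted(missing)}")
        rows[name] = dict(agg)
        rows[name].setdefault("e_luc", 0.0)

    df = pd.DataFrame.from_dict(rows, orient="index")
    closure = df["production"] - (df["doc_co2"] + df["soc_return"]
                                  + df["leached"] + df["delta_doc_stock"])
    scale = df["production"].abs().clip(lower=1e-12)
    bad = closure.abs() / scale > closure_tol
    if bad.any():
        raise InvalidInputError(
            f"DOC budget does not close for regions {list(df.index[bad])}: "
            f"relative defects {list((closure.abs() / scale)[bad].round(9))}")

    total = df.sum(axis=0)
    df.loc["global"] = total

    df["rh"] = df["soc_co2"] + df["doc_co2"]
    df["nep"] = df["npp"] - df["rh"]
    df["nee"] = -df["nep"]
    df["nbp"] = df["nee"] - df["e_luc"]
    df["leached_share_pct"] = 100.0 * df["leached"] / df["production"].where(df["production"] > 0)
    df["doc_lce_npp_pct"] = 100.0 * df["leached"] / df["npp"].where(df["npp"] > 0)
    df["doc_lce_nep_pct"] = 100.0 * df["leached"] / df["nep"].where(df["nep"] > 0)
    return BudgetSummary(df)


def running_mean(series, window: int = 10):
    """Centred moving average; ends use the shorter valid window.

    With ``window = 1`` this is the identity.  Accepts any 1-d sequence
    or pandas Series; returns the same type.
    """
    values = series.to_numpy() if isinstance(series, pd.Series) else np.asarray(series, dtype=float)
    if window < 1:
        raise InvalidInputError("window must be >= 1")
    if window > values.size:
        raise InvalidInputError(
            f"window ({window}) exceeds series length ({values.size})")
    out = (pd.Series(values)
           .rolling(window, center=True, min_periods=1)
           .mean()
           .to_numpy())
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out


def relative_change(baseline: float, later: float) -> float:
    """Percent change of ``later`` relative to ``baseline``."""
    if baseline == 0:
        raise InvalidInputError("relative change undefined for zero baseline")
    return 100.0 * (later - baseline) / baseline
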