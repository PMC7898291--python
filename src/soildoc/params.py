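"""Per-biome parameter sets and the packaged biome table.

A :class:`BiomeParams` bundles everything site-independent the column
stepper needs: DOC kinetics (K_p, K_DOC, CUE, sorption, diffusion), the
rate-modifier configuration (Q10, reference temperature, moisture points),
the litter DPM:RPM split and the soil properties (clay, pH, e-folding
depth).  Defaults for the four calibration biomes — boreal forest,
temperate forest, tropical/subtropical forest, grassland/cropland — ship
as a packaged CSV together with the literature calibration bounds for
K_p (day⁻¹) and the recalcitrant K_DOC (days), and the optimized pairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .doc_dynamics import DocKinetics
from .errors import ConfigurationError
from .soil_carbon import DEFAULT_POOL_RATES, SoilProperties

__all__ = [
    "BIOMES",
    "BiomeParams",
    "load_biome_table",
    "default_params",
    "optimized_params",
    "calibration_bounds",
]

#: Canonical biome keys, with human labels.
BIOMES = {
    "boreal": "boreal forest",
    "temperate": "temperate forest",
    "tropical": "tropical/subtropical forest",
    "grass": "grassland and cropland",
}


@dataclass(frozen=True)
class BiomeParams:
    """Kinetic and physical parameters of one biome."""

    name: str = "temperate"
    # DOC kinetics
    kp: float = 1.0                  # basal DOC production rate, day-1
    kdoc_labile: float = 600.0       # labile DOC turnover time, days
    kdoc_recalcitrant: float = 600.0 # recalcitrant DOC turnover time, days
    cue: float = 0.5                 # carbon use efficiency, fraction
    sorb_a0: float = 0.0
    sorb_a1: float = -0.1
    sorb_a2: float = 1.5
    d_coeff: float = 1.06e-9         # DOC molecular diffusion, m2 s-1
    # rate modifiers
    q10: float = 2.0
    t_ref: float = 298.15            # K
    # litter split
    dpm_fraction: float = 0.25       # DPM share of litter input
    # soil
    clay: float = 0.20
    silt: float = 0.35
    ph: float = 5.5
    zstar: float = 0.35              # SOC e-folding depth, m
    s_wilt: float = 0.15
    s_opt: float = 0.70
    # RothC basal rates, s-1 (DPM, RPM, BIO, HUM)
    pool_rates: tuple[float, ...] = tuple(DEFAULT_POOL_RATES)
    # calibration bounds
    kp_bounds: tuple[float, float] = (1.0, 2.0)
    kdoc_bounds: tuple[float, float] = (500.0, 4545.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dpm_fraction <= 1.0:
            raise ConfigurationError("dpm_fraction must be in [0, 1]")
        self.kinetics()  # validates the kinetic block
        self.soil()      # validates the soil block

    def kinetics(self) -> DocKinetics:
        return DocKinetics(
            kp=self.kp,
            kdoc_labile=self.kdoc_labile,
            kdoc_recalcitrant=self.kdoc_recalcitrant,
            cue=self.cue,
            sorb_a0=self.sorb_a0,
            sorb_a1=self.sorb_a1,
            sorb_a2=self.sorb_a2,
            d_coeff=self.d_coeff,
        )

    def soil(self) -> SoilProperties:
        return SoilProperties(
            clay=self.clay, silt=self.silt, ph=self.ph,
            zstar=self.zstar, s_wilt=self.s_wilt, s_opt=self.s_opt,
        )

    def replace(self, **changes) -> "BiomeParams":
        return dataclasses.replace(self, **changes)


def _packaged_table() -> Path:
    return Path(str(resources.files("soildoc").joinpath("data/biome_params.csv")))


def load_biome_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read a biome parameter table (packaged defaults when path is None)."""
    df = pd.read_csv(path if path is not None else _packaged_table())
    required = {"biome", "kp_day", "kdoc_recalcitrant_day", "kdoc_lo", "kdoc_hi"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"biome table missing columns: {sorted(missing)}")
    return df.set_index("biome")


def _row_to_params(biome: str, row: pd.Series, kp: float, kdoc_rec: float) -> BiomeParams:
    return BiomeParams(
        name=biome,
        kp=float(kp),
        kdoc_labile=float(row["kdoc_labile_day"]),
        kdoc_recalcitrant=float(kdoc_rec),
        cue=float(row["cue"]),
        sorb_a0=float(row["sorb_a0"]),
        sorb_a1=float(row["sorb_a1"]),
        sorb_a2=float(row["sorb_a2"]),
        d_coeff=float(row["d_coeff_m2_s"]),
        q10=float(row["q10"]),
        t_ref=float(row["t_ref_k"]),
        dpm_fraction=float(row["dpm_fraction"]),
        clay=float(row["clay"]),
        silt=float(row["silt"]),
        ph=float(row["ph"]),
        zstar=float(row["zstar_m"]),
        s_wilt=float(row["s_wilt"]),
        s_opt=float(row["s_opt"]),
        kp_bounds=(float(row["kp_lo"]), float(row["kp_hi"])),
        kdoc_bounds=(float(row["kdoc_lo"]), float(row["kdoc_hi"])),
    )


def default_params(biome: str = "temperate", table: pd.DataFrame | None = None) -> BiomeParams:
    """Default (uncalibrated) parameters for a biome."""
    df = table if table is not None else load_biome_table()
    if biome not in df.index:
        raise ConfigurationError(f"unknown biome {biome!r}; known: {list(df.index)}")
    row = df.loc[biome]
    return _row_to_params(biome, row, row["kp_day"], row["kdoc_recalcitrant_day"])


def optimized_params(biome: str = "temperate", table: pd.DataFrame | None = None) -> BiomeParams:
    """Calibrated (K_p, K_DOC) parameters for a biome."""
    df = table if table is not None else load_biome_table()
    if biome not in df.index:
        raise ConfigurationError(f"unknown biome {biome!r}; known: {list(df.index)}")
    row = df.loc[biome]
    return _row_to_params(biome, row, row["kp_optimized"], row["kdoc_optimized"])


def calibration_bounds(biome: str, table: pd.DataFrame | None = None) -> dict[str, tuple[float, float]]:
    """K_p and K_DOC search ranges of one biome."""
    p = default_params(biome, table)
    return {"kp": p.kp_bounds, "kdoc": p.kdoc_bounds}
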