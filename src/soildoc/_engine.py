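"""Vectorised array kernel behind the column simulator.

The public modules (:mod:`soildoc.column`, :mod:`soildoc.calibration`)
delegate the per-step arithmetic to :func:`step`, which operates on raw
numpy arrays with an optional leading batch axis so that many columns
(e.g. all calibration sites) advance in lock-step at the cost of one.

Array conventions — trailing axes are (pool, layer) or (class, layer):

=============  =======================
soc            (..., 4, L)  g C m⁻²
dis / ads      (..., 2, L)  g C m⁻²
t, s, water    (..., L)
sr, ssr, dr,
litter, veg    (...,)
=============  =======================

Operator order within a step (fixed, documented in the methods note):
SOC decomposition → litter input → DOC production → sorption
equilibration → DOC decomposition → vertical diffusion → leaching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .doc_dynamics import sorption_coefficient
from .soil_carbon import (
    BIO_RETURN_FRACTION,
    LayerGrid,
    MOISTURE_FLOOR,
    VEGETATION_FLOOR,
    respired_fraction,
    vertical_fractions,
)

__all__ = ["EngineParams", "make_engine_params", "step", "run_batch"]


@dataclass(frozen=True)
class EngineParams:
    """Everything site-independent, precomputed into plain arrays."""

    k_soc: np.ndarray        # (4,) s-1
    kp_day: np.ndarray       # (4,) day-1
    kdoc_day: np.ndarray     # (2,) days (turnover times)
    cue: float
    co2_share: float         # RothC respired fraction (1 - beta)
    bio_frac: float          # BIO share of the BIO+HUM return
    kd: float                # sorption partition coefficient
    q10: float
    t_ref: float
    s_wilt: float
    s_opt: float
    dpm_fraction: float
    litter_profile: np.ndarray  # (L,), sums to 1
    d_coeff: float
    dz_mid: np.ndarray       # (L-1,) midpoint spacing, m
    dz_min: float            # smallest layer thickness, m
    surface_mask: np.ndarray  # (L,) bool: layers drained by surface runoff

    def with_rate_factors(self, factors: np.ndarray) -> "EngineParams":
        """Scale each pool's total first-order turnover (spin-up acceleration)."""
        f = np.asarray(factors, dtype=float)
        return replace(self, k_soc=self.k_soc * f, kp_day=self.kp_day * f)


def make_engine_params(params, grid: LayerGrid | None = None) -> EngineParams:
    """Flatten a :class:`~soildoc.params.BiomeParams` for the kernel."""
    grid = grid or LayerGrid()
    lp = vertical_fractions(params.zstar, grid)
    return EngineParams(
        k_soc=np.asarray(params.pool_rates, dtype=float),
        kp_day=np.full(4, float(params.kp)),
        kdoc_day=np.array([params.kdoc_labile, params.kdoc_recalcitrant], dtype=float),
        cue=float(params.cue),
        co2_share=respired_fraction(params.clay),
        bio_frac=BIO_RETURN_FRACTION,
        kd=sorption_coefficient(params.ph, params.clay,
                                params.sorb_a0, params.sorb_a1, params.sorb_a2),
        q10=float(params.q10),
        t_ref=float(params.t_ref),
        s_wilt=float(params.s_wilt),
        s_opt=float(params.s_opt),
        dpm_fraction=float(params.dpm_fraction),
        litter_profile=lp / lp.sum(),
        d_coeff=float(params.d_coeff),
        dz_mid=grid.interface_spacing,
        dz_min=float(grid.thickness.min()),
        surface_mask=grid.bottoms <= 0.35 + 1e-12,
    )


def diffusion_substeps(ep: EngineParams, dt: float) -> int:
    """Sub-step count keeping D·dt/Δz² ≤ 0.5 at every interface."""
    if ep.d_coeff == 0.0 or ep.dz_mid.size == 0:
        return 1
    return max(1, math.ceil(ep.d_coeff * dt / (0.5 * ep.dz_min ** 2)))


def step(soc, dis, ads, t, s, water, sr, ssr, dr, litter, veg, ep: EngineParams,
         dt: float, n_diff_sub: int | None = None):
    """Advance one step.  ``soc`` is modified in place; dis/ads are returned.

    Returns ``(soc, dis, ads, fluxes)`` where ``fluxes`` holds per-step
    flux arrays (see keys below), all in g C m⁻² per step:

    ``production`` (...,4,L), ``dec_soc`` (...,4,L), ``co2_soc`` (...,),
    ``dec_doc`` (...,2,L), ``co2_doc`` (...,), ``cue_return`` (...,),
    ``diffusion`` (...,2,L-1) positive downward, ``leach`` (...,L) summed
    over classes, ``leach_surface`` / ``leach_sub`` (...,).
    """
    dt_days = dt / 86400.0
    sr = np.asarray(sr, dtype=float)
    litter = np.asarray(litter, dtype=float)

    # --- rate modifiers ----------------------------------------------------
    ft = ep.q10 ** ((t - ep.t_ref) * 0.1)
    fm = np.clip(MOISTURE_FLOOR + (1.0 - MOISTURE_FLOOR)
                 * (s - ep.s_wilt) / (ep.s_opt - ep.s_wilt), MOISTURE_FLOOR, 1.0)
    fv = 1.0 - (1.0 - VEGETATION_FLOOR) * np.asarray(veg, dtype=float)
    mod = ft * fm * fv[..., None]

    # --- RothC decomposition ----------------------------------------------
    dfrac = -np.expm1(-ep.k_soc[:, None] * mod[..., None, :] * dt)
    dec = soc * dfrac
    soc -= dec
    dec_layer = dec.sum(axis=-2)
    co2_soc_layer = ep.co2_share * dec_layer
    ret = dec_layer - co2_soc_layer
    soc[..., 2, :] += ep.bio_frac * ret
    soc[..., 3, :] += (1.0 - ep.bio_frac) * ret

    # --- litter input ------------------------------------------------------
    lit_layer = litter[..., None] * ep.litter_profile
    soc[..., 0, :] += ep.dpm_fraction * lit_layer
    soc[..., 1, :] += (1.0 - ep.dpm_fraction) * lit_layer

    # --- DOC production ----------------------------------------------------
    pfrac = -np.expm1(-ep.kp_day[:, None] * mod[..., None, :] * dt_days)
    prod = soc * pfrac
    soc -= prod
    # DPM, BIO feed labile; RPM, HUM feed recalcitrant
    dis = dis.copy()
    dis[..., 0, :] += prod[..., 0, :] + prod[..., 2, :]
    dis[..., 1, :] += prod[..., 1, :] + prod[..., 3, :]

    # --- sorption equilibration -------------------------------------------
    total = dis + ads
    dis = total / (1.0 + ep.kd)
    ads = total - dis

    # --- DOC decomposition (dissolved phase only) --------------------------
    ddfrac = -np.expm1(-(dt_days / ep.kdoc_day)[:, None] * ft[..., None, :])
    ddec = dis * ddfrac
    dis = dis - ddec
    ddec_layer = ddec.sum(axis=-2)
    to_soc = ep.cue * ddec_layer
    soc[..., 3, :] += to_soc
    co2_doc_layer = ddec_layer - to_soc

    # --- vertical diffusion ------------------------------------------------
    diff_total = np.zeros(dis.shape[:-1] + (max(dis.shape[-1] - 1, 0),))
    if ep.d_coeff > 0.0 and dis.shape[-1] > 1:
        nsub = n_diff_sub if n_diff_sub is not None else diffusion_substeps(ep, dt)
        dt_sub = dt / nsub
        # layers drier than 1e-9 kg m-2 carry no meaningful solution:
        # treat them as gradient-free instead of overflowing the divide
        wsafe = np.where(water > 1e-9, water, np.inf)[..., None, :]
        for _ in range(nsub):
            conc = 1000.0 * dis / wsafe  # mg C L-1 == g C m-3
            flux = ep.d_coeff * (conc[..., :-1] - conc[..., 1:]) / ep.dz_mid * dt_sub
            # donor-limited: a layer drains through at most two interfaces,
            # so capping each at half the donor stock preserves positivity
            np.minimum(flux, 0.5 * dis[..., :-1], out=flux)
            np.maximum(flux, -0.5 * dis[..., 1:], out=flux)
            dis[..., :-1] -= flux
            dis[..., 1:] += flux
            diff_total += flux

    # --- leaching ----------------------------------------------------------
    # Surface runoff exports at the concentration of the whole 0-35 cm zone,
    # sub-surface runoff + drainage at that of the rest of the column: the
    # leached fraction of each layer is the export-to-water ratio of its zone.
    smask = ep.surface_mask
    w_surf = water[..., smask].sum(axis=-1)
    w_deep = water[..., ~smask].sum(axis=-1)
    roff_deep = np.asarray(ssr) + np.asarray(dr)
    # flooring the denominator both avoids overflow on near-dry zones and
    # lands on the cap (leach the whole stock) whenever export >= water
    f_surf = np.minimum(sr / np.maximum(w_surf, 1e-9), 1.0)
    f_deep = np.minimum(roff_deep / np.maximum(w_deep, 1e-9), 1.0)
    lfrac = np.where(smask, f_surf[..., None], f_deep[..., None])
    leach = dis * lfrac[..., None, :]
    dis = dis - leach
    leach_layer = leach.sum(axis=-2)

    fluxes = {
        "production": prod,
        "dec_soc": dec,
        "co2_soc": co2_soc_layer.sum(axis=-1),
        "dec_doc": ddec,
        "co2_doc": co2_doc_layer.sum(axis=-1),
        "cue_return": to_soc.sum(axis=-1),
        "diffusion": diff_total,
        "leach": leach_layer,
        "leach_surface": np.where(ep.surface_mask, leach_layer, 0.0).sum(axis=-1),
        "leach_sub": np.where(ep.surface_mask, 0.0, leach_layer).sum(axis=-1),
        "litter": litter,
    }
    return soc, dis, ads, fluxes


def run_batch(soc, dis, ads, forcing_arrays: dict, ep: EngineParams, dt: float,
              conc_out: np.ndarray | None = None, residual_out: np.ndarray | None = None,
              surface_water_min: float = 1e-12):
    """Advance a (possibly batched) column through a whole forcing block.

    ``forcing_arrays`` maps the step() driver names to arrays with a
    leading time axis: ``t``/``s``/``water`` are (T, ..., L); ``sr``,
    ``ssr``, ``dr``, ``litter``, ``veg`` are (T, ...).  When ``conc_out``
    (T, ...) is given it receives the surface-soil (0–35 cm) dissolved DOC
    concentration after each step; ``residual_out`` (T, ...) receives the
    per-step carbon-closure defect relative to the step's throughput.
    Returns the final (soc, dis, ads) and a dict of cumulative fluxes.
    """
    n_steps = forcing_arrays["t"].shape[0]
    nsub = diffusion_substeps(ep, dt)
    smask = ep.surface_mask
    cum = {k: 0.0 for k in ("production", "co2_soc", "co2_doc", "cue_return",
                            "leach", "leach_surface", "litter")}
    fa = forcing_arrays
    for k in range(n_steps):
        if residual_out is not None:
            before = soc.sum(axis=(-2, -1)) + dis.sum(axis=(-2, -1)) + ads.sum(axis=(-2, -1))
        soc, dis, ads, fx = step(
            soc, dis, ads,
            fa["t"][k], fa["s"][k], fa["water"][k],
            fa["sr"][k], fa["ssr"][k], fa["dr"][k], fa["litter"][k], fa["veg"][k],
            ep, dt, n_diff_sub=nsub,
        )
        cum["production"] += fx["production"].sum(axis=(-2, -1))
        cum["co2_soc"] += fx["co2_soc"]
        cum["co2_doc"] += fx["co2_doc"]
        cum["cue_return"] += fx["cue_return"]
        cum["leach"] += fx["leach"].sum(axis=-1)
        cum["leach_surface"] += fx["leach_surface"]
        cum["litter"] += fx["litter"]
        if residual_out is not None:
            after = soc.sum(axis=(-2, -1)) + dis.sum(axis=(-2, -1)) + ads.sum(axis=(-2, -1))
            co2 = fx["co2_soc"] + fx["co2_doc"]
            leached = fx["leach"].sum(axis=-1)
            resid = (after - before) - (fx["litter"] - co2 - leached)
            throughput = fx["litter"] + co2 + leached + np.abs(after - before)
            residual_out[k] = np.abs(resid) / np.maximum(throughput, 1e-12)
        if conc_out is not None:
            w_surf = fa["water"][k][..., smask].sum(axis=-1)
            stock_surf = dis[..., smask].sum(axis=(-2, -1))
            conc_out[k] = 1000.0 * stock_surf / np.maximum(w_surf, surface_water_min)
    return soc, dis, ads, cum
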