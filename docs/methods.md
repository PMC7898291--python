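# Methods

`soildoc` simulates the production, turnover and leaching of dissolved
organic carbon (DOC) in a mineral-soil column, together with the tools
needed to calibrate the kinetics against sparse surface-soil DOC
concentration observations and to place the resulting fluxes in a
terrestrial carbon budget.  This note documents the model equations, the
numerical choices, the synthetic data the tests run on, and the known
limitations.

## The soil column

The column spans 3 m, discretised into four layers (0–10, 10–35, 35–100
and 100–300 cm).  The top two layers form the "surface soil" (0–35 cm):
surface-runoff leaching and the concentration compared against surface
observations are computed over this zone.

Solid-phase carbon follows the RothC pool structure: two litter pools
(DPM, decomposable and RPM, resistant plant material) and two soil pools
(BIO, microbial biomass and HUM, humus), with basal first-order rates
3.2·10⁻⁷, 9.6·10⁻⁹, 2.1·10⁻⁸ and 6.4·10⁻¹⁰ s⁻¹ respectively.  Litter
input is split DPM:RPM = 0.25:0.75 by default (configurable per biome)
and distributed over the layers with an exponential depth profile
`f_i ∝ exp(−z_top/z*) − exp(−z_bot/z*)`, e-folding depth `z*` per biome
(defaults 0.25–0.45 m; placeholders pending site profile data).
Decomposed carbon splits into respired CO₂ and a BIO/HUM return
(46:54) using the RothC clay rule `β = 1/(1+x)`,
`x = 1.67(1.85 + 1.60 e^{−0.0786·clay%})`.

All kinetic rates are scaled by dimensionless rate modifiers:

* temperature — Q10 response `F_T = Q10^{(T−T_ref)/10}` with Q10 = 2 and
  T_ref = 298.15 K;
* moisture — 0.2 at or below the wilting point, rising linearly to 1 at
  the optimum saturation fraction, clamped to [0.2, 1];
* vegetation — linear from 1 (bare soil) to 0.6 (full cover).

The product of the three drives SOC decomposition and DOC production;
DOC decomposition responds to temperature only.

## DOC processes

Two DOC classes are tracked, labile (fed by DPM and BIO) and
recalcitrant (fed by RPM and HUM), each with a dissolved and an inert,
immobile adsorbed phase.  Per step, in this order:

1. **Production** `F_p = S (1 − e^{−K_p · m · Δt})` per solid pool, with
   `K_p` a basal rate in day⁻¹ (calibration range 1–2) and `m` the
   combined modifier.  The produced mass moves from the solid pool to
   the matching dissolved class.  Production is a separate first-order
   extraction, not a carve-out of the RothC decomposition flux; with
   `K_p` of order 1 day⁻¹ it is the dominant fate of fresh litter
   carbon, so the simulated solid stocks are litter-supply-limited.
2. **Sorption** re-equilibrates each class instantaneously by a linear
   isotherm, `dissolved = total/(1+K_d)` with
   `log₁₀K_d = a₀ + a₁·pH + a₂·clay` (defaults 0, −0.1, 1.5 —
   placeholder coefficients; because the isotherm is linear and
   re-equilibrated every step, the calibration is insensitive to them).
3. **Decomposition** `F_D = S (1 − e^{−(Δt/K_DOC) F_T})` on the
   dissolved phase, with `K_DOC` a turnover *time* in days (the
   literature tabulates 500–4545 d).  A CUE fraction (default 0.5) of
   the decomposed mass returns to HUM; the rest is respired.
4. **Diffusion** of dissolved DOC between layer midpoints,
   `F = −D ∂C/∂z`, D = 1.06·10⁻⁹ m² s⁻¹, zero-flux boundaries,
   explicit with sub-stepping whenever `D·Δt/Δz² > 0.5` and
   donor-limited flux caps (each interface moves at most half the donor
   layer's stock per sub-step) so stocks can never go negative.
5. **Leaching**: surface runoff exports at the concentration of the
   0–35 cm zone, sub-surface runoff plus drainage at that of the
   35–300 cm zone; each layer loses the fraction
   `min(Roff/TS_zone, 1)` of its dissolved stock, taken proportionally
   from both classes.  Using the zone water (rather than applying the
   full surface runoff to each of layers 1–2 independently) makes the
   surface export exactly `Roff · C(0–35 cm)` and avoids counting the
   same export water twice.

Concentrations are diagnosed as `1000 · stock / water` (g C m⁻² over
kg H₂O m⁻², i.e. mg C L⁻¹).

Every operation conserves carbon by construction; the stepper records a
closure residual `Δ(SOC+DOC) − (litter − CO₂ − leached)` per step, and
`mass_balance_report` re-derives it independently from the stored stock
and flux series.

## Time stepping and spin-up

The native step is 30 min; the engine accepts any step (spin-up and
calibration use daily steps — the kinetics are step-size-safe because
every transfer uses the exact `1 − e^{−kΔt}` form).

Spin-up repeats a one-year climatology until the relative change of
every pool total over one cycle falls below a tolerance (default 10⁻⁴,
configurable).  The accelerated mode multiplies each slow pool's
first-order turnover by `f_n = round(k_DPM/k_n)` — 1, 33, 15, 500 for
the default rates — equilibrates, multiplies the pool sizes by `f_n`,
and finishes with a short unscaled relaxation.  Because this package
treats DOC production as a separate extraction, the factor scales the
pool's *total* turnover (RothC rate and production rate together);
scaling only the RothC rate would not leave the rescaled equilibrium
invariant.  At the accelerated equilibrium the DOC influx already equals
its direct-spin-up value, so the relaxation phase is short.  On a
constant-forcing toy the accelerated and direct equilibria agree pool by
pool to well within 5% (tested).

## Diagnostics

Annual fluxes and mean stocks give three first-order constants:
`K_prod` = production/SOC, `K_dec` = decomposition/DOC and `K_leach` =
leaching/DOC (yr⁻¹), the residence time `τ_DOC = 1/(K_dec + K_leach)`,
and the near-steady-state closure `DOC ≈ SOC · K_prod/(K_dec+K_leach)`
(verified to <1% against the simulated equilibrium).  Budget tables
assemble per-region production / CO₂ / SOC-return / leached partitions
with the identities NEP = NPP − Rh, NEE = −NEP, NBP = NEE − E_LUC and
the export ratios DOC_LCE/NPP and DOC_LCE/NEP.  NPP and E_LUC are
supplied numbers (the package does not simulate vegetation); Rh is
assembled from the simulated SOC- and DOC-derived CO₂.  The global row
is the exact sum of regions; ratio columns are recomputed from the
summed components rather than rounded entries.  Decadal series are
smoothed with a centred 10-year running mean, truncated at the ends.

## Calibration

Per biome, 25 (K_p, K_DOC) pairs are drawn by Latin-hypercube sampling
inside the literature bounds; each pair is scored by the RMSE between
observed and simulated surface-soil concentrations, by default the mean
over sites of per-site RMSE (a pooled-measurement switch exists).  The
sampled K_DOC drives the recalcitrant class only; the labile turnover
stays at its 600 d default, to which soil concentrations are
insensitive.  K-fold cross-validation (default k = 5) over sites is
reported per pair; the final selection uses all sites, with ties broken
towards smaller K_p, then smaller K_DOC.  Observations pair with
simulation output by calendar day of a representative annual cycle, so
dated and climatological records are treated alike.  Sites sharing a
grid-cell id can be averaged beforehand.

Each candidate evaluation spins all sites up in one batch (daily steps,
drift tolerance 10⁻³) and, for speed, candidate pairs are swept in
K_DOC order with the previous pair's equilibrium as the warm start —
the spin-up still runs to the same tolerance, so the result is
independent of the sweep order up to that tolerance.

## Synthetic data

The generator emulates the statistical shape of the drivers, not any
particular site: a seasonal soil-temperature sinusoid damped and
phase-lagged with depth plus AR(1) weather noise; AR(1) soil moisture,
smoother at depth; Poisson-arrival, gamma-sized precipitation events
split into surface runoff / sub-surface runoff / drainage (8–15%
overland flow — overland flow is a minor pathway under intact
vegetation); and a seasonal litterfall cycle normalised to an exact
annual total.  Four shipped biome scenarios (boreal, temperate,
tropical, grassland) set means a field scientist would recognise
(e.g. boreal 276 K / 250 g C m⁻² yr⁻¹ litter; tropical 299 K /
900 g C m⁻² yr⁻¹).  Site ensembles perturb litter, temperature and
runoff per site.  Observation sets are produced by running the
simulator with known truth parameters and applying multiplicative
lognormal noise `exp(N(0, σ²))`, σ = 0.2 by default.

What passing tests on these data do show: conservation, determinism,
the analytic steady state, spin-up equivalence, the transport-to-
substrate transition of leaching, the warm/cold residence-time
contrast, and that the calibration machinery recovers a known K_DOC
where the data constrain it.  What they do not show: skill against real
soils — the generator has no topography, no riparian or saturated-zone
dynamics, no pH/nutrient controls, no moisture–runoff coupling, and its
noise is uncorrelated across sites and dates, all unlike field data.

Parameter recovery is assessed on a warm grassland ensemble
(292 K mean soil temperature): K_DOC controls decomposition, which
competes with leaching only at warm sites, so recovery is measured
where the parameter is expressed.  At cold sites the posterior over
K_DOC is nearly flat — a property of the model structure, not a test
artefact.

## Numerical details and conventions

* All transfers use `1 − e^{−x}` forms, so fluxes are bounded by their
  source stocks for any step size and the small-step limit is first
  order.
* Zero-water layers produce zero concentration and zero leaching inside
  the engine; the public diagnostic functions raise on degenerate water
  states instead of guessing.
* Spin-up starts from empty pools (SOC accumulates from litter; DOC
  from production).
* Determinism: identical states, forcing, parameters and seeds give
  bit-identical results; all randomness flows through explicit
  `numpy.random.Generator` seeds.
* Problem sizes in the shipped tests — one-year columns, 20-site
  calibration ensembles, 10-seed recovery experiments — were chosen as
  the smallest sizes at which each property is cleanly expressed.

## Known limitations

* No peatland/organic-soil representation; mineral soils only.
* Temperature, moisture and the water export fluxes are prescribed
  forcings; there is no soil thermal or hydraulic solver and no
  feedback from carbon state to hydrology.
* Solid-phase carbon is not transported between layers; only its
  diagnostic depth distribution and the dissolved phase are vertical.
* The sorption isotherm coefficients and per-biome e-folding depths are
  placeholders pending site data.
* With the day⁻¹ reading of K_p, solid stocks are litter-limited and
  turn over much faster than field SOC inventories; all process
  structure, budgets and diagnostics are unaffected, but absolute SOC
  magnitudes should not be compared against soil-carbon maps.
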