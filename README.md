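# soildoc

A four-layer soil-column simulator of dissolved organic carbon (DOC)
production, turnover and leaching in mineral soils, with per-biome
calibration against surface-soil DOC concentrations and carbon-budget
diagnostics.

Leaching of DOC from soils into the river network is a small but
systematically ignored term of the terrestrial carbon balance: carbon
that ecosystem bookkeeping counts as stored on land has in fact left
through the drainage network.  Quantifying that term requires a process
model of how DOC is produced from decomposing litter and soil organic
matter, how fast it is consumed again, and how much escapes with runoff
and drainage — calibrated against the sparse surface-soil concentration
measurements that exist.  `soildoc` packages exactly that model chain
for single soil columns, so the process equations can be exercised,
calibrated and audited without a full land-surface model around them.
It is aimed at biogeochemical modellers who want a transparent,
testable implementation of the soil-DOC process stack.

## Model

Solid carbon follows the RothC pool structure (DPM, RPM, BIO, HUM with
basal rates 3.2·10⁻⁷, 9.6·10⁻⁹, 2.1·10⁻⁸, 6.4·10⁻¹⁰ s⁻¹), distributed
over four layers (0–10, 10–35, 35–100, 100–300 cm) by an exponential
depth profile.  Two DOC classes (labile ← DPM+BIO, recalcitrant ←
RPM+HUM), each with a dissolved and an inert adsorbed phase, evolve by

* production  F_p = S·(1 − e^(−K_p·m·Δt)),  K_p in day⁻¹, m the
  temperature × moisture × vegetation rate modifier,
* decomposition  F_D = S·(1 − e^(−(Δt/K_DOC)·F_T)),  K_DOC a turnover
  time in days, with a CUE share (default 0.5) returned to humus,
* linear-isotherm sorption, Fickian vertical diffusion, and advective
  leaching  F = S·min(Roff/TS, 1)  (surface runoff drains the 0–35 cm
  zone, sub-surface runoff + drainage the rest).

On top sit accelerated spin-up (slow-pool turnover scaled by
round(k_DPM/k_n) = 33/15/500, then rescaled), Latin-hypercube
calibration of (K_p, K_DOC) with K-fold cross-validation, and
diagnostics: K_prod, K_dec, K_leach, τ_DOC = 1/(K_dec+K_leach),
steady-state DOC = SOC·K_prod/(K_dec+K_leach), and NEP/NEE/NBP budget
tables with DOC export ratios.  See `docs/methods.md` for the full
account.

## Worked example

`examples/01_single_column_run.py` spins a temperate column up on a
synthetic one-year climatology, runs a recorded year and prints:

```
annual DOC production :    545.4 g C m-2
  respired as CO2     :    115.4 g C m-2
  returned to SOC     :    115.4 g C m-2
  leached to waters   :    314.6 g C m-2
mean surface DOC conc :   4651.4 mg C L-1
closure residual      : 4.68e-15 of litter input
```

Production splits between respiration, return to the soil matrix and
leaching; the closure line is the carbon-budget defect relative to the
litter input — machine precision, because every process transfers mass
exactly.  The other examples cover accelerated spin-up
(`02`, printing the 33/15/500 factors and matching equilibria),
calibration recovery on noisy synthetic observations (`03`), turnover
diagnostics and budget tables (`04`), and forcing file round-trips
(`05`).  A thin CLI mirrors these flows:
`soildoc synth|spinup|run|calibrate|diagnose --seed 1 --out DIR`.

## Layout

```
src/soildoc/      library (soil_carbon, doc_dynamics, column, calibration,
                  diagnostics, synthetic, forcing, io, params, cli)
examples/         one narrative script per capability
tests/            pytest suite (unit, property and end-to-end checks)
scripts/          acceptance.py
docs/methods.md   model description, numerical choices, limitations
```
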