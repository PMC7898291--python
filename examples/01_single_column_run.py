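"""Run one temperate soil column for a year and audit its carbon budget.

Builds a synthetic one-year forcing, spins the column up to
quasi-equilibrium on that climatology, runs a final recorded year and
prints the annual DOC budget with the mass-balance closure.
"""

import soildoc as sd
from soildoc import column, synthetic

params = sd.default_params("temperate")
scenario = synthetic.default_scenario("temperate", years=1, seed=1)
forcing = synthetic.generate_forcing(scenario)

state = column.accelerated_spinup(
    column.SoilColumnState.zeros(), forcing, params,
    column.SpinupConfig(mode="accelerated", tol=1e-4, max_cycles=2000))
result = column.run_simulation(state, forcing, params)

totals = result.fluxes.totals()
report = column.mass_balance_report(result.fluxes, result.states)
conc = result.states.conc_surface.mean()

print(f"annual DOC production : {totals['production']:8.1f} g C m-2")
print(f"  respired as CO2     : {totals['co2_doc']:8.1f} g C m-2")
print(f"  returned to SOC     : {totals['cue_return']:8.1f} g C m-2")
print(f"  leached to waters   : {totals['leached']:8.1f} g C m-2")
print(f"mean surface DOC conc : {conc:8.1f} mg C L-1")
print(f"closure residual      : {report.cumulative_relative:.2e} of litter input")
print()
print("Production splits between respiration, return to the soil matrix and")
print("leaching; the closure line confirms the budget is conservative.")
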