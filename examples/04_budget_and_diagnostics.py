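"""Turnover diagnostics and a regional carbon-budget table.

Runs the boreal and tropical default scenarios to equilibrium, derives
K_prod / K_dec / K_leach and the DOC residence time, and assembles the
two columns into a budget table with NEP bookkeeping and export ratios.
"""

import soildoc as sd
from soildoc import column, diagnostics, synthetic

regions = {}
for biome in ("boreal", "tropical"):
    params = sd.optimized_params(biome)
    scenario = synthetic.default_scenario(biome, years=1, seed=1)
    cycle = synthetic.generate_forcing(scenario)
    state = column.accelerated_spinup(
        column.SoilColumnState.zeros(), cycle, params,
        column.SpinupConfig(mode="accelerated", tol=1e-4, max_cycles=5000))
    res = column.run_simulation(state, cycle, params)
    totals = res.fluxes.totals()
    soc = float(res.states.soc_pools[1:].sum(axis=1).mean())
    doc = float(res.states.doc_total[1:].mean())
    diag = diagnostics.turnover_rates(
        totals["production"], totals["co2_doc"] + totals["cue_return"],
        totals["leached"], soc, doc)
    print(f"{biome:9s}: K_dec {diag.k_dec:6.3f} yr-1, K_leach {diag.k_leach:6.3f} yr-1, "
          f"tau_DOC {diag.tau_doc_days:7.1f} days")
    regions[biome] = {
        "production": totals["production"],
        "doc_co2": totals["co2_doc"],
        "soc_return": totals["cue_return"],
        "leached": totals["leached"],
        "delta_doc_stock": float(res.states.doc_total[-1] - res.states.doc_total[0]),
        "doc_stock": doc,
        "npp": scenario.npp_annual,
        "soc_co2": totals["co2_soc"],
    }

budget = diagnostics.budget_summary(regions, closure_tol=1e-3)
cols = ["production", "leached", "leached_share_pct", "nep", "doc_lce_nep_pct"]
print()
print(budget.table[cols].round(2).to_string())
print()
print("Warm tropical columns turn their DOC over several times faster than")
print("cold boreal ones.  The last column is the share of the net ecosystem")
print("productivity exported as leached DOC.")
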