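"""Recover known DOC kinetics from noisy synthetic observations.

Generates a warm-grassland site ensemble, simulates 'observations' with a
known truth pair (K_p, K_DOC), perturbs them with 20% lognormal noise and
runs the 25-pair Latin-hypercube calibration with 5-fold cross-validation.
"""

import soildoc as sd
from soildoc import calibration, synthetic

truth = sd.default_params("grass").replace(kp=1.4, kdoc_recalcitrant=750.0)
scenario = synthetic.default_scenario(
    "grass", t_mean=292.0, years=1, seed=0, n_sites=20, n_dates=12, obs_sigma=0.2)

forcings = synthetic.site_forcings(scenario)
observations = synthetic.generate_observations(truth, forcings, scenario)
result = calibration.calibrate_biome(observations, forcings, seed=0)

print(result.summary())
print(f"truth pair            K_p = 1.4 day^-1, K_DOC = 750 days")
print()
print("The selected K_DOC should sit near the truth; K_p is weakly")
print("identified because production is litter-supply-limited.")
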