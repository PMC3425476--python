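"""Recover the 13 hidden parameters from synthetic target files.

Forward-simulates with the reference parameters, emits noise-free targets
(organ dimensions and biomasses of the oldest tree plus compartment totals
of the younger ages), then re-estimates the parameters by grouped 2-stage
GLS starting from a deliberately wrong initial guess.
"""

import numpy as np

from pinewater import PlantParams
from pinewater.calibration import (
    HIDDEN_PARAM_NAMES,
    CalibrationConfig,
    fit_gls,
    params_to_theta,
)
from pinewater.synthetic import NoiseSpec, synth_targets, synth_weather_years

config = CalibrationConfig(weather_years=synth_weather_years(seed=1))
theta_star = params_to_theta(PlantParams())
targets = synth_targets(theta_star, config, NoiseSpec(sigma=0.0))
print(f"{len(targets)} target records in {len(set(targets.groups))} observable groups")

init = theta_star * np.array(
    [1.4, 0.7, 1.3, 0.8, 1.5, 1.3, 0.7, 1.4, 0.8, 1.5, 1.3, 0.7, 1.4]
)
fit = fit_gls(targets, config, init=init)
print(f"converged: {fit.converged} after {fit.n_stage_iter} stage iterations\n")
print(f"{'parameter':12s} {'true':>10s} {'estimate':>10s} {'rel err %':>10s}")
for name, true, est in zip(HIDDEN_PARAM_NAMES, theta_star, fit.theta_vector):
    print(f"{name:12s} {true:10.4g} {est:10.4g} {100*abs(est-true)/true:10.4f}")
print()
print("noise-free targets pin every parameter; the per-group variance")
print("weighting matters once observables of different scales carry noise.")
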