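"""Simulate a validation study and recover its parameters by maximum likelihood.

Generates a two-visit cohort of 20000 individuals from known parameters,
residualizes (here: demeans), fits the structured-covariance model with the
generating sensitivity values held fixed, and compares estimates with the
truth using delta-method standard errors.
"""

import numpy as np

import dietme as dm
from dietme.estimation import FitOptions, ParamPacker

params = dm.fruit_veg_scenario_params().copy(
    alpha_Q=np.zeros(2), alpha_R=np.zeros(2), alpha_M=np.zeros(2))
sens = dm.SensitivitySetting(beta_R=0.75, rho_MM=0.4)

data, truth = dm.gen_dataset(dm.SimulationSpec(n=20000, params=params, sens=sens, seed=42))
rdata = dm.residualize(data)
fit = dm.fit_ml(rdata, sens)
ses = dm.standard_errors(fit, rdata, method="delta")

packer = ParamPacker(2, FitOptions())
true_vals = packer.natural(packer.pack(params))
print(f"converged: {fit.converged}   log likelihood: {fit.loglik:.2f}\n")
print(f"{'parameter':14s} {'truth':>9s} {'estimate':>9s} {'SE':>8s} {'z':>6s}")
for name, tv, est, se in zip(ses.param_names, true_vals, ses.param_values, ses.param_se):
    print(f"{name:14s} {tv:9.4f} {est:9.4f} {se:8.4f} {(est - tv) / se:6.2f}")

print("\nEvery |z| should be small: estimates agree with the generating values "
      "within sampling uncertainty at n = 20000.")
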