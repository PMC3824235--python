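"""Closed-form moment structure, regression dilution ratios and correlations.

Builds the implied covariance of the six measurements (FFQ, food record and
biomarker at two visits) for a realistic parameter set, then prints the
derived RDRs and correlations with true intake.  The RDR is the factor by
which measurement error shrinks (or inflates) a linear diet-disease
coefficient: regression calibration divides the observed coefficient by it.
"""

import numpy as np

import dietme as dm

params = dm.fruit_veg_scenario_params()
sens = dm.SensitivitySetting(beta_R=1.0, rho_MM=0.0)  # conventional assumptions

moments = dm.build_implied_moments(params, sens)
print("slot order:", moments.order)
print("implied covariance (conditional on covariates):")
print(np.array_str(moments.cov, precision=3, suppress_small=True))

print("\nderived quantities at (beta_R=1, rho_MM=0):")
for x, label in (("Q", "FFQ"), ("R", "food record")):
    lam_lt = dm.rdr(params, sens, x, 0, "longterm")
    lam_ts = dm.rdr(params, sens, x, 0, "timespecific")
    rho = dm.corr_with_true(params, sens, x, 0, "timespecific")
    print(f"  {label:12s} visit 1: RDR (long-term) = {lam_lt:.3f}, "
          f"RDR (time-specific) = {lam_ts:.3f}, corr with T_i1 = {rho:.3f}")
rho_m = dm.corr_with_true(params, sens, "M", 0, "timespecific")
print(f"  {'biomarker':12s} visit 1: corr with T_i1 = {rho_m:.3f}")

print("\nAn RDR of ~0.15 means an observed log odds ratio understates the true "
      "association by a factor ~6.5; the correlations govern study power.")
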