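"""One-sample MR on a simulated cohort: observational vs instrumented slope.

Generates a cohort at the calibrated defaults — n = 3701, a single SNP
explaining ~5.3% of log-exposure variance, and confounding that pushes the
observational (OLS) slope to about +1 mm Hg per SD of log-exposure even
though the true causal effect is zero — then contrasts OLS with 2SLS and
runs the Durbin-Wu-Hausman endogeneity test.
"""

import mrpipe as mp

cohort = mp.simulate_cohort(mp.CohortConfig(seed=1))
z = mp.standardize_log_exposure(cohort["exposure"])

ols = mp.ols_fit(cohort["sbp"], z)
tsls, first_stage = mp.tsls_fit(cohort["sbp"], z, cohort["genotype"])
dwh = mp.dwh_test(cohort["sbp"], z, cohort["genotype"])

print(f"n = {len(cohort)}; first stage F = {first_stage.f_statistic:.0f}, "
      f"R2 = {100 * first_stage.r2:.1f}%")
print(f"OLS : {ols.beta:+.2f} mm Hg/SD (95% CI {ols.ci_low:+.2f}, {ols.ci_high:+.2f})")
print(f"2SLS: {tsls.beta:+.2f} mm Hg/SD (95% CI {tsls.ci_low:+.2f}, {tsls.ci_high:+.2f})")
print(f"DWH : statistic = {dwh.statistic:.2f}, p = {dwh.p_value:.2f}")
print()
print("The OLS slope is confounded upward; the 2SLS (instrumented) slope is")
print("consistent for the true causal effect, here zero. A wide 2SLS CI is")
print("the price of instrumenting: only ~5% of exposure variance is usable.")
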