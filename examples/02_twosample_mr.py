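"""Two-sample MR on a simulated 18-SNP summary panel with pleiotropy.

The panel is generated with a true causal effect of 0.5 mm Hg per SD of
log-exposure plus directional horizontal pleiotropy (every SNP adds on
average +0.1 mm Hg directly to the outcome). IVW, which assumes no
pleiotropy, is biased; MR-Egger separates the pleiotropy (intercept) from
the causal slope.
"""

import mrpipe as mp

panel = mp.simulate_two_sample_summary(
    mp.TwoSampleConfig(causal_beta=0.5, pleiotropy_mean=0.1, pleiotropy_sd=0.05, seed=24)
)
panel = mp.harmonize(panel)  # orient every SNP to its exposure-increasing allele

ivw = mp.ivw_multi(panel)
egger = mp.egger_regression(panel, n_boot=10_000, seed=24)
meta = mp.fixed_effects_meta(panel["beta_out"], panel["se_out"])

print(f"k = {ivw.n_snps} SNPs; outcome-association heterogeneity I2 = {meta.i2:.0f}%")
print(f"IVW slope      : {ivw.beta:+.2f} (95% CI {ivw.ci_low:+.2f}, {ivw.ci_high:+.2f})")
print(f"Egger slope    : {egger.slope:+.2f} (95% CI {egger.slope_ci[0]:+.2f}, {egger.slope_ci[1]:+.2f})")
print(f"Egger intercept: {egger.intercept:+.3f} (95% CI {egger.intercept_ci[0]:+.3f}, "
      f"{egger.intercept_ci[1]:+.3f}) mm Hg/allele")
print()
print("True values: slope 0.5, intercept 0.1. IVW absorbs the directional")
print("pleiotropy into its slope; the Egger intercept isolates it and the")
print("Egger slope stays near the causal effect (at the cost of a wider CI).")
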