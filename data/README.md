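# data

Drop-in location for real summary-statistic panels.

`tests/test_acceptance.py::test_published_summary_panel_reproduction` looks
here for `published_18snp_panel.tsv`: the published panel of 18
homocysteine-associated SNPs crossed with consortium blood-pressure
associations, in the standard dialect

    snp  effect_allele  other_allele  beta_exp  se_exp  beta_out  se_out

(`beta_exp` in SD units of log homocysteine per effect allele, `beta_out`
in mm Hg per effect allele). That per-SNP table is not redistributable
with this repository, so the file is absent and the reproduction check
reports failure until a user supplies it. All other tests generate their
inputs programmatically.
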