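"""Two-stage association of a genomic region with longitudinal blood pressure.

Summarizes the causal region by its empirical-Bayes genetic load and rare
burden, fits the kinship-structured longitudinal mixed model, and reports
the 2-df Wald test of the region effect together with the Bonferroni level
one would use for a scan that produced several regions.
"""

import numpy as np

import ibdassoc as ia
from ibdassoc.association import (bonferroni_alpha, eb_summarize, fit_lmm,
                                  rare_count, wald_2df)

cfg = ia.SimConfig(n_families=20, effect_beta2=4.0, effect_beta3=3.0, seed=5)
ds = ia.simulate_dataset(cfg)

lo, hi = cfg.causal_region
idx = np.flatnonzero((ds.panel["cm"] >= lo) & (ds.panel["cm"] <= hi))
ebs = eb_summarize(ds.genotypes, idx, ds.ids, region_id="causal")
burden = rare_count(ds.genotypes, idx, ds.ids, rare_maf_max=0.05)

print(f"stage 1: {len(idx)} markers, stage-1 variances "
      f"sigma2_b={ebs.sigma2_b:.3f} sigma2_e={ebs.sigma2_e:.3f}; "
      f"{burden.n_rare_markers} rare markers, "
      f"{int((burden.s > 0).sum())} burden carriers")

R = ia.relationship_matrix(ds.pedigree, ds.ids)
fit = fit_lmm(ds.phenotypes, R, eb=ebs.eb, s=burden.s)

b2, b3 = fit.beta["eb"], fit.beta["s"]
cov = fit.cov_beta.loc[["eb", "s"], ["eb", "s"]].to_numpy()
W, p = wald_2df(np.array([b2, b3]), cov)

print(f"stage 2: beta2 (EB load) = {b2:.2f}, beta3 (rare burden) = {b3:.2f}, "
      f"sigma_u2 = {fit.sigma_u2:.2f}")
print(f"2-df Wald: W = {W:.2f}, p = {p:.2e}")
exact, shown = bonferroni_alpha(0.05, 7)
print(f"Bonferroni level for a 7-region scan: {exact:.5f} (reported {shown:g})")
print("\nA joint p below the Bonferroni level declares the region associated "
      "with diastolic blood pressure after accounting for family structure "
      "and repeated measurements.")
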