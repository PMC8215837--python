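"""Cross-trait LD score regression on simulated z-statistics.

Draws 5,000 variants' z-statistics for two traits with h2 = 0.4 each and
genetic covariance 0.2 (genetic correlation rg = 0.5), then regresses
chi-square and z1*z2 on the LD scores to recover heritabilities, genetic
covariance and rg with block-jackknife standard errors.
"""

import cardiomr as c

cfg = c.LDSCSimConfig(m=5000, h2_1=0.4, h2_2=0.4, gencov=0.2,
                      n1=50_000, n2=50_000, seed=11)
ld = cfg.make_ld_scores()
z1, z2 = c.simulate_ldsc_z(cfg, ld)

res = c.cross_trait_ldsc(z1, z2, ld, n1=50_000, n2=50_000)
print(f"h2 trait 1 = {res.h2_trait1:.3f} +/- {res.h2_trait1_se:.3f}  (truth 0.4)")
print(f"h2 trait 2 = {res.h2_trait2:.3f} +/- {res.h2_trait2_se:.3f}  (truth 0.4)")
print(f"genetic covariance = {res.gencov:.3f} +/- {res.gencov_se:.3f}  (truth 0.2)")
print(f"genetic correlation rg = {res.rg:.3f} +/- {res.rg_se:.3f}  (truth 0.5)")
print(f"bivariate intercept = {res.intercept_biv:.3f}  (0 expected: no sample overlap)")
print("\nrg close to 0.5 with a small jackknife SE shows the product-of-z"
      "\nregression separates polygenic sharing from confounding inflation.")
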