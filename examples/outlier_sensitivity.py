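"""Outlier-robust sensitivity analysis with a planted pleiotropic variant.

Builds a 20-instrument dataset where 19 variants obey the true ratio 0.3
and one follows ratio 3.0 (a strongly pleiotropic instrument), then runs
the residual-sum-of-squares outlier scan and the contamination-mixture
estimator, and refits after excluding the flagged variants.
"""

import numpy as np

import cardiomr as c
from cardiomr.robust import conmix, presso, refit_after_exclusion
from cardiomr.sumstats import HarmonizedSet

rng = np.random.default_rng(42)
J, theta = 20, 0.3
maf = rng.uniform(0.05, 0.5, J)
se = 1 / np.sqrt(2 * 100_000 * maf * (1 - maf))
bx_true = rng.uniform(5.5, 30, J) * se * rng.choice([-1.0, 1.0], J)
by = theta * bx_true + rng.normal(0, se)
by[0] = 3.0 * bx_true[0] + rng.normal(0, se[0] / 3)   # the planted outlier
h = HarmonizedSet(["X"], "Y", [f"rs{j+1}" for j in range(J)],
                  (bx_true + rng.normal(0, se))[:, None], se[:, None], by, se)

report = presso(h, n_sim=1000, seed=7)
print(f"global RSS test p = {report.global_pvalue:.4f}  "
      f"(small p: the instrument set is contaminated)")
print(f"flagged variants: {report.flagged_ids}")
print("(the planted rs1 is flagged; a strong outlier also contaminates the"
      " leave-one-out fits of other variants, so collateral flags appear)")

r = c.wald_ratios(h)
cm = conmix(r, grid_points=2001)
print(f"contamination mixture: theta = {cm.theta:+.3f} "
      f"[{cm.ci_low:+.3f}, {cm.ci_high:+.3f}], "
      f"{len(cm.valid_ids)}/{J} variants assigned valid")

before = c.ivw(r)
after = refit_after_exclusion(h, excluded=["rs1"], seed=1)["estimates"][0]
print(f"IVW with outlier:    {before.theta:+.3f} (Q = {before.heterogeneity_Q:.1f})")
print(f"IVW after exclusion: {after.theta:+.3f} (Q = {after.heterogeneity_Q:.1f})")
print("\nExcluding the planted variant moves IVW back toward the true 0.3 and"
      "\ncollapses the heterogeneity statistic.")
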