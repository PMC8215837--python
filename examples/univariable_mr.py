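"""Univariable two-sample MR on synthetic GWAS summary statistics.

Simulates 100 genome-wide-significant instruments for an exposure with a
true causal effect of 0.15 on the outcome (n = 100,000 per sample, no
pleiotropy), harmonizes the two tables (palindromic variants and
instruments with a genome-wide-significant direct outcome association
are excluded), and runs the estimator battery.  Every method's estimate
should sit near 0.15.
"""

import cardiomr as c

truth = c.make_truth(theta=0.15, J=100, n=100_000, seed=7, palindromic_fraction=0.2)
(exposure,), outcome, (instruments,) = c.simulate_two_sample(truth)

h = c.harmonize(exposure, outcome, instruments)
print(f"retained {h.n_variants} of {len(instruments)} instruments; "
      f"dropped: {sorted(set(r for _, r in h.dropped))}")

for est in c.estimator_battery(h, seed=1):
    print(f"{est.method:>16}  theta={est.theta:+.3f}  se={est.se:.3f}  "
          f"95% CI [{est.ci_low:+.3f}, {est.ci_high:+.3f}]  p={est.pvalue:.2e}")

print("\nEach row is one causal-effect estimate (true value 0.15); the methods"
      "\ndiffer in how they guard against pleiotropic instruments.")
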