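# Methods

This note records the statistical model behind each stage of `cardiomr`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that matter for
reproducing results.

## Two-sample MR model and assumptions

All estimators work on summary statistics from two non-overlapping
samples. The identifying assumptions are the usual instrumental-variable
triplet — relevance (instruments associate with the exposure),
independence (no confounder of instrument and outcome) and exclusion
(no path to the outcome other than through the exposure) — with each
robust method relaxing exclusion in its own way: Egger allows
directional pleiotropy if it is independent of instrument strength
(InSIDE), the weighted median allows up to half the weight to sit on
invalid instruments, the mode-based estimate requires only that the
largest cluster of ratio estimates be the valid one (ZEMPA), and the
contamination mixture models invalid variants explicitly as a
zero-centred wide component.

## Harmonization

Records are aligned per variant to the orientation of the instrument's
home exposure. Matching precedence is exact → swapped → strand
complement → swapped complement; anything else is an irreconcilable
pair. Palindromic (A/T, C/G) variants are excluded unconditionally — no
allele-frequency rescue — because strand cannot be resolved from
alleles alone. Instruments whose outcome association is itself
genome-wide significant (p < 5×10⁻⁸, configurable) are excluded as
having a potential direct effect on the outcome. Missing p-values are
recomputed as two-sided normal tails of β/SE, which the direct-effect
filter needs. Missing variants are dropped and logged, not proxied.

Note one interaction relevant to simulation studies: when the true
causal effect is strong and instruments are strong, an instrument's
outcome association can reach genome-wide significance *through the
causal path*, so the direct-effect filter then selects on outcome noise
and biases estimates downward. Pipeline runs keep the filter (it is part
of the design being emulated); estimator-calibration tests disable it,
because the property under test is the estimator on valid instruments,
not the filter.

## Instrument selection

Greedy clumping: candidates with p below the instrument threshold
(default 5×10⁻⁸) are visited by ascending p-value; each retained index
variant removes remaining same-chromosome variants within the window
(default ±1 Mb, centered; a one-sided variant is available because the
convention is ambiguous) whose r² with it is ≥ 0.2. Ties in p-value
break by (chrom, pos), then variant id, making the output invariant to
input row order. Variants missing from the LD reference are treated as
unlinked with a warning. Per-variant instrument strength is reported as
the squared z-statistic, the large-sample F of the one-SNP regression.

## Estimator details

- **Ratio SEs.** First-order σⱼ = σ_Yj/|β̂_Xj| is the default;
  the second-order form adds the delta-method term
  β̂²_Yj σ²_Xj/β̂⁴_Xj. Calibration simulations in this package use the
  second-order form since with equal sample sizes the first-order form
  understates the ratio variance by a factor ≈ (1+θ²).
- **IVW.** Fixed-effect by default (no residual scaling); the
  multiplicative random-effects option never deflates the SE below the
  fixed-effect value.
- **Egger.** Weighted least squares via statsmodels; the reported SEs
  replace the estimated residual scale with max(1, RSE), so exact data
  yield the fixed-effect SE rather than a spuriously tiny one.
- **Weighted median.** Standardized cumulative-weight percentiles
  pⱼ = 100(Sⱼ − wⱼ/2)/S_J, linear interpolation at 50. SE from a
  parametric bootstrap (θ*ⱼ ~ N(θ̂ⱼ, σⱼ)), default 1000 draws, seed
  mandatory and recorded in the output.
- **Mode.** Weighted normal-kernel density with bandwidth
  φ·0.9·min(sd, MAD/0.6745)·J^(−1/5); when one of sd/MAD is zero the
  smallest positive one is used, and a bandwidth below 10⁻¹⁰ of the
  data scale triggers the degenerate (point-mass) path. The density is
  evaluated on 512 grid points spanning [min θ − 3 max σ,
  max θ + 3 max σ]; argmax ties resolve to the smaller value. SE by the
  same parametric bootstrap.
- **Penalized weights.** wⱼ′ = wⱼ·min(1, 20qⱼ) with qⱼ the χ²₁ upper
  tail of Qⱼ = wⱼ(θ̂ⱼ − θ_ref)²; the constant 20 means only variants
  with qⱼ < 0.05 are downweighted. Weights are floored at 10⁻³⁰⁰ so
  extreme outliers keep finite σ.

## Outlier-robust procedures

The residual-sum-of-squares scan computes, per variant, the
leave-one-out IVW prediction and its squared residual; the null
distribution comes from parametric simulation (β*_X ~ N(β̂_X, σ_X),
β*_Y ~ N(θ̂₍₋ⱼ₎β̂_X, σ_Y)), with empirical p-values using the
(r+1)/(n+1) correction so they are never zero. Per-variant flags use a
Bonferroni-adjusted threshold α/J. The distortion test of the cited
family of methods is deliberately out of scope: only exclusion lists
feed the refits. Note that a very strong outlier contaminates the
leave-one-out estimates of *other* variants, so collateral flags around
a planted outlier are expected behavior of this class of procedure.

The contamination mixture profiles a θ grid: each variant contributes
the larger of its valid log-density N(θ̂ⱼ; θ, σⱼ²) and invalid
log-density N(θ̂ⱼ; 0, σⱼ² + ψ²); default ψ = 1.5·SD(θ̂ⱼ). The CI is the
set of grid points within 1.92 (χ²₁ 95%/2) of the profile maximum,
reported as its convex hull with a multimodality flag when disjoint.
**Grid resolution matters**: with strong instruments the CI can span
only a few points of the default 401-point grid and quantization then
shrinks it; precision-sensitive analyses (and this package's pipeline
and calibration tests) use 2001 points.

## Multivariable MR and mediation

The joint fit regresses β̂_Y on all K exposure columns, weighted
σ_Y⁻², no intercept (instrument orientation makes an intercept a
pleiotropy term). Both residualization variants are provided: outcome-
only residualization matches the descriptive "residuals as outcome"
recipe; residualizing the target column as well reproduces the joint
coefficient exactly (Frisch–Waugh–Lovell), and the two differ once
exposures are correlated.

Mediation uses the difference method: total effect C from univariable
IVW, direct effect C′ from the mediator-adjusted joint fit, indirect =
C − C′, percent mediated = 100·(C − C′)/C (undefined when |C| ≤ 10⁻¹²).
The label "mediation" requires both supporting paths at level α: the
A-path (exposure → mediator) is tested by univariable IVW, and the
B-path (mediator → outcome) by the mediator's *conditional* coefficient
in the joint fit — the conditional form is used because a naive
univariable B-path over all joint-set variants is contaminated by the
exposure's instruments whenever a direct exposure→outcome path exists.
Failing either path, the difference is reported as attenuation.

## Cross-trait LD score regression

LD scores use the bias-adjusted estimator ℓⱼ = Σ_k [r²ⱼk − (1 −
r²ⱼk)/(n_ref − 2)] over the window, with the self term fixed at exactly
1. Univariate fits regress χ² on ℓ with weights 1/max(ℓ, 1) (a
heteroscedasticity proxy; plain OLS available — the cited software's
full iterative weighting is out of scope), estimating the intercept in
a first step restricted to χ² < 30 and fixing it in the second;
h² = slope·m/n. The bivariate fit regresses z₁z₂ on ℓ with a freely
estimated intercept (sample overlap is not constrained);
genetic covariance = slope·m/√(n₁n₂) and r_g = cov/√(h²₁h²₂). All SEs
come from a delete-a-block jackknife over 200 contiguous blocks in
input order — a stand-in for genomic blocks that is exact for the
synthetic data, whose variants are exchangeable. r_g is reported
missing with a reason when either h² estimate is non-positive;
|r_g| > 1 only raises a flag. The two-step χ² < 30 cutoff is tuned to
real GWAS signal densities; the scaled-down simulations here (m = 5000)
put most variants above it, which inflates the *intercept* attribution
while leaving slopes — and therefore h² and r_g — accurate, as the
recovery tests verify.

## The synthetic generator

The generator emulates consortium-scale two-sample GWAS summary data:

- A K-trait acyclic causal matrix B (B[i,j] = direct effect of trait i
  on trait j, last trait the outcome); marginal variant effects follow
  all directed paths, Γ(I + B + B² + …).
- Per-variant standard errors 1/√(2·n·maf·(1−maf)) on a unit-variance
  trait scale, maf ~ Uniform(0.05, 0.5); observed β̂ = true β + N(0, se)
  with exposure and outcome noise independent (non-overlapping samples).
- Instrument effects drawn on the z-scale: |γ|/se ~ Uniform(5.5, 30),
  i.e. F between ≈30 and 900. This emulates selection at p < 5×10⁻⁸
  with the long upper tail of real consortium instruments; it also
  keeps regression-dilution negligible, which matters for Egger.
- Pleiotropy: a configurable fraction of variants receives a direct
  outcome effect N(mean, sd), applied per copy of the
  exposure-increasing allele — otherwise the arbitrary allele coding
  would cancel a directional mean and no method could detect it.
- A configurable fraction of variants receives palindromic alleles
  (default 0: instrument counts then equal what was requested; tests of
  the harmonization filter switch it on).
- Binary traits are treated on the log-odds scale without
  liability-scale conversion, matching how case-control betas enter MR.
- LDSC z-statistics are drawn jointly normal per variant with
  Var(zᵢ) = 1 + nᵢh²ᵢℓ/m and Cov = √(n₁n₂)·cov_g·ℓ/m (no overlap), ℓ
  from a uniform profile on [1, 200] by default.

What it does **not** emulate: LD between MR instruments (they are
post-clumping independent by construction; LD enters only the clumping
and LDSC fixtures), genome-realistic LD maps or allele-frequency
spectra, sample overlap between cohorts, winner's-curse bias in
instrument effects, and population stratification. Passing recovery
tests therefore show the estimators are correct under their stated
assumptions — not that real-data analyses are immune to these
additional complications.

## Problem sizes and determinism

Calibration and recovery runs use J = 100 instruments at n = 10⁵
(coverage, 500 replicates per effect size), J = 20 for the outlier scan
(200 null replicates at 1000 simulations each), J = 150 per trait for
mediation (50 replicates), and m = 5000 variants for LDSC — sizes at
which Monte-Carlo error is small relative to every tested margin while
the full suite stays interactive. Bootstrap SEs inside the coverage
loops use 200 draws (the MC error of a bootstrap SE at 200 draws is
≈5%, immaterial to a coverage check); standalone analyses default to
1000. Every stochastic routine takes an explicit seed, generators are
byte-reproducible given the seed, and per-replicate seeds are drawn
from an independent stream so different master seeds give independent
experiments.

## Known limitations

- The consistency verdict (≥2 nominal methods, agreeing direction) is
  a screening rule, not a calibrated test; with six correlated methods
  its null pass rate is ≈5–10%.
- The outlier scan's exclusion lists inherit the contamination problem
  described above; refits after exclusion are sensitivity analyses, not
  unbiased estimates.
- MVMR assumes the union of instruments is valid for the joint model;
  no per-covariate instrument re-selection is attempted.
- Egger remains vulnerable to violations of InSIDE and to weak spread
  in instrument strength (dilution); the generator's strong-instrument
  regime sidesteps the latter by design.
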