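# Methods

## The causal model

Two-sample Mendelian randomisation treats genetic variants as instrumental
variables for an exposure.  Variant j carries a per-allele effect β_Xj on the
exposure (here in exposure-SD units) estimated in one GWAS, and an effect
β_Yj on a binary outcome (log-odds) estimated in a second, non-overlapping
GWAS.  If the variant affects the outcome only through the exposure (no
horizontal pleiotropy), β_Yj = b·β_Xj, where b is the causal log-odds effect
of one SD of exposure.  Each variant therefore supplies a Wald ratio
θ̂ⱼ = β̂_Yj/β̂_Xj with first-order standard error σ_Yj/|β̂_Xj| (the exposure
uncertainty is ignored at first order; this is the standard choice when the
exposure GWAS is much larger than the outcome GWAS, as here: ~170 000 vs
11 744).

**IVW.** The inverse-variance-weighted estimate combines the ratios with
weights wⱼ = β̂_Xj²/σ_Yj², equivalently a zero-intercept weighted regression
of β̂_Y on β̂_X.  The fixed-effect SE is (Σwⱼ)^(−1/2).  The default
"multiplicative random effects" model inflates it by max(1, √(Q/df)) —
continuous with the fixed model, identical to it for homogeneous instruments,
and conservative otherwise.  IVW is consistent only when *all* instruments
are valid.

**Weighted median.** Ratios are ordered ascending; with normalised weights
the half-step cumulative weights sⱼ = Σ_{k≤j} w_k − wⱼ/2 define a piecewise-
linear quantile function, and the estimate interpolates it at 1/2.  It is
consistent when at least half the total weight comes from valid instruments,
hence its role as the pleiotropy-robust sensitivity analysis.  Its SE is a
parametric bootstrap: β̂_X and β̂_Y are resampled from normal distributions
at their reported SEs (default 10 000 replicates, seed mandatory).

**Heterogeneity.** Cochran's Q = Σⱼ(θ̂ⱼ − β̂)²/se(θ̂ⱼ)² is chi-square with
n−1 df under homogeneity; excess Q flags pleiotropy or harmonisation error.

Confidence intervals are normal-theory (±1.96·SE) on the log-odds scale and
exponentiated for odds-ratio reporting; the OR interval is therefore
asymmetric but order-preserving.

## Instrument construction

The pipeline applies, in order: (1) a significance filter (default
p < 8.31×10⁻⁹, strict inequality); (2) greedy LD clumping — variants visited
in ascending p (ties broken by rsid for order-invariance) and accepted iff
r² < 0.01 with every prior acceptance; the method is not named in most GWAS
reports, and greedy-by-significance is the community standard and
deterministic; (3) harmonisation of each exposure variant against the
outcome GWAS.

Harmonisation resolves, in this order: palindromic (A/T, C/G) variants with
minor-allele frequency above 0.45 are dropped — near 50% frequency the
strand cannot be inferred, and allele letters carry no information for
palindromes; variants absent from the outcome panel are replaced by their
best LD proxy with r² ≥ 0.8 when one exists (highest r², ties by basepair
distance then rsid), inheriting the index variant's exposure record; outcome
effects reported for the other allele are negated (and frequencies
complemented), after strand complementation when the letters only match that
way.  Below-threshold palindromes and proxies are aligned by allele-frequency
side rather than letters; proxy alignment is logged as lower-confidence
because an r²-only LD reference carries no phase.  Proxies are sought only
for variants absent from the outcome set; palindrome exclusions are final.
Every input variant lands in exactly one audit category and the stage counts
reconcile exactly (`InstrumentAudit.check`).

## Genetic risk scores and variance explained

The GRS is beta-weighted, Σⱼ dosage_ij·β̂_Xj, matching its use here: the
variance a *weighted* score explains in an independent cohort validates the
discovery weights.  Missing dosages are mean-imputed at 2·eaf and logged.
Individual-level R² is the squared sample correlation of exposure and score,
with a nonparametric bootstrap percentile CI over individuals (default 2000
replicates).  Summary-level R² uses the linkage-equilibrium identity
Σⱼ2fⱼ(1−fⱼ)βⱼ²/σ², with σ the trait SD of the target population supplied
explicitly (the discovery populations here have SD 0.82%, the validation
cohort 1.40%, so the same score legitimately explains different fractions);
its CI is a parametric bootstrap over βⱼ.  Whether the original individual-
level CI was bootstrap or closed-form is not stated anywhere we can check;
bootstrap was chosen and is recorded here.

The observational association is a binomial GLM (IRLS, deviance tolerance
10⁻⁸, ≤50 iterations) of case status on exposure/scale_unit + age + sex; the
default scale unit 1.4% RDW is one control-population SD, so the coefficient
reads as log-odds per SD.  Perfect separation raises an explicit error.

## Power

Power uses the non-centrality approximation
z = √(N·R²·K(1−K))·|ln OR|, power = Φ(z − z₁₋α/₂), with N the outcome GWAS
size and K its case fraction.  It inverts in closed form for the minimum
detectable OR, exp((z₁₋α/₂+z_power)/√(N·R²·K(1−K))), and the required
sample size N = (z₁₋α/₂+z_power)²/(R²·K(1−K)·ln²OR) with case count
ceil(N·K) at a 1:c case:control ratio (K = 1/(1+c)).  The formula reproduces
the motivating study's printed anchors (minimum detectable ORs 1.52 and 1.7
at R² 2.6% and 1.7%; ~20 600 required cases within 5%), which is why this
variant was adopted; published MR power calculators differ in small terms
and the exact variant behind a given figure is rarely printed.  Note the
two-sided approximation ignores the opposite-tail rejection region, so
"power" at OR = 1 is Φ(−z₁₋α/₂) ≈ 0.025, not α.  z-values are always
computed from scipy, never hard-coded.

## Between-study meta-analysis

When the outcome GWAS is itself a meta-analysis (here four case-control
studies with differently ascertained controls: 847/5048, 694/1560, 269/1068,
275/1983 cases/controls), the causal effect is re-estimated within each
study and compared: Cochran's Q with fixed-effect weights 1/se², and a
DerSimonian–Laird random-effects pool, tau² = max(0, (Q−df)/(Σw−Σw²/Σw)),
weights 1/(se²+tau²).  DL is the default moment estimator in meta-analytic
practice; REML is out of scope.  tau² truncates to zero whenever Q ≤ df, so
the pool then equals the fixed-effect estimate, and the random-effects SE is
never below the fixed-effect SE.

## The synthetic-data generator

The generator emulates the study conditions end to end:

- **Exposure GWAS** (default N = 170 000): minor-allele frequencies uniform
  on (0.05, 0.5); true per-allele effects drawn as magnitude shapes and
  deterministically rescaled so Σ2f(1−f)β² equals the target R² *exactly*
  (default 0.12; the full-scale scenario uses 0.127 with a 5-variant
  iron-status subset scaled separately to 0.017).  Observed effects add
  independent N(0, se²) noise with se = 1/√(2f(1−f)N); p-values are
  two-sided Wald, clamped at the smallest positive normal double.  Effects
  are oriented so the reported effect allele is the trait-increasing allele,
  as GWAS instrument tables conventionally are.
- **Outcome GWAS** (default N = 11 744, K = 2085/11 744): true effects
  b·β_X plus any pleiotropic direct effect; observed on the log-odds scale
  with se = 1/√(2f(1−f)·N·K(1−K)) and noise independent of the exposure
  draw (the defining two-sample property).  Generating summary statistics
  directly, rather than simulating outcome genotypes, is what makes the
  analytic power formula an exact description of the simulated test
  statistic and keeps thousand-replicate calibration runs cheap.
- **Representation noise**: a configurable fraction of outcome records is
  reported for the other allele (30%) and/or the other strand (20%), so
  harmonisation is genuinely exercised in every simulated run.
- **Pleiotropy**: "balanced" draws mean-zero direct effects; "directional"
  draws one-signed direct effects U(0, 0.2) for a 30% invalid fraction — a
  common convention in MR simulation work, sized so invalid instruments
  carry a visible directional shift relative to Wald-ratio noise at this
  outcome sample size.
- **LD and proxies**: block-diagonal r² references; the full-scale scenario
  removes 32 instruments from the outcome panel and gives 12 of them an
  r² = 0.9 proxy partner, reproducing the 212 → −13 palindromic → −20
  unmatched → +12 proxied → 179 audit arithmetic.
- **Cohort**: Hardy–Weinberg Binomial(2, f) dosages for independent loci;
  the exposure is √R²·(standardised score) + √(1−R²)·noise so the
  *population* score-R² equals its target (default 0.026, VUMC-like mean
  13.6 and SD 1.4); case status is logistic in standardised exposure, age
  and sex with the intercept solved numerically for the target case
  fraction, and the default exposure log-OR is ln 1.90 per SD.

All randomness flows from one root seed through a fixed SeedSequence split
(variant structure / exposure / outcome / cohort / per-study / pleiotropy),
so every stage is independently reproducible and two runs with one seed are
identical.

**Effect-shape choice.** Default shapes are |N(0,1)| ("no particular scale",
rescaled anyway).  The full-scale `paper_shape` preset instead uses
sign·(1+0.3|N(0,1)|) and re-draws observation noise for any variant whose
observed p misses the significance threshold: with unbounded shapes roughly
40% of a 212-variant panel scaled to R² = 12.7% would miss genome-wide
significance in any one realisation, and the fixed 212 → 179 audit
arithmetic could not be reproduced deterministically.  This mimics the real
situation — published instrument lists are, by construction, conditioned on
discovery significance.  Estimator-calibration scenarios keep the plain
normal shapes and do *not* re-select on significance, because re-selection
would add winner's-curse conditioning that the analytic power formula does
not model.

**What the generator does not emulate**: realistic LD from reference panels
(blocks are constant-r²), population stratification, relatedness, assortative
mating, between-cohort allele-frequency differences, case-control
ascertainment effects on the exposure GWAS, and effect-size/frequency
coupling.  Passing calibration tests therefore demonstrates internal
statistical correctness of the estimators and pipeline under the stated
model, not robustness to those real-data complications.

## Problem sizes and numerical choices

Calibration runs use 1000 replicates for the null type-I error, 500 for
empirical-vs-analytic power, and 200 for the pleiotropy bias contrast; at
the analytic-SE outcome noise these sizes put the Monte-Carlo SE well inside
each acceptance band.  The causal-recovery scenario uses 50 strong
instruments at R² = 2.6% so that regression dilution from noisy exposure
effects (≈ n_instr/(N_X·R²)) stays near 1% and the analytic power formula
describes the simulated statistic; the type-I and recovery scenarios use 150
instruments at R² = 12%.  Weighted-median bootstraps inside replicate loops
use 200 resamples (point estimates are bootstrap-free; only SEs need
resampling).  Ties in LD pruning break by rsid; proxy ties break by distance
then rsid; the weighted median at an exact half-weight boundary returns the
boundary ratio.  Degenerate inputs (zero exposure effect, single instrument
under random effects, constant scores, single-class cohorts, separation)
raise explicit errors or documented fallbacks rather than propagating NaNs.

## Known limitations

- No MR-Egger, mode-based, or outlier-removal estimators: the implemented
  pair (IVW + weighted median) is the analysis this package reproduces.
- First-order Wald SEs; no correction for winner's curse or sample overlap.
- The individual-level R² bootstrap is percentile-method only.
- The power approximation is a non-centrality argument, not an exact
  likelihood calculation; it reproduces the study anchors but differs in
  small terms from other published calculators.
- One reporting discrepancy in the motivating study is preserved as
  documentation: the primary IVW CI appears once as 0.92–1.24 and once as
  0.93–1.23; the package reports one normal-theory CI per fit and does not
  adjudicate between the two printed versions.
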