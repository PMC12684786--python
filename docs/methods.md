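# Methods notes

This note records the modeling choices behind `cismr`: what each component
assumes, which knobs matter, what the synthetic generator does and does not
emulate, and where the genuinely open design decisions were resolved.

## Instrument construction

A cis instrument is the set of variants within the target gene ± a flank
(default 300 kb, both boundaries inclusive) whose exposure association has
`p < 5×10⁻⁸`, thinned by greedy LD clumping at `r² < 0.1`.  Clumping
repeatedly takes the smallest-p unassigned variant as an index and discards
unassigned variants with `r² ≥` threshold against it; ties on p are broken
by variant id, so output is independent of input row order.  The LD matrix
is an explicit input (square TSV or the simulator's realized `r²`); no
reference panel is bundled, since which panel to use is analysis-specific.

Instrument strength is summarized by per-variant `F = (β/se)²` (> 10 is the
conventional weak-instrument floor) and by the additive variance explained
`Σ 2p(1−p)β²/Var(trait)`.  The additive sum treats clumped variants as
independent; residual correlation up to `r² = 0.1` makes it a mild
overestimate, which we accept as the field's standard approximation.

## Harmonization

Outcome effects are re-expressed on the exposure's effect allele: matching
labels (or their strand complement) pass through; swapped labels negate the
outcome beta and complement the frequency.  Palindromic variants (A/T, C/G)
cannot be oriented from labels; they are aligned by allele frequency when
the minor-allele frequency is below 0.42 in both studies (window 0.08 from
0.5) and dropped otherwise, the standard conservative practice.
Irreconcilable allele sets and variants absent from the outcome are
excluded with per-reason counts, never fatally.  Missing numerics are
written as `NA` and `NA`/empty/`.` parse as missing; indels and
multi-allelic rows are rejected at parse, because the instruments of
interest are SNPs.

## Estimators

All ratio-based estimators use first-order weights `w_j = b_Xj²/se_Yj²`,
ignoring exposure-side error in the weights.  This matches the default of
the analysis stacks practitioners use; it slightly understates uncertainty
for weak instruments, which is why the instrument-strength gate matters.

- IVW (fixed effect): weighted mean of ratios; `se = (Σw)^{-1/2}`.  With a
  single variant the Wald ratio is used instead (the pipeline switches
  automatically).
- Cochran Q against the IVW estimate, df = n−1, chi-square upper tail.
- MR-Egger: WLS of `b_Y` on `b_X` with free intercept after orienting all
  variants to `b_X ≥ 0` (Egger is not invariant to allele flips; this
  orientation is the conventional fix).  Coefficient SEs use multiplicative
  residual dispersion floored at 1, so they never deflate below the
  fixed-effect SE; with exactly collinear inputs the dispersion is zero and
  the floor keeps the covariance finite.
- Weighted median: ratios sorted, standardized cumulative weights
  `s_j = (Σ_{i≤j} w_i − w_j/2)/Σw`, linear interpolation at 0.5.  SE from a
  seeded parametric bootstrap (default 1000 draws of `(b_X, b_Y)` from
  their reported errors).  Finite-sample note: with a directional invalid
  fraction approaching 50% of the weight and *homogeneous* instrument
  precision, the estimator's crossing-quantile bias is comparable to its
  SE; robustness in practice comes from heterogeneous precision, where the
  crossing sits inside the tight cluster of strong valid instruments.  The
  robustness test reflects that regime deliberately.
- Weighted mode: normal-kernel density of the ratios with bandwidth
  `φ·0.9·min(sd, IQR/1.34)·n^{−1/5}` (φ default 1), maximized on a
  512-point grid spanning mean ± 4 sd; SE by seeded bootstrap.  If all
  ratios coincide the common value is returned.
- Leave-one-out: IVW re-estimated dropping each variant, as a tidy table.

CIs are normal-theory at ±1.959964·se; p-values are two-sided normal.  A
report-level Bonferroni threshold 0.05/(number of primary outcomes) is
recomputed from the analysis config rather than hardcoded.

## Decrement scaling

Exposure-unit effects (per ln-biomarker unit) are re-expressed per d%
proportional reduction via `scale = ln(1 − d/100)`; betas and SEs multiply
by `scale` and `|scale|`, so z and p are unchanged.  The package's default
conventions are 30% (multi-variant score) and 18% (focal missense variant
homozygote contrast).  Whether the exposure GWAS reports natural-log or SD
units is a user decision; everything downstream is linear in that choice.

## Between-outcome contrasts and power

Two estimates on the same scale are contrasted by a two-study fixed-effect
Cochran Q (df = 1).  Recovering `(β, se)` from a printed OR and 95% CI uses
`β = ln(OR)`, `se = (ln hi − ln lo)/(2·1.959964)`; note that contrasts
recomputed from *rounded* printed CIs can lose significance that the
unrounded analysis had — the wide-interval hemorrhage comparison is the
canonical example, and the test suite documents it as such.

Power uses the binary-outcome non-centrality approximation
`z = b·sqrt(N·r²·K(1−K))`, `power = Φ(z − z_{1−α/2})`, inverted in closed
form for the minimum detectable (protective) OR at target power.  External
power calculators parameterize the same quantity slightly differently, so
printed thresholds from other tools should be read as qualitative
anchors rather than exact targets.

## Individual-level analyses

The genetic risk score is a weighted dosage sum.  Percentile contrasts
compare median biomarker in the top vs bottom score tails (type-7 quantile
cuts), with a percentile bootstrap CI (default 10 000 iterations, seeded)
and a Mann-Whitney test.  Medians, not means, are contrasted: biomarker
distributions like CRP are heavily right-skewed, and the percent change in
medians is the quantity that survives monotone rescaling.  Genotype-class
contrasts report class medians and percent decreases vs the reference
homozygote with bootstrap CIs, Kruskal–Wallis across classes and Dunn's
pairwise z tests with tie correction; multiplicity adjustment is Holm by
default (the correction method is configurable, since Dunn's test is named
in the literature without one).  Variance explained is the R² of the
univariable OLS of ln-biomarker on the predictor; the adjusted fit (age,
sex, 10 principal components) is reported alongside for coefficients only.

Dunn's test is implemented in-package (pooled-rank z statistics with tie
term `Σ(t³−t)/(12(N−1))`) because no installed library provides it; it is
validated against hand-ranked examples and the no-tie closed form.

## Synthetic-data generator

Genotypes: two haplotypes per individual, each a latent standard-normal
AR(1) process across variants (adjacent correlation `ld_rho`, default 0.3)
thresholded at the per-variant MAF quantile; dosage is the haplotype sum.
This gives tunable, realistic-magnitude adjacent `r²` (about 0.08 for the
default, i.e. just under the clumping threshold) without a reference panel.

Biomarker: `ln T = Σ a_j (dos_j − 2·maf_j) + ε`, `ε ~ N(0, σ²)`, σ default
1 (the ln-CRP scale).  Centering keeps the trait median near 1 so
proportional decrements stay interpretable.  When `a` is not supplied it is
drawn so per-variant F statistics are log-uniform on [40, 1600] *at the
configured exposure sample size* — instrument strength, not raw effect
size, is what the estimators respond to, and this mirrors the wide F range
typical of large biomarker GWAS.  When a target variance explained is
needed instead (e.g. a score explaining 0.45% of ln-CRP variance),
`effects_for_variance_explained` splits the implied genetic variance
equally across variants.

Disease: `logit P(case) = intercept + θ·ln T + Σ γ_j dos_j`, intercept
default −3 (≈ 5–6% prevalence), γ default 0.  Association scans use exact
per-variant logistic maximum likelihood (a dedicated two-parameter Newton
solver, validated against a general-purpose implementation in the tests)
so outcome effects are genuine log-odds; quantitative scans use closed-form
least squares.

**Non-collapsibility.** Logistic models marginalize: the per-variant
GWAS-scale log-odds is attenuated relative to the conditional θ by the
biomarker variation the variant does not explain, and the attenuation
depends on prevalence (it vanishes for rare outcomes and peaks near 50%).
`marginal_log_odds` computes the small-effect marginal slope
`θ·E[p(1−p)]/(K(1−K))` by Gauss–Hermite quadrature;
`conditional_log_odds` inverts it and `calibrate_theta_for_marginal`
applies the inversion using a config's own noise, genetic variance and
prevalence.  Recovery tests and the acceptance script target the marginal
estimand, because that is what a summary-statistics MR can ever see.

What the generator does **not** emulate: ancestry structure and relatedness,
imputation uncertainty, genome-wide polygenic background, case-control
ascertainment other than a simple prevalence intercept, and sample overlap
between exposure and outcome studies.  Passing tests therefore demonstrate
the statistical machinery is correct under the stated model, not that any
particular real-data result is beyond doubt.

## Problem sizes

Default simulated sample sizes (exposure 100 000; outcome 150 000; cohort
100 000, with 50 000 used in the recovery checks) are chosen so a full
analysis runs in seconds on a single core while keeping per-variant F
statistics, case counts and score-R² in the regimes of the motivating
consortia studies.  Calibration studies run at the summary level
(`sample_summary_instruments`) — drawing `(b_X, b_Y)` directly from the
two-sample sampling model — which is exact for the estimator properties
being measured and lets type-I error and coverage be assessed over
thousands of replicates.

## Known limitations

- First-order IVW weights; no second-order or exact weighting option.
- Correlated instruments are treated as independent after clumping
  (`r² < 0.1`); no generalized (LD-aware) IVW.
- No MR-PRESSO or multivariable MR.
- The bundled 26-variant instrument table is synthetic (see its `.meta.yaml`);
  its genome build is recorded as unknown, mirroring the general situation
  that a cis window is only meaningful relative to a stated build.
- The percentile-contrast magnitude in a synthetic cohort follows
  normal-theory tail expectations for the configured score R²; empirical
  biobank contrasts can differ from those expectations (skewed score
  distributions, assay floors), so the generator reproduces the procedure,
  not any particular printed percentage.
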