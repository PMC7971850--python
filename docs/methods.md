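# Methods

## Model and identifying assumptions

`summr` implements 2-sample Mendelian randomization on summary statistics.
The structural model behind every estimator is

    β_Yj = θ · β_Xj + α_j ,

where β_Xj is variant j's effect on the exposure (estimated in one GWAS),
β_Yj its effect on the outcome (estimated in a second, non-overlapping
GWAS), θ the causal effect of interest, and α_j a horizontal-pleiotropy
term.  Valid instruments have α_j = 0 and the three usual IV conditions:
association with the exposure, no association with confounders, and no
effect on the outcome except through the exposure.  The estimators differ
in what they assume about the α_j:

| estimator | assumption on pleiotropy |
|---|---|
| IVW (fixed/random) | α_j = 0 for all j (random-effects absorbs balanced heterogeneity) |
| MR-Egger | α_j independent of β_Xj (InSIDE); mean α estimated as the intercept |
| weighted median | valid instruments carry ≥ 50 % of the inverse-variance weight |
| mode-based | the largest cluster of similar Wald ratios is valid |
| MR-PRESSO | most variants valid; pleiotropic ones are detectable outliers |

Binary outcomes enter on the log-odds scale, so θ exponentiates to an odds
ratio per unit (or SD) of the exposure.

## Estimator details and numerical choices

**Wald ratio.** θ̂_j = β̂_Yj/β̂_Xj with first-order delta-method standard
error se_Yj/|β̂_Xj|.  A second-order variance (adding β̂²_Yj se²_Xj/β̂⁴_Xj)
is available behind a flag and propagates into the weights of the median
and mode estimators; the first-order form is the default and is recorded in
the estimate metadata.

**IVW.** Closed-form weighted regression through the origin, weights
1/se²_Yj.  The random-effects model is multiplicative overdispersion with a
floor at 1 — the standard error is never deflated below the fixed-effect
value when Q < k−1.  Confidence intervals use the normal 0.975 quantile.
With a single instrument IVW degrades to the Wald ratio and says so in its
metadata.

**MR-Egger.** Rows are re-oriented so every β̂_Xj ≥ 0 before fitting
(the intercept is not equivariant to per-variant sign flips).  Both
coefficient standard errors carry the multiplicative factor
max(1, √(Q_egger/(k−2))); intervals and p-values use the t distribution
with k−2 degrees of freedom, the small-sample convention for this
estimator.  At least 3 instruments are required.

**Weighted median.** Ratios are sorted; the cumulative normalized weight of
ratio j is p_j = (S_j − w_j/2)/S_total and the estimate interpolates the
ratio at p = 0.5.  The standard error is a parametric bootstrap: β̂_Xj and
β̂_Yj are redrawn from normals centred at their observed values with their
reported standard errors, 1,000 replicates by default, seeded; the seed and
replicate count are recorded in the output.  Stochastic estimators refuse
to run without an explicit seed.

**Mode-based.** A weighted Gaussian kernel density over the ratios with
weights proportional to inverse ratio variance and bandwidth
= bandwidth_factor × 1.4826·MAD(ratios) (bandwidth_factor defaults to 1;
the sample standard deviation substitutes when the MAD degenerates to 0).
The estimate is the density argmax located on a 2,001-point grid spanning
the ratios ± 3 bandwidths; grid ties resolve to the lowest grid index.  If
all ratios coincide the common ratio is returned exactly.  Bootstrap se as
for the median.

**Cochran's Q and leave-one-out.** Q uses the Wald ratios with first-order
inverse-variance weights against chi-square with k−1 df.  Leave-one-out
refits random-effects IVW k times and flags any variant whose omission
moves the estimate by more than a configurable multiple (default 1) of the
full-data standard error.

**MR-PRESSO.** The observed statistic is the weighted residual sum of
squares around leave-one-out IVW fits.  The null distribution comes from
parametric simulation (default 1,000 draws; the acceptance battery uses
2,000 so that Bonferroni-adjusted per-variant p-values can resolve below
0.05 with 50 instruments): β̂*_Xj ~ N(β̂_Xj, se_Xj), β̂*_Yj ~ N(θ̂_(−j)β̂_Xj,
se_Yj).  Empirical p-values use (r+1)/(n_sim+1), so no p is ever exactly 0.
Per-variant outlier p-values are Bonferroni-adjusted across instruments,
and — following the reference convention — outliers are only declared when
the global test is itself significant; this is what keeps the verdict
stable across resampling seeds on clean data.  The distortion test compares
the raw-vs-corrected slope displacement with the displacement caused by
removing equally many randomly chosen variants.  The corrected estimate is
plain random-effects IVW on the outlier-removed set.

**Multivariable MR.** Weighted multiple regression of β̂_Y on the m
exposures' effect columns jointly, no intercept, weights 1/se²_Yj, with
multiplicative overdispersion on k−m df.  A condition number above 1e10 on
the weighted normal equations raises a collinearity error.  An exposure
whose effect column is identically zero carries no information: the fit
solves the reduced system and reports beta 0 with infinite standard error
for that exposure, which makes the single-informative-exposure case reduce
exactly to univariable IVW.  Conditional instrument strength for a target
exposure regresses its variant effects on the other exposures' effects
(weights 1/se²_X,target, no intercept) and reports the precision-weighted
residual Q against chi-square with k−(m−1) df; large Q (small upper-tail p)
means the panel predicts the target beyond what it predicts of the other
exposures.  This Sanderson-style convention is validated against its
analytic noncentral expectation by simulation rather than against external
reference output.

## Instrument selection and harmonization

Selection keeps variants with p below the genome-wide threshold (default
5×10⁻⁸) and then clumps greedily in ascending p-value order: a variant is
discarded if it has r² above the threshold (default 0.01) with an already
accepted variant or lies within the distance window (default 1,000,000 bp,
center-to-center, half-open) of one on the same chromosome.  Ties on p
break by (chrom, pos, variant_id) so the output is order-independent.  The
stricter sensitivity configuration r² < 0.001 is a one-argument change.
Pairs absent from the LD table count as unlinked; this is logged when the
table is non-empty, and an explicitly empty `LDSource.independent()` means
"all unlinked" by declaration.  LD never comes from genotypes here — the
`LDSource` contract isolates that concern.

Per-variant variance explained uses the p-value/sample-size F inversion for
continuous traits (r² = F/(F+n−2), with the normal-quantile square as the
large-n fallback when the F quantile overflows for extreme p).  For binary
traits the per-allele log odds ratio is linearized onto the unit-variance
liability scale, b_liab ≈ b·K(1−K)/φ(Φ⁻¹(K)) with prevalence K defaulting
to the sample case fraction, and r² = 2f(1−f)·b²_liab.  This observed-scale
approximation is validated against an exact liability-threshold contingency
oracle in the tests (relative error well under 20 % for realistic effect
sizes) and is symmetric under allele relabeling.

Harmonization aligns every shared variant to the exposure's effect allele:
matching labels keep the outcome beta, swapped labels negate it, and
strand complements are tried for non-palindromic single-nucleotide pairs
(indels compare as exact strings, never complemented).  Palindromic pairs
(A/T, C/G) are strand-ambiguous: they are excluded when either dataset's
allele frequency lies in the configured window (default [0.4, 0.6]) or is
missing, and otherwise aligned by which side of 0.5 the frequencies fall
on.  The window applies to both datasets and the filter is applied in both
univariable and multivariable analyses by default (a flag disables it) —
the conservative reading.  Multivariable datasets take the union of
variants genome-wide significant in at least one exposure, require presence
in every exposure table and the outcome (absences are logged), clump the
union ranked by the best p across exposures, and align all tables to the
first exposure's effect allele.

## The screen

The screening driver fixes random-effects IVW as the primary estimator;
sensitivity methods (Egger, median, mode, leave-one-out, optional
MR-PRESSO) are reported alongside but never set the significance flag.
Significance is declared when the primary p-value falls below
α/(n_exposures × n_outcomes).  The threshold is reported exactly and as a
display string using the fewest significant digits (1 or 2) that keep the
relative rounding error within 5 % — the convention that reproduces how
such thresholds are conventionally quoted (0.05/34 → "0.0015",
0.05/8 → "0.006").  Each pair also carries a direction-concordance
indicator (all requested methods agree in sign) and per-pair seeds derived
by hashing (seed, exposure, outcome), so results are bit-identical across
runs and independent of iteration order.  Pairs that cannot be analysed
are recorded as failures and the screen continues.

`detectable_or` is a normal-approximation power calculation: the IVW log-OR
variance is taken as 1/(n_eff·R²) with n_eff = 4/(1/n_case + 1/n_control),
so the smallest detectable log OR at two-sided level α and a given power is
(z_{1−α/2} + z_power)/√(n_eff·R²).  The formula is deliberately matched to
the simulator's noise model and is validated against simulated rejection
rates at the boundary effect size; with other noise conventions the
absolute detectable ORs will differ even at the same R² and sample sizes.

## The synthetic generator

`simulate_gwas_pair` emulates the regime of a biobank-era MR analysis: a
continuous exposure GWAS of n = 300,000 (per-variant variance explained
drawn uniformly from [0.02 %, 0.1 %], so a default 50-variant panel
explains ~1.5–5 % of the exposure, and per-variant F runs ~60–300), and a
binary outcome GWAS with 6,406 cases and 902,088 controls reported on the
log-odds scale with standard errors 1/√(2·n_eff·f(1−f)).  Effect-allele
frequencies are uniform on [0.05, 0.95]; 10 % of variants get palindromic
allele pairs by default; chromosome/position assignments place variants
> 1 Mb apart, i.e. the panel is post-clumping by construction and carries
no LD.  Exposure and outcome noise come from independent spawned random
streams (the 2-sample design), and every draw descends from a single seed,
so identical seeds give identical tables.

Pleiotropy regimes: `none` (α = 0), `balanced(sd)` (zero-mean normal), and
`directional(mean, sd)`.  Directional means are applied relative to each
variant's exposure-increasing allele; without that orientation an
arbitrary allele-labelling would randomize the sign of α and silently turn
directional pleiotropy into balanced pleiotropy.  The calibration battery
sets the directional mean to twice the median outcome standard error with
sd = mean/2 — a moderate, dispersed pleiotropy scenario.

`simulate_multi_exposure` gives each exposure its own block of primary
variants and propagates effects through a strictly lower-triangular matrix
of cross-exposure path coefficients, so a mediation design (target →
mediator → outcome, no direct target effect) is expressed as a zero direct
θ for the target plus a nonzero path into the mediator.  Multiple outcomes
can share one variant panel with independent noise, which is how the
exposure × outcome screen is exercised jointly.

What the generator does *not* emulate: LD between instruments, winner's
curse from discovery-and-use in the same sample, sample overlap between
exposure and outcome GWASs, allele-frequency differences between cohorts,
strand errors, population stratification, and non-collapsibility of the
odds ratio (outcome effects are generated directly on the log-odds scale
rather than through individual-level disease liability).  Passing the
calibration suite therefore demonstrates that the estimators and their
inference are correct under the stated summary-statistic model, not that
real analyses are immune to those additional artifacts.

## Problem sizes in the test and acceptance batteries

Oracle-equivalence checks use 50 random fixtures of 5–25 variants;
parameter recovery runs 500 replicates per effect size (θ = 0, 0.1, 0.3;
k = 50), null calibration 2,000 replicates for the type-I error and 1,000
for the Q-uniformity Kolmogorov–Smirnov check, the pleiotropy battery 200
replicates, and MR-PRESSO stability 10 resampling seeds on one fixed
dataset with 2,000 null simulations each.  These sizes put Monte-Carlo
standard errors comfortably inside the assertion bands while keeping the
full battery to a few seconds.

## Known limitations

* Only the multiplicative random-effects model is offered for IVW/MVMR;
  additive overdispersion is out of scope.
* No MR-RAPS, debiased IVW, Steiger direction filtering, or nonlinear MR.
* Weak-instrument bias of order θ/F̄ is visible in principle but is ~0.5 %
  of θ at the default instrument strengths; nothing corrects for it.
* The liability-scale variance-explained formula is a linearization and
  degrades for large per-variant odds ratios (|log OR| ≳ 1).
* MR-PRESSO's single-pass outlier test inherits the reference method's
  behaviour: a very large outlier slightly contaminates the leave-one-out
  fits of its neighbours, which is why outlier declaration is gated on the
  global test.
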