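# Methods

This note documents the statistical model, the algorithmic choices and the
synthetic data-generating process implemented by `precisionrct`, including
the places where the design was genuinely open and the package had to make
a choice.

## Problem setting

A two-arm RCT randomizes participants to an intervention (A = 1) or usual
care (A = 0) with known probability p (default 0.5). Baseline covariates X
and outcomes at 0 and 18 months are observed. The analysis estimates an
individualized treatment rule d(X) → {0, 1} that maximizes the expected
*clinical reward* R (a scalar transform of 18-month change where higher is
better), and — distinctively — also identifies a third *muted* group for
whom the fitted model declares the two arms exactly equivalent.

Estimation and evaluation use the same sample (no sample splitting or
external validation); the value comparisons are therefore exploratory and
optimistically biased, which is inherent to the post hoc design this
package mirrors. This is the single most important caveat on any output.

## Rewards

Univariate rewards are fixed affine maps of 18-month change, clipped to
[0, 1]:

* HbA1c (% of total hemoglobin): change bounds (+5 worst, −5 best); a drop
  of 5 points maps to 1, a rise of 5 points to 0, no change to 0.5.
* PedsQL quality of life (0–100): change bounds (−30, +30), increasing.
* BMI z-score: reward 1 if the 18-month BMIz is ≤ 1.04 (the 85th
  percentile for age and sex) **or** below baseline; otherwise
  max(0, 1 − Δ/s) with penalty scale s = 1.0 z-unit of worsening.

Bounds are clinical constants rather than per-sample extremes so the reward
scale is identical across imputations and bootstrap resamples (a per-sample
min–max option exists but is not the default).

The composite reward encodes the hierarchy glycemia ≻ QoL ≻ weight status
by tiering on 18-month *levels*: HbA1c ≥ 9.0 % ⇒ r_C = r_H; HbA1c
acceptable but QoL < 70 ⇒ r_C = 1 + r_Q; both acceptable ⇒ r_C = 2 + r_B.
The tier thresholds (9.0 %, 70 points) and the linear BMIz penalty are
reconstructions of a published tiering narrative whose exact functional
form is not public; both are configurable, and the run manifest flags them
as reconstructions.

## Imputation

Missing values are allowed only in non-CGM baseline covariates
(participants without complete CGM data or missing outcomes are excluded
up front, mirroring the trial's participant flow). Chained equations run
over the incomplete columns in order of increasing missingness fraction,
10 sweeps per chain, m = 11 independent chains: continuous and count
columns use a ridge-stabilized linear model followed by a
predictive-mean-matching draw from the k = 5 nearest observed donors (so
imputed values always lie in the observed support); binary/categorical
columns use a multinomial draw from logistic-model probabilities. Each
conditional model regresses on all other covariates plus arm and the six
outcome fields (standard congeniality practice). m is required to be odd
because the final assignment is a vote; 11 is the smallest odd number
above 10. A complete-cases mode is available as a sensitivity analysis.

## The RLT forest and muting

Each of the 100 trees is grown on an independent 80 % subsample drawn
without replacement. At each node:

1. **Embedded importance.** `embedded_trees` = 20 bootstrap bags of the
   node's rows are drawn. For each bag and candidate variable, a stump cut
   is *chosen* on the bag (≥ `min_node_size` = 10 bag-weighted rows per
   side) and *evaluated* as the SSE reduction it achieves on the
   out-of-bag rows, minus the null expectation of that reduction (the OOB
   residual variance — one extra fitted mean). The honest evaluation is
   essential: an in-sample criterion lets a continuous variable with
   hundreds of candidate cutpoints overfit its way past a binary variable
   such as the arm indicator, which would systematically mute the
   treatment variable regardless of signal. Each bag also takes one
   *lookahead* step: variables are re-scored inside the two children of
   the bag's best first split, and a variable's bag score is the larger of
   its marginal and conditional gains. The lookahead is what lets the arm
   indicator rank highly at the root of a cohort whose treatment effects
   have opposite signs in different strata and therefore cancel
   marginally.
2. **Signal screen.** A variable's importance is its mean bag score only
   when that mean exceeds `importance_threshold` = 3 bag standard errors,
   else exactly zero. Pure-noise nodes thus terminate as leaves instead of
   splitting arbitrarily; this screen is the forest's signal-versus-noise
   discrimination and the main driver of the muted group.
3. **Split and mute.** The node splits on the top-importance variable at
   the in-sample variance-minimizing cutpoint (midpoint between adjacent
   sorted values; importance ties break to the lowest variable index, cut
   ties to the smallest cut). The bottom ⌈muting_rate · |others|⌉ of the
   remaining candidates (muting_rate = 0.3; the split variable is never
   muted at its own node) are removed from both children's candidate
   sets — muting is hereditary, so a variable muted at a node has exactly
   zero effect everywhere below it.

With muting_rate = 0, embedded_trees = 1, subsample_frac = 1 and
n_trees = 1 the estimator degenerates to a greedy variance-reduction CART
tree (a single embedded learner is defined as the deterministic in-sample
one-step lookahead), which the test suite verifies against an independent
brute-force CART implementation.

Counterfactual predictions set the arm coordinate to 1 and to 0 (binary
covariates, including arm, are not standardized; continuous and count
covariates are standardized to mean 0/SD 1 within each imputed dataset).
With tolerance 0 — the default — the *muted* label requires bitwise
equality of the two predictions, which occurs precisely when no tree in
the forest consults the arm variable on either routing path; a small ε
option exists for robustness. A participant's final label is the
plurality winner over the 11 per-imputation labels; two- or three-way
plurality ties (possible with three categories despite odd m, e.g.
4/4/3) resolve to muted, the conservative choice given that a tie means
no arm preference was replicated across imputations.

A single-forest muted label can be fragile in a near-null cohort — one
rogue tree whose root splits on the arm un-mutes every participant of that
forest — and the 11-forest vote is the mechanism that absorbs this.

## Value estimation

The value of a rule is the normalized (ratio) Horvitz–Thompson estimator
over rule-concordant participants (weights 1/p and 1/(1−p)). The ratio
form guarantees V̂ stays inside the reward's range and reduces exactly to
the within-arm mean for a constant-arm rule; the unnormalized sum/n form
does neither. Muted participants are evaluated under their observed arm by
default (the rule declares the arms equivalent for them, and this keeps
every participant concordance-eligible); excluding them is available by
flag. Percentile bootstrap CIs (B = 1000 by default) resample participants
with replacement with the rule held fixed — re-estimating 11 forests per
resample would be computationally disproportionate, and the resulting CIs
must be read as conditional on the estimated rule. Resamples in which a
required quantity is inestimable (an arm absent, or no concordant row) are
redrawn and counted in the manifest.

## Subgroup profiles

Continuous variables: mean (SD), one-way ANOVA, pairwise Welch t.
Right-skewed variables (the CGM hypoglycemia counts by default): median
(IQR, linear-interpolation quartiles), Kruskal–Wallis, pairwise rank-sum.
Categorical: n (%), Pearson χ² without continuity correction, switching to
Fisher's exact test (2×2) or a fixed-margins Monte-Carlo test (larger
tables, 20,000 draws) when any expected count is below 5. Pairwise
comparisons are against the intervention group. Benjamini–Hochberg
adjustment is applied within two families — all omnibus tests, and all
pairwise tests — at two-tailed α = 0.05; the family boundary is a package
choice and is recorded with the outputs. Skewedness is schema-declared,
not auto-detected, to avoid coupling the test choice to a normality test.

## Synthetic cohorts

The generator emulates the eligible sample of an 18-month adolescent
type 1 diabetes trial:

* HbA1c drawn from a normal parent N(6.529, 2.747²) truncated to the
  eligibility window [8.0, 13.0] — the parent parameters are solved once so
  the *truncated* distribution has exactly mean 9.6 / SD 1.2, since the
  published moments describe the eligible sample, not the population.
* QoL from N(81.730, 13.385²) clipped to [0, 100], solved the same way for
  mean 81.2 / SD 12.4; BMIz from N(0.73, 0.91²).
* Age uniform 13–16 y; 50 % female; diabetes duration truncated-normal
  (6.3, 3.7) on [1, 15] y; a psychosocial self-management z-score N(0, 1).
* Hypoglycemia episode counts (CGM-derived, 7-day wear): negative binomial
  with (n, p) = (0.85, 0.18) for episodes < 70 mg/dL (median 2, IQR 1–6)
  and (0.70, 0.35) for < 54 mg/dL (median 1, IQR 0–2) — right-skewed
  count distributions matched to published medians and quartiles.
* Arm: Bernoulli(0.5), independent of everything at baseline.
* 18-month outcomes: baseline + drift (+0.3 % HbA1c, −1 QoL point,
  +0.05 BMIz) + κ·(population mean − baseline) + A·(stratum effect) +
  Gaussian noise (SDs 1.0 / 10.0 / 0.3). The mean-reversion term
  (κ = 0.3 for HbA1c and QoL, 0.1 for BMIz) gives realistic outcome
  tracking (corr(HbA1c₀, HbA1c₁₈) ≈ 0.65) and, importantly, means a null
  trial still contains prognostic baseline signal — which is what a
  fitted forest should latch onto instead of the arm indicator.
* Treatment-effect strata are half-open intervals of one covariate
  (default: benefit for self-management z ≥ 0.5, true null for |z| < 0.5,
  harm for z ≤ −0.5, effects ∓0.5 % HbA1c / ±5 QoL / ∓0.2 BMIz,
  scalable via `effect_scale`), validated to be exhaustive and mutually
  exclusive, and recorded per participant as ground truth.
* Missingness: 5 % MCAR on non-CGM covariates by default, with a MAR
  variant keyed to baseline HbA1c; 15.5 % of participants are flagged
  CGM-incomplete, mirroring the published participant flow.

What the generator does **not** emulate: covariate–covariate correlation
at baseline (all covariates are drawn independently), longitudinal visit
structure, informative dropout, CGM traces, or outcome missingness beyond
the eligibility filter. Passing tests on this generator therefore show
that the pipeline recovers the kinds of structure it models — calibrated
marginals, randomization, stratum-wise effects, MCAR/MAR covariate
missingness — not that it would recover subgroups in data with correlated
covariates or informative missingness.

## Numerical and testing choices

* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; stage sub-seeds are derived independently, so
  changing the bootstrap size cannot change the ITR.
* Standardization uses the n−1 (sample) SD; zero-variance columns pass
  through as zeros with a warning.
* Test problem sizes: generator calibration at n = 200,000; estimator
  unbiasedness over 1,000 cohorts of n = 500; subgroup recovery on one
  signal and one null cohort of n = 500 with m = 11 imputations and 100
  trees; bootstrap coverage over 500 replicates at n = 500 with B = 200.
  These sizes give Monte-Carlo error comfortably inside the asserted
  bands while keeping the full suite in a few minutes.

## Limitations

* No sample splitting: value estimates are in-sample and optimistic.
* The bootstrap holds the rule fixed; CI coverage is for the value of the
  *estimated* rule, not for rule-estimation uncertainty.
* Categorical covariates enter the forest as numeric codes; unordered
  categories with many levels would need explicit encoding.
* The muted/non-muted boundary depends on the importance screen
  (`importance_threshold`); lowering it grows trees deeper and shrinks
  the muted group, and no single value is right for every effect size.
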