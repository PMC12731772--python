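# Methods

## Problem setting

The package stratifies individuals into four ordered Type-2-Diabetes risk
classes (A low, B moderate, C high, D diagnosed) from eleven lifestyle
columns: age (y), sex, family history, smoking, drinking, thirst
(drinks/day), urination (voids/day), height (cm), weight (kg), fatigue,
and the binary diabetes outcome. The real cohort the method was developed
for is private; all development and testing run on a synthetic stand-in
(below).

## Synthetic cohort generator

The generator reproduces, by construction or by calibration, the published
structure of the study cohort:

* **Band allocation.** n = 1939 participants in five age bands
  (5–17, 18–30, 31–45, 46–60, 61–83) with fixed sizes
  (112, 384, 612, 517, 314) and fixed per-band case counts
  (3, 41, 148, 201, 149; 542 cases, prevalence 28.0%). Sizes and case
  counts are exact, not sampled, so band prevalences (2.7%, 10.7%, 24.2%,
  38.8%, 47.5%) are deterministic; which rows are cases is randomized.
* **Ages** are rounded truncated normals within each band,
  scale = band width / 4. Band locations form the one-parameter family
  loc_b(t) = lo_b + t·width_b; the single shared t is solved (bracketed
  root find on the analytic truncated-normal means) so the pooled mean
  equals 41.77 y. Solving against truncated rather than nominal means
  removes a ≈ +0.33 y truncation bias that the naive closed form leaves.
* **Symptoms** are conditional on outcome: thirst ~ N(8.5 / 5.3, 2.0) and
  urination ~ N(10.5 / 4.8, 2.2) (case / control means, rounded, clipped to
  their admissible ranges); weight ~ N(m₀ + 8.8 / m₀, 10) kg with m₀ solved
  so the prevalence-weighted mixture mean is 61.65 kg; fatigue
  Bernoulli(0.88 / 0.62), family history (0.45 / 0.20), drinking
  (0.25 / 0.15), smoking (0.15 / 0.15, null by design), sex Bernoulli(0.47)
  independent of outcome. These choices reproduce the published pooled
  means (thirst 6.18, urination 6.40, fatigue 0.69, family history 0.27,
  drinking 0.18) and the strong/weak association split (urination, fatigue,
  age strong; sex, smoking null).
* **Height** is N(161.6, 10) clipped to the observed 61–195 cm range and is
  independent of outcome. The printed SD of the source table (33.14) is
  inconsistent with its own quartiles (154/162/167); we match the quartiles.
  The nominal upper range "766 cm" is treated as a typo for 195.
* The printed outcome mean of 0.50 conflicts with the band case totals
  (542/1939 ≈ 0.28); the generator follows the band totals, which the
  age-prevalence table fixes exactly.
* Duplicate rows (possible on an integer grid) are removed by re-jittering
  height, so the no-missing / no-duplicate data-quality property holds by
  construction. A single `numpy` Generator seeded from the config drives
  every draw; identical configs give byte-identical tables.

**What the generator does not emulate:** survey measurement error,
within-band age clustering, correlations among symptoms beyond the shared
outcome (thirst and urination are conditionally independent given outcome),
or any real-world label noise. Passing tests therefore demonstrate internal
consistency and parameter recovery under the stated conditions, not
performance on the private cohort.

## Fuzzy risk labeling

Six graded features (age, urination, thirst, weight, height, fatigue) are
min–max scaled on their observed ranges (binary columns pass through; the
scaler is stored for prediction-time reuse). The composite score is a
convex combination with default weights proportional to the published
association effect sizes of those features (0.52, 0.79, 0.43, 0.33, 0.21,
0.64, renormalized) — the aggregation rule itself is not specified by the
source method, so this is a declared design choice that follows its own
effect-size ordering.

The S-membership function uses knots a = 0.1, b = 0.9 by default (the
source leaves them unstated): a full-range inclined segment with small
saturation margins. The printed bands (0.0–0.3 / 0.4–0.6 / 0.7–0.9 / 1.0)
leave gaps; we use the contiguous half-open bands A = [0, 0.4),
B = [0.4, 0.7), C = [0.7, 1), D = {1}, which cover [0, 1] totally and
reproduce every published (membership, class) example. Outcome 1 forces
μ = 1 / class D after scoring.

With these defaults the synthetic cohort labels as A=802, B=524, C=71,
D=542 (seed 1): class C is deliberately rare, which stresses the
calibration stage (see below).

## Classifier

All ten predictors (normalized, never the fuzzified score) feed a
64–32–16 ReLU network with a 4-way softmax head, categorical cross-entropy
plus an L2 penalty (10⁻³), Adam (lr 10⁻³), batch size 32, inverted dropout
0.2 on hidden layers, Glorot-uniform initialization, and at most 150
epochs. Early stopping is unspecified in the source configuration; we
monitor cross-entropy on a stratified 10% slice of the training partition,
patience 10 epochs, and restore the best weights. The implementation is
pure numpy so a single seed reproduces initialization, dropout, shuffling
and therefore the fitted weights bit-for-bit.

## Monotone-spline calibration

Per class, one-vs-all: sort raw probabilities (stable; exact ties pooled),
fit pool-adjacent-violators (PAV) isotonic regression against the binary
indicators, collapse each PAV block to a (weighted-mean p, block value)
node, and interpolate the nodes with a monotonicity-preserving cubic
Hermite interpolant (PCHIP). PCHIP through monotone nodes cannot overshoot,
so the isotonic constraint holds exactly while the map is smooth between
knots. Evaluation is clamped: constant extrapolation outside the outermost
nodes, outputs clipped to [0, 1]. The per-class maps are combined row-wise
and renormalized onto the simplex; a row on which all maps evaluate below
10⁻¹² falls back to the uniform vector with a warning (the ratio is
undefined there, and uniform is the maximum-entropy completion).

Calibration is fitted on the training partition by default (it consumes
true labels), with an option to fit on held-out data instead.

The practical effect on the synthetic cohort is concentrated in the rare
class C: raw softmax scores for C almost never reach the argmax, while the
calibrated scores recover most C records (test recall 4.8% → 61.9% at
seed 1) at a small precision cost, with overall accuracy and macro AUC
essentially unchanged. Both raw and calibrated reports are always emitted,
since which variant a deployment should report is a policy choice.

## Evaluation

Threshold metrics come from the confusion matrix; κ = (p_o − p_e)/(1 − p_e)
with chance agreement from marginal products; per-class metrics with zero
denominators are reported as 0 with a warning. One-vs-rest AUC uses the
rank (Mann–Whitney) formulation with ties credited 0.5 — analytically equal
to trapezoidal ROC integration but stable when the classifier emits few
distinct probability values; macro AUC is the unweighted mean. Feature
importance is the classical one-way ANOVA F; a zero within-class variance
with nonzero between-class spread is reported as an infinite-F sentinel
with a flag. Chi-square association tests use no continuity correction,
Cramér's V no bias correction, numeric variables are quartile-binned first
(the binning is a package choice; published V values are treated as
ordering guidance only), and raw p-values are compared to α = 0.05 without
multiple-testing correction.

## Recommender

A static rule base (YAML, shipped with the package, editable) maps each
class to diet / activity / monitoring / referral items with structured
parameters (kcal ranges, minutes/day) and to an exercise chart (a 5-item
chart for diagnosed patients; a 7-item chart adding jogging and resistance
work otherwise). Rules carry an ordinal intensity that is asserted
non-decreasing A → D; class D always includes a clinician referral. A small
offline catalog stub stands in for live grocery-price feeds; no scraping or
network access is involved.

## Problem sizes and numerical choices

Default experiments run at the full cohort size (n = 1939); the end-to-end
pipeline smoke tests use a scaled cohort (n = 240) with proportionally
scaled bands. Tolerances: simplex conservation 10⁻⁹; membership-function
continuity 10⁻¹²; generator fidelity ±0.5 on the pooled age and weight
means across a 20-seed sweep; spline-vs-PAV agreement exact (10⁻¹²) at the
knots. Ties: stable sorts everywhere; PAV pools exact ties before fitting.
Degenerate inputs: constant non-binary columns refuse to scale (named
error), single-level categorical variables yield V = 0 with a warning,
one-class AUC dichotomies raise.

## Limitations

* The composite-score aggregation and the SMF knots are declared stand-ins;
  the exact fuzzified values printed in the source's example table are not
  derivable from its text and are not reproduced row-for-row.
* The published headline metrics (93.64% accuracy, κ 91.50%, per-class
  AUCs ≈ 0.93–0.95) were measured on the private cohort and are not
  reproducible here; the synthetic parameter-recovery experiment
  (accuracy ≥ 0.85, macro AUC ≥ 0.90 held out) is the stated surrogate.
* Risk labels are deterministic functions of the features by construction,
  so classifier performance on the synthetic cohort is an upper bound on
  what noisy real labels would allow.
* The recommender is a transcription of expert-curated static rules; it
  does not personalize beyond the class (profiles are accepted but
  currently informational) and is not medical advice.
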