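# Methods

## The reasoning model

The system is a lazy, instance-based predictor over a *case base* of
previously discharged NICU neonates.  A case is a vector of expert-selected
risk factors — birth weight (BW, grams) and gestational age (GA, weeks) as
continuous features, the rest boolean (respiratory distress syndrome,
sepsis, intraventricular hemorrhage, …) — plus a solved outcome: alive/dead
for the survival task, an integer stay in days for the LOS task.

Retrieval ranks stored cases by the weighted Euclidean distance

    d(x, y) = sqrt( Σᵢ wᵢ² (xᵢ − yᵢ)² / Σᵢ wᵢ² )

computed on min–max normalized features, so every coordinate difference and
hence d lies in [0, 1].  The similarity a clinician sees is 100·(1 − d)%;
this linear transform is a design choice — any monotone transform preserves
the ranking, and the linear one keeps 100% ⇔ identical and 0% ⇔ maximally
distant.  The denominator makes the distance invariant to rescaling all
weights by a constant, so only weight *ratios* matter.  Distance ties break
on ascending case id; this makes retrieval deterministic across runs and
file orderings (features are always taken in schema order).

Reuse: for survival, the k retrieved cases vote and ties go to the nearest
neighbor, so k = 1 — the setting used throughout the evaluation harness —
reduces to the nearest case's outcome.  For LOS the prediction is the
similarity-weighted mean of the neighbors' stays rounded half-up to whole
days (k = 1 again reduces to the nearest case's stay; if all similarities
are zero the plain mean is used).  The weighting rule for k > 1 is a
package choice: it is continuous in the similarities and coincides with the
k = 1 behavior in the limit.

Revise/retain: a solved case is parked in a temporary store with the
system's prediction; if the clinician rejects the prediction their own
solution is recorded alongside.  Only after the real discharge outcome is
known is the case promoted into the permanent base — with the *actual*
outcome as its solution, so the base only ever contains verified cases.
Promotion marks the fitted normalization bounds stale; they must be refitted
before the next retrieval, which keeps every stored case and every new probe
normalized against the same bounds.

## Expert weights

Candidate risk factors are rated by a panel on a 1–5 importance scale.  A
factor is retained when ≥ 60% of raters give it a 4 or 5 (ties at exactly
60% are retained).  The retained factor's raw weight is its mean rating,
normalized by the sum of retained means so the weights sum to one.
Sum-normalization rather than min–max is deliberate: min–max would assign
weight zero to the least-important retained factor, which contradicts both
the intent (every retained factor matters) and the shipped schemas, whose
weights are all positive and sum to ≈ 1 (0.9992 after 4-decimal rounding).
Normalization is scale-free: weight ratios equal mean-rating ratios.

## Preprocessing

**Imputation** is class-conditional for the survival task: within each
outcome class, a continuous feature's missing cells are filled with the
class mean when the observed class sample passes Shapiro–Wilk normality at
α = 0.05, otherwise the class median; samples with n < 3 (below the test's
minimum) or zero range default to the median, which there equals the mean.
Boolean features are filled with the class-majority value, with a 50/50 tie
filling 1 — a deterministic rule chosen over probabilistic draws for
reproducibility.  New problems have no class by definition and are filled
from pooled (all-case) statistics; the same applies to the LOS task, whose
outcome is a day count rather than a class.  A feature with no observed
values inside a class is an error, not a silent fill.  Imputation never
touches observed cells.

**Normalization** maps each feature through (x − lo)/(hi − lo) clipped to
[0, 1], with lo/hi fitted on the *development* case base only (boolean
features are pinned to [0, 1], constant features map to 0).  Test cases and
new problems reuse the development bounds and clip when out of range — no
statistic is ever fitted on evaluation data.

**SMOTE.**  Mortality runs near 9%, so the retrieval base is optionally
balanced by synthesizing minority cases: pick a random minority case x, one
of its k = 5 nearest minority neighbors nn (weighted Euclidean distance in
normalized space), and return s = x + u·(nn − x) with u ~ Uniform(0, 1).
Synthetic booleans round to {0, 1}; synthetic cases are flagged and carry
their parents' ids, and exactly majority − minority of them are generated
(exact parity).  k = 5 is the technique's classical default.  Balancing
applies only to the retrieval base — the test set is never resampled.

## Evaluation

An 80/20 random split (development size = round-half-up of 0.8·n, so
1682 → 1346/336) separates the case base from the test set.  Survival
predictions are tallied with **alive as the positive class**: sensitivity is
survivor recall, specificity is death recall.  The suite is accuracy,
precision, sensitivity, specificity (percentages), F-score, MCC and
standard Cohen's kappa; any metric with a zero denominator is reported as
undefined (`None`), never as 0.  LOS is scored by RMSE in days.  Reports
round percentages to 2 decimals and unitless coefficients to 3.

## Synthetic cohorts

The generator emulates the coarse structure of the development registry:
~9% mortality, BW ~ N(3200, 600²) g clipped to [500, 5000], GA ~ N(38, 2.5²)
weeks clipped to [22, 42], boolean risk factors Bernoulli(0.15) among
survivors, ~1% missingness completely at random, and LOS averaging 15 days
in 0–191.

One knob, `effect_size`, controls class separation: the dead class's
continuous means shift down by `effect_size` within-class standard
deviations, and each risk factor's log-odds shift up by `effect_size`
(at effect 2: 0.15 → 0.57).  At `effect_size = 0` the classes are
exchangeable by construction.

LOS is log-normal with log-linear terms in the number of risk factors
present (slope 0.30) and in a continuous severity score — the standardized
BW/GA shortfall (slope 0.50) — plus residual log-sd 0.35; the intercept is
calibrated at generation time so the pre-clipping sample mean equals the
configured `los_mean`, after which stays are rounded to whole days and
clipped to [0, los_max].  Tying the stay to the very features the retriever
measures is what makes the LOS signal learnable by a nearest-neighbor
regressor; with these slopes the 1-NN RMSE sits well below a
predict-the-mean baseline (≈16–22 vs ≈22–26 days across seeds at n = 1682)
while the stay distribution stays right-skewed with mean ≈ 15.  An optional
`ga_bw_correlation` knob induces a chosen within-class GA–BW correlation via
a shared latent; it defaults to 0 because the real registry's correlations
are not published.

What the generator does *not* emulate: the registry's true marginal
distributions and feature correlations, informative missingness, temporal
drift, and any dependence of LOS on survival status.  Passing tests
therefore demonstrate that the machinery is correct and recovers planted
structure — not that the published real-cohort performance is reproduced.

A second generator builds complete expert-rating matrices in which a chosen
number of factors is guaranteed to reach the 60% agreement rule and the rest
guaranteed to fail it, for exercising the weights pipeline end to end.

## Known behavior under the null

With exchangeable labels (effect 0), a 1-NN prediction is a draw from the
label marginal, so expected accuracy is the chance-agreement rate
p² + q² (≈ 83.6% at 9% mortality) — *below* the majority rate p (91%) by
q(p − q) ≈ 7.4 points.  A nearest-neighbor classifier on uninformative
features is strictly worse than always predicting "alive"; the test suite
checks the null accuracy against p² + q².

## Problem sizes and numerical choices

The test suite and the reproduction script run cohorts of n ≤ 1682 (the
registry scale) with exact-scan retrieval — a 336 × 1346 weighted distance
matrix is a single vectorized operation, so no approximate indexing is
needed or provided.  Property tests use 10³ random vectors/matrices;
hypothesis suites are derandomized for reproducibility.  All randomness
(cohort generation, splits, SMOTE) flows through explicit integer seeds of
`numpy.random.default_rng`; equal-seed runs are bit-identical.

## Limitations

- The two shipped schemas encode one expert panel's weights; the package
  aggregates new rating matrices but does not model rater reliability.
- Imputation is univariate (mean/median/mode); no model-based imputation.
- The balanced evaluation mode applies only to the survival task: SMOTE
  needs a binary class, and no defensible balancing rule exists for a
  regression case base.
- Case bases are plain CSV and the temporary store a JSON journal; there is
  no database backend or concurrent-access story.
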