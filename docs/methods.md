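# Methods

## Model

`evidfuse` fuses the outputs of several pre-trained binary risk models
into one evidential verdict. The frame of discernment is the two-state
outcome Θ = {positive, negative} (here: MACE vs no MACE during an ACS
admission). Each base model is one evidence source; its reliability is
not assumed but *estimated* from how much its dichotomized output reduces
uncertainty about the outcome, and that reliability discounts its
evidence before combination.

The pipeline has four stages, all deterministic given the training data:

1. **Per-model operating threshold.** For each score channel the
   threshold is the *observed score* whose ROC point (FPR, TPR), under
   the strict rule "positive iff score > t", minimizes the Euclidean
   distance to (0, 1). Searching only observed values keeps the
   threshold an attainable operating point; ties break toward the
   smallest candidate (the more sensitive operating point), making the
   choice deterministic and independent of candidate order. Integer risk
   scores (GRACE-like channels, range outside [0, 1]) are min-max
   normalized with bounds taken from the training cohort; test-time
   scores outside the fitted bounds clip to [0, 1], since an affine map
   fitted on one cohort has no mandate to extrapolate evidence strength
   beyond it.

2. **Rough-set weights.** Dichotomized outputs plus outcomes form a
   decision table. The dependence of the outcome partition U/IND(R) on
   the attribute partition U/IND(A) is measured by the conditional
   entropy H(R|A) (natural log, 0·ln 0 = 0); attribute significance is
   ω(a) = |H(R | A−{a}) − H(R | A)| and weights normalize the ω's to the
   simplex. A duplicated or constant column has significance exactly 0.
   Two conditioning directions exist in the literature depending on
   which partition is held outside the sum; conditioning the *outcome*
   on the *attributes* is the direction under which a model that
   perfectly predicts the outcome receives maximal significance, so it
   is the default (`entropy_direction="decision-given-attrs"`). The
   transposed form is retained behind `entropy_direction="as-printed"`
   for auditability; it is not recommended, since under it a perfect
   single predictor can receive zero significance.

3. **Rescaling to a common evidential scale.** The piecewise-linear map
   A\* sends [0, threshold] onto [0, 0.5] and [threshold, 1] onto
   [0.5, 1], so "model votes positive" is exactly "A\* > 0.5" for every
   channel regardless of its native threshold.

4. **Weighted BPA and Dempster combination.** Source i with weight w and
   adjusted output a contributes masses m(1) = w·a/(w+1),
   m(0) = w·(1−a)/(w+1), m(Θ) = 1/(w+1): weight 0 is the vacuous
   assignment (total ignorance, the identity of Dempster's rule) and
   large weights approach the categorical (a, 1−a, 0). Dempster's rule
   combines sources pairwise, renormalizing the conflict mass K by
   1/(1−K); with three focal elements on a binary frame the rule is
   closed-form. The decision value R = m(1)/(m(0)+m(1)) is thresholded
   (strict >) at a cut-off calibrated by the same top-left search on the
   training decision values. Belief and plausibility of the positive
   outcome, Bel = m(1) and Pl = m(1)+m(Θ), are reported as the
   ignorance interval.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `entropy_direction` | `decision-given-attrs` | conditioning direction of the rough-set dependence measure (see above) |
| `normalize` | `"auto"` | min-max bounds are fitted (training min/max) for any channel whose training scores leave [0, 1]; a dict of explicit `(min, max)` per channel overrides |
| decision threshold | fitted | cut-off on R; strict comparison, boundary classified negative, mirroring dichotomization |
| `cross_validate(k, seed)` | 5, required | stratified shuffled folds; the original study does not state its splitting scheme, so stratification with an explicit seed was chosen for reproducibility and to guarantee both classes per fold |

Evaluation conventions: AUC is the rank-based Mann–Whitney statistic with
ties counted 0.5; summaries report the arithmetic mean and *sample*
(n−1) standard deviation across folds — the n−1 convention is the one
consistent with the reference per-fold aggregation rows embedded in
`datasets.reference_fold_metrics`.

## Numerical choices

- Significances below 1e-12 are treated as exactly 0 before
  normalization: entropy differences of order machine epsilon would
  otherwise be amplified into arbitrary weights by the simplex
  normalization. Genuine significances on realistic cohort sizes are
  many orders of magnitude larger.
- If *every* significance is 0 (all channels redundant or constant after
  dichotomization) the weights fall back to uniform with a warning
  rather than dividing by zero; similarly a combined BPA with no
  committed mass (all sources vacuous) yields decision value 0.5 with a
  warning. Both cases are unreachable in normal fitted operation but the
  functions are total.
- Mass assignments are renormalized after each combination step so the
  sum-to-one invariant holds to 1e-12 throughout chains; combination
  order is input order, and associativity/commutativity are asserted by
  test rather than assumed.
- Externally supplied weight vectors (e.g. published values rounded to 4
  decimals) are accepted within 1e-3 of the simplex and used exactly as
  given, because re-normalizing them would change reproduced third-party
  tables.
- Model JSON and prediction CSV files render floats at round-trip
  precision (`%.17g`); console output rounds to 4 decimals for
  readability. CSV parsing goes through correctly-rounded `float()`
  (pandas' fast parser can lose the last ulp).
- The embedded worked example reproduces its reference tables
  cell-by-cell with one caveat: the patient-2 SVM adjusted output prints
  as 0.2663 in the reference but equals 0.266184 when computed from the
  *printed* raw score and threshold — the reference tables were rendered
  from unrounded internal values. Comparisons against such printed
  tables therefore warrant a one-unit-in-the-last-digit band; the same
  propagation argument applies to re-aggregated fold summaries, whose
  inputs are printed at 3 decimals.

## Synthetic cohorts

`evidfuse.simulate.generate_cohort` emulates the statistical structure
the method assumes: a binary outcome with configurable prevalence
(default 0.30, a typical in-hospital MACE composite rate band for ACS
registries) and several score channels that are *graded* (continuous,
monotone in risk), *partially correlated* (all load on one shared
standard-normal latent, the common severity signal) and *individually
imperfect* (channel-specific Gaussian noise inside a logistic link). The
default four channels mimic SVM / L1-LR / CART probability outputs plus
a GRACE-like integer score mapped affinely into the range 2–258
(rounding half away from zero, clipping at the bounds); signal strengths
default to values placing single-channel AUCs roughly in the 0.63–0.71
band observed for real base models — a documentation aid, not a
guarantee. Everything is deterministic given the seed.

What the generator does **not** emulate: miscalibration patterns of real
learners, label noise and ambiguous outcome adjudication, non-Gaussian
dependence between models (e.g. tree models agreeing on plateaus),
missingness, and cohort shift. Tests passing on synthetic cohorts
therefore demonstrate that the pipeline recovers weights and fuses
evidence correctly under its own assumptions, not that it attains any
particular performance on real EHR data.

## Known limitations

- The method consumes model *outputs* only; base-model training and the
  clinical computation of GRACE are out of scope.
- Weights derive from dichotomized agreement, so a model informative
  only in its extreme tails can be under-weighted.
- Dempster's rule is undefined under total conflict (K = 1); this
  requires two sources with zero ignorance mass disagreeing, impossible
  for weighted BPAs with finite weights, but the combiner raises a clear
  error for hand-constructed masses.
- Reference headline results on the original 2930-patient hospital
  cohort (ensemble AUC 0.715) are not reproducible here — that dataset
  is not public; only the aggregation arithmetic over the published
  per-fold values and the method's internal consistency are verified.
- The acceptance checks and default tests run the cross-validated
  synthetic experiments at n = 2000 with 5 folds, the package's standard
  demonstration scale.
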