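# Methods

## The validation problem

A verbal autopsy (VA) assigns a cause of death from a structured caregiver
interview. Validating VA for neonatal deaths means comparing, case by case,
the VA-derived primary cause against a reference cause assigned from
hospital clinical, radiology and laboratory records, over a cohort in which
both are available. `neoval` models the three stages of that comparison —
cause assignment, reviewer adjudication, accuracy estimation — plus a
synthetic-cohort generator that makes the whole pipeline testable without
patient data.

## Cause taxonomy and assignment hierarchy

Causes form a fixed ten-category taxonomy (congenital anomalies, injuries,
birth asphyxia, tetanus, sepsis, meningitis, pneumonia, diarrhea,
prematurity complications, other specific cause) plus two terminal labels:
`unexplained` (no case definition met) and `unclassifiable` (three reviewers
disagreed). Clinical case definitions are *inputs* — boolean eligibility
flags per cause — not something the package evaluates; real studies apply
standardized definitions that are not machine-readable here.

Assignment is deterministic: the case's stratum is chosen by age at death
(< 3 vs ≥ 3 completed days; "3 days" means the third completed day, so the
young band is days 0–2) and gestation (< 32 vs ≥ 32 weeks, with exactly 32.0
in the upper band), and the first cause in the stratum's ordered list whose
flag is true wins. Birth asphyxia carries an "if age < 7 days" condition in
the ≥ 3-day strata. The serious-infection slot is a composite that fires on
the first eligible member in the fixed order sepsis > meningitis >
pneumonia > diarrhea; a member-level label is always returned because
mortality fractions are reported per member.

Three gestation thresholds coexist deliberately and are separate constants:

| constant | value | role |
|---|---|---|
| stratum boundary | 32 wk | which ordered list applies |
| collapse cutoff | 34 wk | optional asphyxia → prematurity relabeling |
| prematurity definition | 33 wk | CSMF reporting / generator coherence |

They are not reconciled into one number because they serve different roles
in the procedure; unifying them would silently change results.

The collapse rule is **off by default**: it is an alternative convention
(asphyxia is hard to diagnose in very preterm babies), not part of the core
hierarchy. Missing gestation is a policy decision, not an imputation: the
default refuses to assign (`error`), and `assume_ge32`/`assume_lt32` place
the case in a band without inventing a value. Under `assume_ge32` the
collapse rule is not applied to a missing-gestation case (the band statement
says nothing about the 34-week cutoff); under `assume_lt32` it is.

## Adjudication

Each death is coded by two independent, mutually blinded reviewers; on
disagreement an arbiter reviews the case. The final cause is the one two of
the three agree on; if all three differ the death is `unclassifiable`. The
arbiter has no unilateral override — a third distinct opinion cannot become
the final cause. Consensus percentages are reported half-up to one decimal,
matching standard table formatting; full-precision proportions are used
everywhere internally.

## Accuracy estimation

With the reference diagnosis as truth and VA as the test, a case is positive
for a target cause iff its final label equals that cause (any member, for
the severe-infection composite). `unexplained` and `unclassifiable` count as
negative for every specific cause, so each per-cause 2×2 table totals the
full number of paired cases.

Confidence intervals use the **Wilson score interval** (default 95%),
computed via `statsmodels` and cross-checked in the tests against the closed
form. Wilson is pinned because it reproduces the published validation
tables this package's tests are anchored to, where a Wald interval is off by
up to 0.7 percentage points; it is also the better-behaved interval near 0
and 1. A statistic with a zero denominator is reported as undefined
(`None`/NaN with a warning), never as 0.

Per-cause association is tested with the Pearson chi-square on the 2×2
table, without continuity correction by default (a "simple" chi-square);
Yates correction is a flag. Degenerate margins raise for the scalar
operation; the multi-cause table reports NaN for that cause and continues,
since a rare cause can legitimately receive zero VA calls in a small cohort.
Expected cells below 5 produce a warning only. No multiple-testing
adjustment is applied — the analysis reports five pre-specified causes, not
a screen.

## Synthetic cohorts

The generator emulates the structure of a two-hospital neonatal validation
study of 626 deaths. Its defaults are the study conditions:

* **CSMF profile** — reference-cause probabilities from the observed cause
  counts (prematurity 224/626, asphyxia 176/626, sepsis 162/626, …).
* **Confusion matrix** — the VA cause is drawn from a row-stochastic matrix
  whose diagonal is the observed per-cause sensitivity (asphyxia 147/176,
  prematurity 209/224, congenital 8/14, tetanus 6/9, each infection member
  138/175). Off-diagonal mass is spread proportionally to the target cause's
  CSMF — a misdiagnosis lands on a common cause more often than a rare one —
  because only marginal false-positive counts, not a full confusion matrix,
  are observable from published tables. The two residual categories
  (`unexplained`, `other_specific`) get a diagonal of 0.5, a deliberately
  noisy default for categories with no published accuracy data.
* **Reviewer process** — primary reviewers agree with probability 494/626
  (hospital) or 461/626 (VA). In a discrepant pair, a randomly chosen
  reviewer carries the case's label; the arbiter sides with that reviewer
  with probability 127/132 (hospital) or 146/165 (VA) and otherwise returns
  a third opinion, which adjudicates to `unclassifiable`. Reviewer errors
  are independent across reviewers and cases; no correlation structure is
  modeled.
* **Covariates** — age at death ~ N(5.9, 6.7²) days resampled (never
  clipped) into 0–28 completed days; gestation ~ N(33.6, 4.1²) weeks on
  [22, 44]; 59.6% male; birth weight ~ N(2398.6, 1578.4²) g on [300, 6000].
  Covariates are independent of cause except where the hierarchy forces
  coherence: tetanus needs age ≥ 3 days, asphyxia age < 7 days, an infection
  cause cannot occur in the (< 3 days, < 32 weeks) stratum, "other specific"
  needs ≥ 32 weeks, and prematurity deaths get gestation < 33 weeks.
  Draws violating a constraint are rejected and resampled. Gestation is
  always present in synthetic cohorts: the default missing-gestation policy
  refuses to impute, so injecting missingness would only exercise the error
  path.

Eligibility flags are constructed so the hierarchy reproduces the intended
reference cause exactly: the intended cause's flag is true, every
higher-priority flag in the case's stratum is false, and lower-priority
flags are set true with probability 0.25 (they cannot change the first
match, but make the flag patterns less artificial).

**What the labels mean.** The `labels` table carries the drawn reference and
VA causes — the analysis dataset. Reviewer noise is layered *around* those
labels: adjudicating the generated review tables recovers them except for
the small all-three-differ fraction (~0.8% hospital, ~3% VA under the
defaults), which adjudicates to `unclassifiable`. The published tables this
emulates carry the same tension — the adjudication accounting shows
unclassifiable cases while every death in the accuracy and CSMF tables has a
specific cause — and the generator resolves it the same way: accuracy and
CSMF are computed on fully labeled pairs, while the adjudication summary
reflects the reviewer process. Pushing the unclassifiable fraction into the
accuracy denominators instead would deflate every sensitivity by ~3%
relative to the configured diagonals.

**What passing tests show.** Parameter recovery at n = 10,000 (each
per-cause sensitivity within 2 Monte-Carlo standard errors of its configured
diagonal, CSMFs within 1.5 points, consensus rates within 1 point) shows the
pipeline is an unbiased estimator *of the generator's own parameters*. The
generator does not model interview content, recall bias, correlated reviewer
errors, cause-dependent covariates beyond the coherence constraints, or
missing data — so passing says nothing about VA's accuracy in a new
population, only that the estimation machinery is correct.

## Numerical choices

* Percentages are rounded half away from zero to one decimal at the
  reporting boundary only (`round_half_up`); all arithmetic is at full
  precision.
* Problem sizes: the exhaustive hierarchy check enumerates all four strata ×
  all eligibility combinations × all ages (≈ 42,000 cases); stochastic
  checks use one 10,000-death cohort and 5,000 Monte-Carlo replicates for
  interval coverage — sizes at which binomial standard errors are several
  times smaller than the tolerances being checked.
* Seeds: every stochastic component takes an explicit seed through
  `numpy.random.default_rng`; identical configs and seeds give byte-identical
  output tables.

## Limitations

* Case definitions are opaque flags; the package cannot detect internally
  inconsistent flag patterns beyond hierarchy order.
* The reference standard is treated as error-free truth; hospital-record
  misdiagnosis is not modeled.
* `unclassifiable` handling in downstream denominators follows the
  negative-label convention; alternatives (exclusion, redistribution) are
  not implemented.
* Later VA-literature metrics (CSMF accuracy, chance-corrected concordance,
  kappa) and ROC analysis are out of scope.
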