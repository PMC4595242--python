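# neoval

Validation of verbal-autopsy (VA) causes of neonatal death against a
hospital reference standard.

In settings without routine death certification, the cause of a newborn's
death is often inferred from a structured caregiver interview — a verbal
autopsy. Before VA-derived cause distributions can steer health policy, the
instrument has to be validated against deaths for which a clinical reference
diagnosis exists. `neoval` implements that validation pipeline for
biostatisticians and epidemiologists working on neonatal mortality:

* **Hierarchical cause assignment** — a single primary cause from a fixed
  ten-cause taxonomy, chosen as the first eligible cause in an ordered list
  that depends on age at death (< 3 vs ≥ 3 completed days) and gestation
  (< 32 vs ≥ 32 weeks), with an "if age < 7 days" condition on birth
  asphyxia in the older strata and an optional rule collapsing asphyxia into
  prematurity complications below 34 weeks.
* **Dual-reviewer/arbiter adjudication** — two blinded reviewers per death;
  disagreements go to a third senior reviewer, and the cause two of the
  three agree on is assigned (`unclassifiable` when all three differ).
* **Diagnostic accuracy and CSMF** — per-cause 2×2 tables of VA against the
  reference standard, with sensitivity = TP/(TP+FN), specificity =
  TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN), each with a 95% Wilson
  score interval

  p̂ ± z²/2n ± z·√(p̂(1−p̂)/n + z²/4n²) , all over 1 + z²/n ,

  plus cause-specific mortality fractions (CSMF), overall agreement, and a
  Pearson chi-square test per cause (Yates correction optional).
* **Synthetic cohorts** — a generator producing case records, reviewer
  tables and paired labels with a configurable CSMF profile, VA confusion
  structure, reviewer agreement rates and covariate distributions, so the
  whole pipeline is reproducible without access to patient data.

## Worked example

`examples/03_diagnostic_accuracy.py` evaluates VA for birth asphyxia from a
published 2×2 table (147 true positives, 41 false positives, 409 true
negatives, 29 false negatives over 626 deaths):

```
sensitivity   83.5%  (95% CI 77.3-88.3)
specificity   90.9%  (95% CI 87.9-93.2)
ppv           78.2%  (95% CI 71.8-83.5)
npv           93.4%  (95% CI 90.7-95.4)

chi-square = 333.4, p = 1.76e-74  (VA and reference diagnoses are strongly associated)
```

VA found 83.5% of asphyxia deaths and correctly ruled out 90.9% of
non-asphyxia deaths; a positive VA call was right 78.2% of the time.

`examples/04_synthetic_study.py` simulates a 626-death cohort under the
default study profile and runs the full pipeline (seed 42):

```
reviewer consensus: hospital 78.8%, VA 73.5%
overall VA/reference agreement: 82.4%

cause                        CSMF ref  CSMF va   sens    spec
congenital_anomalies            1.9%     1.9%   83.3%   99.7%
prematurity_complications      33.5%    37.9%   91.4%   89.2%
birth_asphyxia                 30.4%    29.2%   83.2%   94.3%
tetanus                         1.8%     1.6%   72.7%   99.7%
severe_infection               28.1%    26.4%   78.4%   93.8%
```

The CSMF columns show how closely the VA cause distribution tracks the
reference one; `severe_infection` groups sepsis, meningitis, pneumonia and
diarrhea for accuracy reporting.

The remaining examples cover hierarchy assignment (`01`) and adjudication
(`02`). A thin CLI wraps the same functions:

```bash
neoval run --out study/ --seed 42 --n-cases 626        # end-to-end
neoval assign --input cases.csv --output assigned.csv  # stage by stage
neoval adjudicate --input reviews.csv --output final.csv --summary s.json
neoval validate --reference ref.csv --va va.csv --out report/
```

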