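"""Simulate a full validation study and run the end-to-end pipeline.

Generates a 626-death paired cohort under the default study profile
(prematurity ~36%, asphyxia ~28%, sepsis ~26% of reference causes; VA
misclassification calibrated to the observed per-cause sensitivities;
reviewer consensus ~78.9% hospital, ~73.6% VA), then assigns reference
causes through the hierarchy, adjudicates both review tables and compares
VA against the reference standard.
"""
from neoval import default_study_config
from neoval.pipeline import run_synthetic_study

result = run_synthetic_study(default_study_config(n_cases=626, seed=42))
report = result.validation.report

adj = report["adjudication"]
print(f"reviewer consensus: hospital {adj['hospital']['pct_consensus']}%, "
      f"VA {adj['verbal_autopsy']['pct_consensus']}%")
print(f"overall VA/reference agreement: {report['overall_agreement_pct']}%\n")

INFECTION_MEMBERS = ("sepsis", "meningitis", "pneumonia", "diarrhea")
ref_csmf = {r["cause"]: r["pct"] for r in report["csmf"]["reference"]}
va_csmf = {r["cause"]: r["pct"] for r in report["csmf"]["va"]}


def csmf_of(table: dict, cause: str) -> float:
    if cause == "severe_infection":  # composite: sum its member causes
        return sum(table.get(m, 0.0) for m in INFECTION_MEMBERS)
    return table.get(cause, 0.0)


print("cause                        CSMF ref  CSMF va   sens    spec")
for row in report["accuracy"]:
    cause = row["cause"]
    print(f"{cause:28s} {csmf_of(ref_csmf, cause):6.1f}% {csmf_of(va_csmf, cause):7.1f}% "
          f"{row['sensitivity']['pct']:6.1f}% {row['specificity']['pct']:6.1f}%")
print("\n(sens/spec estimate how often VA finds a reference-positive cause "
      "and rules out a reference-negative one)")
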