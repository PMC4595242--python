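"""End-to-end orchestration: assign -> adjudicate -> validate -> report."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import metrics
from .adjudication import AdjudicationSummary, round_half_up, adjudicate_table, summarize_adjudication, AdjudicatedDiagnosis, Resolution
from .causes import Cause
from .simulate import SimulatedCohort, SimulationConfig, simulate_cohort


def summary_as_dict(s: AdjudicationSummary) -> dict:
    return {
        "n_reviewed": s.n_reviewed,
        "n_consensus": s.n_consensus,
        "n_discrepant": s.n_discrepant,
        "n_arbiter_agrees_one": s.n_arbiter_agrees_one,
        "n_all_differ": s.n_all_differ,
        "pct_consensus": s.pct_consensus,
    }


def summarize_final_table(final: pd.DataFrame) -> AdjudicationSummary:
    """Adjudication summary from an adjudicated table (final_cause/resolution)."""
    diags = [
        AdjudicatedDiagnosis(
            str(r.case_id), Cause.parse(r.final_cause), Resolution(r.resolution)
        )
        for r in final.itertuples(index=False)
    ]
    return summarize_adjudication(diags)


def build_report(
    pairs: pd.DataFrame,
    accuracy: pd.DataFrame,
    *,
    adjudication: Optional[dict] = None,
    ndigits: int = 1,
) -> dict:
    """Assemble the machine-readable twin of the three result tables."""
    csmf_ref = metrics.csmf(pairs["reference_cause"])
    csmf_va = metrics.csmf(pairs["va_cause"])

    def csmf_rows(df: pd.DataFrame) -> list[dict]:
        return [
            {
                "cause": r.cause,
                "count": int(r.count),
                "pct": round_half_up(100 * r.fraction, ndigits),
            }
            for r in df.itertuples(index=False)
        ]

    acc_rows = []
    for r in accuracy.itertuples(index=False):
        row = {"cause": r.cause, "tp": int(r.tp), "fp": int(r.fp), "tn": int(r.tn), "fn": int(r.fn)}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            point = getattr(r, name)
            lo = getattr(r, f"{name}_lo")
            hi = getattr(r, f"{name}_hi")
            row[name] = {
                "pct": None if pd.isna(point) else round_half_up(100 * point, ndigits),
                "ci_lo": None if pd.isna(lo) else round_half_up(100 * lo, ndigits),
                "ci_hi": None if pd.isna(hi) else round_half_up(100 * hi, ndigits),
            }
        row["chi2"] = round(float(r.chi2), 3)
        row["p_value"] = float(r.p_value)
        acc_rows.append(row)

    report = {
        "n_cases": int(len(pairs)),
        "overall_agreement_pct": round_half_up(
            100 * metrics.overall_agreement(pairs), ndigits
        ),
        "csmf": {"reference": csmf_rows(csmf_ref), "va": csmf_rows(csmf_va)},
        "accuracy": acc_rows,
    }
    if adjudication is not None:
        report["adjudication"] = adjudication
    return report


@dataclass
class ValidationResult:
    pairs: pd.DataFrame
    accuracy: pd.DataFrame
    csmf_reference: pd.DataFrame
    csmf_va: pd.DataFrame
    report: dict


def run_validation(
    reference: pd.DataFrame,
    va: pd.DataFrame,
    *,
    targets: Sequence[metrics.TargetLike] = metrics.DEFAULT_TARGETS,
    confidence: float = 0.95,
    continuity_correction: bool = False,
    adjudication: Optional[dict] = None,
) -> ValidationResult:
    """Compare adjudicated VA diagnoses against the reference standard."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    pairs = metrics.paired_labels(reference, va)
    accuracy = metrics.accuracy_table(
        pairs, targets, confidence=confidence, continuity_correction=continuity_correction
    )
    return ValidationResult(
        pairs=pairs,
        accuracy=accuracy,
        csmf_reference=metrics.csmf(pairs["reference_cause"]),
        csmf_va=metrics.csmf(pairs["va_cause"]),
        report=build_report(pairs, accuracy, adjudication=adjudication),
    )


@dataclass
class StudyResult:
    cohort: SimulatedCohort
    assigned: pd.DataFrame  # hierarchy output on the synthetic case records
    hospital_final: pd.DataFrame
    va_final: pd.DataFrame
    validation: ValidationResult


def run_synthetic_study(
    config: SimulationConfig,
    *,
    confidence: float = 0.95,
    continuity_correction: bool = False,
) -> StudyResult:
    """Simulate a cohort and push it through the whole pipeline.

    Reference labels come from the assignment hierarchy applied to the
    generated eligibility flags; VA labels are the cohort's analysis labels.
    Both review tables are adjudicated so the consensus accounting is part of
    the report.
    """
    from .io import CASE_COLUMNS  # noqa: F401  (documented schema lives in io)
    from .hierarchy import CaseRecord
    from .causes import ASSIGNABLE

    cohort = simulate_cohort(config)

    records = []
    for row in cohort.cases.itertuples(index=False):
        d = row._asdict()
        records.append(
            CaseRecord(
                case_id=d["case_id"],
                age_at_death_days=int(d["age_at_death_days"]),
                gestation_weeks=float(d["gestation_weeks"]),
                sex=d["sex"],
                birth_weight_g=float(d["birth_weight_g"]),
                eligibility={c: bool(d[f"elig_{c.value}"]) for c in ASSIGNABLE},
                source=d["source"],
            )
        )
    from .hierarchy import assign_cases

    assigned = assign_cases(records)
    hospital_final = adjudicate_table(cohort.hospital_reviews)
    va_final = adjudicate_table(cohort.va_reviews)
    adjudication = {
        "hospital": summary_as_dict(summarize_final_table(hospital_final)),
        "verbal_autopsy": summary_as_dict(summarize_final_table(va_final)),
    }

    reference = assigned.rename(columns={"assigned_cause": "final_cause"})[
        ["case_id", "final_cause"]
    ]
    va = cohort.labels.rename(columns={"va_cause": "final_cause"})[
        ["case_id", "final_cause"]
    ]
    validation = run_validation(
        reference,
        va,
        confidence=confidence,
        continuity_correction=continuity_correction,
        adjudication=adjudication,
    )
    return StudyResult(
        cohort=cohort,
        assigned=assigned,
        hospital_final=hospital_final,
        va_final=va_final,
        validation=validation,
    )
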