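"""Dual-reviewer / arbiter adjudication of cause-of-death calls.

Two reviewers code each death independently and blinded to each other.  When
they agree, that cause stands (consensus).  When they disagree, a third
senior reviewer arbitrates: the cause on which two of the three agree is
assigned, and when all three differ the death is labeled unclassifiable.
The arbiter never overrides both reviewers with a cause of their own.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .causes import Cause


class Resolution(str, Enum):
    CONSENSUS = "consensus"
    ARBITER_AGREES_R1 = "arbiter_agrees_r1"
    ARBITER_AGREES_R2 = "arbiter_agrees_r2"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class AdjudicatedDiagnosis:
    case_id: str
    final_cause: Cause
    resolution: Resolution


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching report-table formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def resolve_case(
    r1: Cause,
    r2: Cause,
    arbiter: Optional[Cause] = None,
    *,
    case_id: str = "",
) -> AdjudicatedDiagnosis:
    """Resolve one case from two primary reviews and an optional arbiter.

    The arbiter is required exactly when the reviewers disagree.  An arbiter
    supplied alongside agreeing reviewers is ignored with a warning.
    """
    if r1 == r2:
        if arbiter is not None:
            warnings.warn(
                f"case {case_id!r}: reviewers agree; arbiter assignment ignored"
            )
        return AdjudicatedDiagnosis(case_id, r1, Resolution.CONSENSUS)
    if arbiter is None:
        raise ValueError(
            f"case {case_id!r}: reviewers disagree ({r1.value} vs {r2.value}) "
            "but no arbiter assignment was supplied"
        )
    if arbiter == r1:
        return AdjudicatedDiagnosis(case_id, r1, Resolution.ARBITER_AGREES_R1)
    if arbiter == r2:
        return AdjudicatedDiagnosis(case_id, r2, Resolution.ARBITER_AGREES_R2)
    return AdjudicatedDiagnosis(case_id, Cause.UNCLASSIFIABLE, Resolution.UNCLASSIFIABLE)


@dataclass(frozen=True)
class AdjudicationSummary:
    """Consensus/discrepancy accounting over a reviewed case set."""

    n_reviewed: int
    n_consensus: int
    n_discrepant: int
    n_arbiter_agrees_one: int
    n_all_differ: int
    pct_consensus: float

    def __post_init__(self) -> None:
        assert self.n_reviewed == self.n_consensus + self.n_discrepant
        assert self.n_discrepant == self.n_arbiter_agrees_one + self.n_all_differ


def summarize_adjudication(
    diagnoses: Iterable[AdjudicatedDiagnosis],
) -> AdjudicationSummary:
    """Count resolution paths; consensus percentage reported to one decimal."""
    diags = list(diagnoses)
    if not diags:
        raise ValueError("no adjudicated diagnoses supplied")
    ids = [d.case_id for d in diags]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate case ids: {dups}")
    n_consensus = sum(d.resolution is Resolution.CONSENSUS for d in diags)
    n_all_differ = sum(d.resolution is Resolution.UNCLASSIFIABLE for d in diags)
    n_arbiter = len(diags) - n_consensus - n_all_differ
    return AdjudicationSummary(
        n_reviewed=len(diags),
        n_consensus=n_consensus,
        n_discrepant=len(diags) - n_consensus,
        n_arbiter_agrees_one=n_arbiter,
        n_all_differ=n_all_differ,
        pct_consensus=round_half_up(100.0 * n_consensus / len(diags), 1),
    )


def adjudicate_table(reviews: pd.DataFrame) -> pd.DataFrame:
    """Adjudicate a long-format review table.

    Expects columns ``case_id``, ``reviewer_id``, ``round`` (primary/arbiter)
    and ``cause``; enforces exactly two primary reviews from distinct
    reviewers per case and at most one arbiter review.  Returns one row per
    case with ``final_cause`` and ``resolution``.
    """
    required = {"case_id", "reviewer_id", "round", "cause"}
    missing = required - set(reviews.columns)
    if missing:
        raise ValueError(f"review table missing columns: {sorted(missing)}")

    out = []
    for case_id, grp in reviews.groupby("case_id", sort=True):
        primary = grp[grp["round"] == "primary"]
        arb = grp[grp["round"] == "arbiter"]
        if len(primary) != 2 or primary["reviewer_id"].nunique() != 2:
            raise ValueError(
                f"case {case_id!r}: expected exactly two primary reviews from "
                f"distinct reviewers, got {len(primary)}"
            )
        if len(arb) > 1:
            raise ValueError(f"case {case_id!r}: more than one arbiter review")
        primary = primary.sort_values("reviewer_id")
        r1, r2 = (Cause.parse(c) for c in primary["cause"])
        arbiter = Cause.parse(arb["cause"].iloc[0]) if len(arb) == 1 else None
        if r1 == r2 and arbiter is not None:
            arbiter = None  # silently drop: agreement needs no arbiter
        d = resolve_case(r1, r2, arbiter, case_id=str(case_id))
        out.append(
            {
                "case_id": d.case_id,
                "final_cause": d.final_cause.value,
                "resolution": d.resolution.value,
            }
        )
    return pd.DataFrame(out, columns=["case_id", "final_cause", "resolution"])
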