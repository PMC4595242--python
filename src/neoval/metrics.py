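"""Diagnostic-accuracy and mortality-fraction metrics.

Per-cause 2x2 contingency tables of verbal-autopsy (VA) diagnoses against the
hospital reference standard, sensitivity/specificity/PPV/NPV with Wilson
score intervals, cause-specific mortality fractions (CSMF), overall
agreement, and Pearson chi-square comparison of each 2x2 table.

Conventions: the reference diagnosis is truth and the VA diagnosis is the
test.  A case is positive for a target cause iff its label equals that cause
(or any member, for the severe-infection composite); the terminal labels
``unexplained`` and ``unclassifiable`` are therefore negative for every
specific cause, which keeps every table's total equal to the number of paired
cases.  Proportions are kept at full precision; percentages in reports are
rounded half-up to one decimal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .adjudication import round_half_up
from .causes import SEVERE_INFECTION, Cause

TargetLike = Union[Cause, str, Sequence[Cause]]

#: Name used for the infection composite in tables and CLI output.
SEVERE_INFECTION_LABEL = "severe_infection"


def _target_set(target: TargetLike) -> tuple[str, frozenset[Cause]]:
    """Normalise a target spec to (label, set of member causes)."""
    if isinstance(target, Cause):
        return target.value, frozenset([target])
    if isinstance(target, str):
        if target.lower() == SEVERE_INFECTION_LABEL:
            return SEVERE_INFECTION_LABEL, frozenset(SEVERE_INFECTION)
        return _target_set(Cause.parse(target))
    members = frozenset(Cause.parse(c) if not isinstance(c, Cause) else c for c in target)
    if not members:
        raise ValueError("empty composite target")
    return "+".join(sorted(c.value for c in members)), members


def paired_labels(reference: pd.DataFrame, va: pd.DataFrame) -> pd.DataFrame:
    """Pair reference and VA final causes on case id.

    Both inputs need ``case_id`` and ``final_cause`` columns; the id universes
    must coincide exactly.  Returns one row per case with columns
    ``case_id``, ``reference_cause``, ``va_cause``.
    """
    for name, df in (("reference", reference), ("va", va)):
        missing = {"case_id", "final_cause"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
        if df["case_id"].duplicated().any():
            dups = sorted(df.loc[df["case_id"].duplicated(), "case_id"].astype(str))
            raise ValueError(f"duplicate case ids in {name} table: {dups}")
    ref_ids = set(reference["case_id"])
    va_ids = set(va["case_id"])
    if ref_ids != va_ids:
        only_ref = sorted(map(str, ref_ids - va_ids))[:10]
        only_va = sorted(map(str, va_ids - ref_ids))[:10]
        raise ValueError(
            f"case id mismatch: {len(ref_ids - va_ids)} only in reference "
            f"(e.g. {only_ref}), {len(va_ids - ref_ids)} only in va (e.g. {only_va})"
        )
    merged = reference.rename(columns={"final_cause": "reference_cause"}).merge(
        va.rename(columns={"final_cause": "va_cause"}), on="case_id"
    )
    merged["reference_cause"] = [Cause.parse(c).value for c in merged["reference_cause"]]
    merged["va_cause"] = [Cause.parse(c).value for c in merged["va_cause"]]
    return merged[["case_id", "reference_cause", "va_cause"]]


@dataclass(frozen=True)
class ContingencyCounts:
    """Per-cause 2x2 counts with the reference standard as truth."""

    cause: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def contingency(pairs: pd.DataFrame, target: TargetLike) -> ContingencyCounts:
    """Cross-tabulate one target cause (or composite) over paired labels."""
    label, members = _target_set(target)
    values = frozenset(c.value for c in members)
    ref_pos = pairs["reference_cause"].isin(values).to_numpy()
    va_pos = pairs["va_cause"].isin(values).to_numpy()
    return ContingencyCounts(
        cause=label,
        tp=int((ref_pos & va_pos).sum()),
        fp=int((~ref_pos & va_pos).sum()),
        tn=int((~ref_pos & ~va_pos).sum()),
        fn=int((ref_pos & ~va_pos).sum()),
    )


def score_interval(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion.

    Obtained by inverting the score test; well behaved at the boundaries
    (lower bound is exactly 0 at zero successes).
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside 0..{trials}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    lo, hi = proportion_confint(successes, trials, alpha=1 - confidence, method="wilson")
    if successes == 0:
        lo = 0.0
    if successes == trials:
        hi = 1.0
    return float(lo), float(hi)


@dataclass(frozen=True)
class ProportionEstimate:
    point: float
    lower: float
    upper: float
    successes: int
    trials: int

    def as_pct(self, ndigits: int = 1) -> tuple[float, float, float]:
        return tuple(
            round_half_up(100 * v, ndigits) for v in (self.point, self.lower, self.upper)
        )


@dataclass(frozen=True)
class AccuracyEstimate:
    """Sensitivity, specificity, PPV and NPV for one cause.

    A statistic whose denominator is zero is ``None`` (undefined), never 0.
    """

    cause: str
    sensitivity: Optional[ProportionEstimate]
    specificity: Optional[ProportionEstimate]
    ppv: Optional[ProportionEstimate]
    npv: Optional[ProportionEstimate]


def _estimate(
    successes: int, trials: int, confidence: float, what: str, cause: str
) -> Optional[ProportionEstimate]:
    if trials == 0:
        warnings.warn(f"{what} undefined for {cause!r}: zero denominator")
        return None
    lo, hi = score_interval(successes, trials, confidence)
    return ProportionEstimate(successes / trials, lo, hi, successes, trials)


def diagnostic_accuracy(
    counts: ContingencyCounts, confidence: float = 0.95
) -> AccuracyEstimate:
    """Compute the four accuracy statistics with score intervals."""
    c = counts
    return AccuracyEstimate(
        cause=c.cause,
        sensitivity=_estimate(c.tp, c.tp + c.fn, confidence, "sensitivity", c.cause),
        specificity=_estimate(c.tn, c.tn + c.fp, confidence, "specificity", c.cause),
        ppv=_estimate(c.tp, c.tp + c.fp, confidence, "PPV", c.cause),
        npv=_estimate(c.tn, c.tn + c.fn, confidence, "NPV", c.cause),
    )


def csmf(
    labels: Iterable[Union[Cause, str]],
    causes: Optional[Sequence[Cause]] = None,
) -> pd.DataFrame:
    """Cause-specific mortality fractions over a set of final labels.

    Returns a DataFrame with ``cause``, ``count`` and ``fraction`` columns
    (fractions at full precision; they sum to 1).  ``causes`` fixes the row
    order and forces zero-count rows; by default rows cover every label seen,
    in taxonomy order.
    """
    parsed = [c if isinstance(c, Cause) else Cause.parse(c) for c in labels]
    if not parsed:
        raise ValueError("no labels supplied")
    if causes is None:
        seen = set(parsed)
        causes = [c for c in Cause if c in seen]
    total = len(parsed)
    rows = [
        {"cause": c.value, "count": parsed.count(c), "fraction": parsed.count(c) / total}
        for c in causes
    ]
    return pd.DataFrame(rows, columns=["cause", "count", "fraction"])


def overall_agreement(pairs: pd.DataFrame) -> float:
    """Fraction of cases whose reference and VA labels are identical."""
    if len(pairs) == 0:
        raise ValueError("no paired cases")
    return float((pairs["reference_cause"] == pairs["va_cause"]).mean())


def chi_square_2x2(
    counts: ContingencyCounts, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of association on a per-cause 2x2 table.

    Optional Yates continuity correction; p-value from chi-square with 1 df.
    Degenerate margins (an empty row or column) raise; small expected cells
    (< 5) only warn, matching common epidemiological practice.
    """
    table = np.array([[counts.tp, counts.fn], [counts.fp, counts.tn]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate margin in 2x2 table for {counts.cause!r}")
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        warnings.warn(
            f"expected cell count below 5 for {counts.cause!r}; "
            "chi-square approximation may be poor"
        )
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


DEFAULT_TARGETS: tuple[TargetLike, ...] = (
    Cause.CONGENITAL_ANOMALIES,
    Cause.PREMATURITY_COMPLICATIONS,
    Cause.BIRTH_ASPHYXIA,
    Cause.TETANUS,
    SEVERE_INFECTION_LABEL,
)


def accuracy_table(
    pairs: pd.DataFrame,
    targets: Sequence[TargetLike] = DEFAULT_TARGETS,
    confidence: float = 0.95,
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Per-target accuracy summary over paired labels.

    One row per target cause/composite: 2x2 counts, the four accuracy
    statistics with interval bounds (full-precision proportions), and the
    chi-square statistic and p-value.
    """
    rows = []
    for target in targets:
        cc = contingency(pairs, target)
        acc = diagnostic_accuracy(cc, confidence)
        try:
            stat, p = chi_square_2x2(cc, continuity_correction)
        except ValueError as exc:  # degenerate margin: report NaN, keep going
            warnings.warn(str(exc))
            stat, p = float("nan"), float("nan")
        row = {"cause": cc.cause, "tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            est: Optional[ProportionEstimate] = getattr(acc, name)
            row[name] = est.point if est else np.nan
            row[f"{name}_lo"] = est.lower if est else np.nan
            row[f"{name}_hi"] = est.upper if est else np.nan
        row["chi2"] = stat
        row["p_value"] = p
        rows.append(row)
    return pd.DataFrame(rows)
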