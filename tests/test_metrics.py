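"""Contingency tables, Wilson intervals, CSMF, agreement and chi-square."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2, norm

from neoval import (
    Cause,
    ContingencyCounts,
    chi_square_2x2,
    contingency,
    csmf,
    diagnostic_accuracy,
    overall_agreement,
    paired_labels,
    round_half_up,
    score_interval,
)
from neoval.causes import SEVERE_INFECTION
from neoval.metrics import SEVERE_INFECTION_LABEL, accuracy_table

ALL_LABELS = [c.value for c in Cause]


def wilson_oracle(s, n, conf=0.95):
    """Closed-form Wilson score interval, independent of the implementation."""
    z = norm.ppf(1 - (1 - conf) / 2)
    p = s / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return center - half, center + half


def brute_force_contingency(pairs, members):
    tp = fp = tn = fn = 0
    for _, row in pairs.iterrows():
        ref = row["reference_cause"] in members
        va = row["va_cause"] in members
        tp += ref and va
        fp += (not ref) and va
        tn += (not ref) and (not va)
        fn += ref and (not va)
    return tp, fp, tn, fn


# --- pairing ---------------------------------------------------------------

def _diag(ids, labels):
    return pd.DataFrame({"case_id": ids, "final_cause": labels})


def test_paired_labels_matches_on_ids():
    ref = _diag(["a", "b"], ["sepsis", "tetanus"])
    va = _diag(["b", "a"], ["sepsis", "sepsis"])
    pairs = paired_labels(ref, va)
    assert len(pairs) == 2
    row = pairs.set_index("case_id").loc["b"]
    assert (row["reference_cause"], row["va_cause"]) == ("tetanus", "sepsis")


def test_paired_labels_rejects_id_mismatch_and_duplicates():
    ref = _diag(["a", "b"], ["sepsis", "sepsis"])
    with pytest.raises(ValueError, match="mismatch"):
        paired_labels(ref, _diag(["a", "c"], ["sepsis", "sepsis"]))
    with pytest.raises(ValueError, match="duplicate"):
        paired_labels(_diag(["a", "a"], ["sepsis", "sepsis"]), ref)


# --- contingency -----------------------------------------------------------

def test_contingency_tiny_fixture_against_brute_force(tiny_pairs):
    for target in [Cause.SEPSIS, Cause.PREMATURITY_COMPLICATIONS, SEVERE_INFECTION_LABEL]:
        members = (
            {c.value for c in SEVERE_INFECTION}
            if target == SEVERE_INFECTION_LABEL
            else {target.value}
        )
        cc = contingency(tiny_pairs, target)
        assert (cc.tp, cc.fp, cc.tn, cc.fn) == brute_force_contingency(tiny_pairs, members)
        assert cc.total == len(tiny_pairs)


def test_contingency_random_sets_against_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(10):
        n = int(rng.integers(1, 50))
        pairs = pd.DataFrame(
            {
                "case_id": [f"c{i}" for i in range(n)],
                "reference_cause": rng.choice(ALL_LABELS, n),
                "va_cause": rng.choice(ALL_LABELS, n),
            }
        )
        target = Cause(rng.choice(ALL_LABELS[:10]))
        cc = contingency(pairs, target)
        assert (cc.tp, cc.fp, cc.tn, cc.fn) == brute_force_contingency(
            pairs, {target.value}
        )


def test_perfect_test_has_no_errors(tiny_pairs):
    perfect = tiny_pairs.assign(va_cause=tiny_pairs["reference_cause"])
    cc = contingency(perfect, Cause.SEPSIS)
    assert cc.fp == 0 and cc.fn == 0


def test_composite_dominates_members(tiny_pairs):
    comp = contingency(tiny_pairs, SEVERE_INFECTION_LABEL)
    for member in SEVERE_INFECTION:
        assert comp.tp >= contingency(tiny_pairs, member).tp


def test_terminal_labels_count_negative(tiny_pairs):
    """Unexplained/unclassifiable never contribute positives for any cause."""
    cc = contingency(tiny_pairs, Cause.SEPSIS)
    # case c5 has reference unexplained, va sepsis: a false positive
    assert cc.fp >= 1
    assert cc.total == len(tiny_pairs)


# --- Wilson score interval -------------------------------------------------

@pytest.mark.parametrize(
    "s, n, lo, hi",
    [
        (147, 176, 0.773, 0.883),
        (209, 224, 0.892, 0.959),
    ],
)
def test_score_interval_reference_values(s, n, lo, hi):
    got = score_interval(s, n, 0.95)
    assert round(got[0], 3) == lo and round(got[1], 3) == hi


def test_score_interval_zero_successes_lower_bound_exactly_zero():
    lo, hi = score_interval(0, 10, 0.95)
    assert lo == 0.0 and 0 < hi < 1


def test_score_interval_rejects_bad_inputs():
    with pytest.raises(ValueError):
        score_interval(1, 0)
    with pytest.raises(ValueError):
        score_interval(5, 4)


@settings(max_examples=200, derandomize=True)
@given(n=st.integers(1, 1000), frac=st.floats(0, 1), conf=st.sampled_from([0.9, 0.95, 0.99]))
def test_score_interval_matches_closed_form(n, frac, conf):
    s = int(round(frac * n))
    lo, hi = score_interval(s, n, conf)
    olo, ohi = wilson_oracle(s, n, conf)
    assert lo == pytest.approx(max(olo, 0.0), abs=1e-9)
    assert hi == pytest.approx(min(ohi, 1.0), abs=1e-9)
    assert 0 <= lo <= s / n <= hi <= 1


# --- accuracy --------------------------------------------------------------

def test_diagnostic_accuracy_asphyxia_row():
    acc = diagnostic_accuracy(ContingencyCounts("birth_asphyxia", 147, 41, 409, 29))
    assert acc.sensitivity.as_pct()[0] == 83.5
    assert acc.specificity.as_pct()[0] == 90.9
    assert acc.ppv.as_pct()[0] == 78.2
    assert acc.npv.as_pct()[0] == 93.4
    for est in (acc.sensitivity, acc.specificity, acc.ppv, acc.npv):
        assert est.lower <= est.point <= est.upper


def test_diagnostic_accuracy_perfect_test():
    acc = diagnostic_accuracy(ContingencyCounts("x", 5, 0, 7, 0))
    assert acc.sensitivity.point == 1.0 and acc.specificity.point == 1.0


def test_diagnostic_accuracy_zero_denominator_is_undefined_not_zero():
    with pytest.warns(UserWarning, match="sensitivity undefined"):
        acc = diagnostic_accuracy(ContingencyCounts("x", 0, 3, 7, 0))
    assert acc.sensitivity is None
    assert acc.specificity is not None


# --- CSMF ------------------------------------------------------------------

def test_csmf_fractions_sum_to_one():
    labels = ["sepsis"] * 3 + ["tetanus"] * 1
    table = csmf(labels)
    assert table["count"].sum() == 4
    assert table["fraction"].sum() == pytest.approx(1.0)
    assert table.set_index("cause").loc["sepsis", "fraction"] == pytest.approx(0.75)


def test_csmf_single_cause_is_100_percent():
    table = csmf(["sepsis"] * 5, causes=[Cause.SEPSIS, Cause.TETANUS])
    by = table.set_index("cause")
    assert by.loc["sepsis", "fraction"] == 1.0
    assert by.loc["tetanus", "count"] == 0


def test_csmf_study_counts():
    labels = ["prematurity_complications"] * 224 + ["other_specific"] * 402
    table = csmf(labels).set_index("cause")
    assert round_half_up(100 * table.loc["prematurity_complications", "fraction"]) == 35.8


# --- agreement and chi-square ----------------------------------------------

def test_overall_agreement(tiny_pairs):
    assert overall_agreement(tiny_pairs) == pytest.approx(2 / 6)
    perfect = tiny_pairs.assign(va_cause=tiny_pairs["reference_cause"])
    assert overall_agreement(perfect) == 1.0
    discordant = tiny_pairs.assign(va_cause=["tetanus"] * 6)
    assert overall_agreement(discordant) < 0.5


def test_chi_square_independent_table_is_zero():
    stat, p = chi_square_2x2(ContingencyCounts("x", 10, 10, 10, 10))
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi_square_matches_textbook_formula():
    a, b, c, d = 147, 29, 41, 409  # tp, fn, fp, tn
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    stat, p = chi_square_2x2(ContingencyCounts("birth_asphyxia", a, c, d, b))
    assert stat == pytest.approx(expected)
    assert p == pytest.approx(chi2.sf(expected, df=1))


def test_chi_square_yates_shrinks_statistic():
    cc = ContingencyCounts("x", 20, 5, 30, 10)
    plain, _ = chi_square_2x2(cc, continuity_correction=False)
    corrected, _ = chi_square_2x2(cc, continuity_correction=True)
    assert corrected < plain


def test_chi_square_degenerate_margin_errors():
    # VA never calls the cause: the test-positive column is empty
    with pytest.raises(ValueError, match="degenerate"):
        chi_square_2x2(ContingencyCounts("x", 0, 0, 40, 20))
    # reference never positive: an empty truth row
    with pytest.raises(ValueError, match="degenerate"):
        chi_square_2x2(ContingencyCounts("x", 0, 12, 40, 0))


def test_chi_square_small_expected_cells_warn():
    with pytest.warns(UserWarning, match="below 5"):
        chi_square_2x2(ContingencyCounts("x", 2, 1, 30, 1))


# --- accuracy table invariants ---------------------------------------------

def test_accuracy_table_count_conservation(tiny_pairs):
    table = accuracy_table(tiny_pairs, targets=[Cause.SEPSIS, Cause.TETANUS])
    totals = table[["tp", "fp", "tn", "fn"]].sum(axis=1)
    assert (totals == len(tiny_pairs)).all()
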