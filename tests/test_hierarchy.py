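"""Hierarchy assignment: stratum boundaries, ordered first-match, collapse rule."""
import pytest
from hypothesis import given, settings, strategies as st

from neoval import (
    ASSIGNABLE,
    CaseRecord,
    Cause,
    MissingGestationPolicy,
    assign_primary_cause,
    stratum_of,
)
from neoval.hierarchy import AgeBand, GestationBand

# Independent transcription of the four stratum lists, used as a brute-force
# first-match oracle.  "<7" marks the asphyxia age condition.
ORACLE_LISTS = {
    ("lt3", "lt32"): ["congenital_anomalies", "injuries", "birth_asphyxia",
                      "prematurity_complications"],
    ("ge3", "lt32"): ["congenital_anomalies", "injuries", "birth_asphyxia<7",
                      "tetanus", "sepsis", "meningitis", "pneumonia", "diarrhea",
                      "prematurity_complications"],
    ("lt3", "ge32"): ["congenital_anomalies", "injuries", "birth_asphyxia",
                      "sepsis", "meningitis", "pneumonia", "diarrhea",
                      "prematurity_complications", "other_specific"],
    ("ge3", "ge32"): ["congenital_anomalies", "injuries", "birth_asphyxia<7",
                      "tetanus", "sepsis", "meningitis", "pneumonia", "diarrhea",
                      "prematurity_complications", "other_specific"],
}


def oracle_assign(age: int, gestation: float, flags: dict[str, bool]) -> str:
    key = ("lt3" if age < 3 else "ge3", "lt32" if gestation < 32 else "ge32")
    for item in ORACLE_LISTS[key]:
        name, lt7 = (item[:-2], True) if item.endswith("<7") else (item, False)
        if flags.get(name, False) and (not lt7 or age < 7):
            return name
    return "unexplained"


def make_record(age, gestation, flags, case_id="x"):
    return CaseRecord(
        case_id=case_id,
        age_at_death_days=age,
        gestation_weeks=gestation,
        eligibility={Cause.parse(k): v for k, v in flags.items()},
    )


@pytest.mark.parametrize(
    "age, gestation, age_band, gest_band",
    [
        (2, 30, AgeBand.LT3_DAYS, GestationBand.LT32_WEEKS),
        (3, 32, AgeBand.GE3_DAYS, GestationBand.GE32_WEEKS),  # both boundaries
        (10, 36, AgeBand.GE3_DAYS, GestationBand.GE32_WEEKS),
        (0, 31.9, AgeBand.LT3_DAYS, GestationBand.LT32_WEEKS),
        (28, 25, AgeBand.GE3_DAYS, GestationBand.LT32_WEEKS),
    ],
)
def test_stratum_boundaries(age, gestation, age_band, gest_band):
    s = stratum_of(age, gestation)
    assert (s.age_band, s.gestation_band) == (age_band, gest_band)


def test_missing_gestation_policies():
    with pytest.raises(ValueError, match="missing"):
        stratum_of(5, None)
    assert stratum_of(5, None, missing_gestation="assume_ge32").gestation_band is GestationBand.GE32_WEEKS
    assert stratum_of(5, None, missing_gestation=MissingGestationPolicy.ASSUME_LT32).gestation_band is GestationBand.LT32_WEEKS


@pytest.mark.parametrize(
    "age, gestation, flags, collapse, expected",
    [
        # very preterm early death: prematurity is rank 4 after congenital/injuries/asphyxia
        (1, 30, {"congenital_anomalies": False, "injuries": False,
                 "birth_asphyxia": False, "prematurity_complications": True},
         False, Cause.PREMATURITY_COMPLICATIONS),
        # asphyxia carries "if age < 7 days" in the older strata, so tetanus wins
        (10, 36, {"birth_asphyxia": True, "tetanus": True}, False, Cause.TETANUS),
        # collapse relabels asphyxia below 34 weeks
        (1, 33, {"birth_asphyxia": True}, True, Cause.PREMATURITY_COMPLICATIONS),
        # no criteria met
        (4, 38, {}, False, Cause.UNEXPLAINED),
        # infection composite: sepsis outranks pneumonia within the slot
        (5, 36, {"pneumonia": True, "sepsis": True}, False, Cause.SEPSIS),
        # asphyxia has no age condition in the <3-day strata
        (1, 30, {"birth_asphyxia": True, "prematurity_complications": True},
         False, Cause.BIRTH_ASPHYXIA),
    ],
)
def test_assignment_examples(age, gestation, flags, collapse, expected):
    a = assign_primary_cause(make_record(age, gestation, flags), collapse_lt34=collapse)
    assert a.cause is expected
    assert a.collapse_applied == (collapse and expected is Cause.PREMATURITY_COMPLICATIONS
                                  and flags.get("birth_asphyxia", False))


def test_collapse_not_applied_at_or_above_34_weeks():
    a = assign_primary_cause(make_record(1, 34.0, {"birth_asphyxia": True}), collapse_lt34=True)
    assert a.cause is Cause.BIRTH_ASPHYXIA
    assert not a.collapse_applied


def test_eligibility_flag_for_terminal_cause_rejected():
    with pytest.raises(ValueError, match="unexplained"):
        CaseRecord(case_id="x", age_at_death_days=1, gestation_weeks=38,
                   eligibility={Cause.UNEXPLAINED: True})


def test_age_out_of_neonatal_range_rejected():
    with pytest.raises(ValueError, match="age_at_death_days"):
        CaseRecord(case_id="x", age_at_death_days=29, gestation_weeks=38)


flag_sets = st.dictionaries(
    st.sampled_from([c.value for c in ASSIGNABLE]), st.booleans(), max_size=10
)
ages = st.integers(min_value=0, max_value=28)
gestations = st.floats(min_value=22, max_value=44, allow_nan=False)


@settings(max_examples=300, derandomize=True)
@given(age=ages, gestation=gestations, flags=flag_sets)
def test_matches_brute_force_oracle(age, gestation, flags):
    """Random-case equivalence with the independent first-match scan."""
    a = assign_primary_cause(make_record(age, gestation, flags))
    assert a.cause.value == oracle_assign(age, gestation, flags)


@settings(max_examples=200, derandomize=True)
@given(age=ages, gestation=gestations, flags=flag_sets,
       earlier=st.sampled_from([c.value for c in ASSIGNABLE]))
def test_order_dominance(age, gestation, flags, earlier):
    """Raising an earlier-listed cause's flag never yields a later cause."""
    base = assign_primary_cause(make_record(age, gestation, flags)).cause
    raised = dict(flags)
    raised[earlier] = True
    new = assign_primary_cause(make_record(age, gestation, raised)).cause
    key = ("lt3" if age < 3 else "ge3", "lt32" if gestation < 32 else "ge32")
    order = [i.split("<")[0] for i in ORACLE_LISTS[key]] + ["unexplained"]
    if earlier in order and base.value in order:
        assert order.index(new.value) <= order.index(base.value)


@settings(max_examples=200, derandomize=True)
@given(age=ages, gestation=st.floats(min_value=22, max_value=33.9, allow_nan=False),
       flags=flag_sets)
def test_collapse_monotonicity(age, gestation, flags):
    """With collapse on, no death below 34 weeks is ever labeled asphyxia."""
    a = assign_primary_cause(make_record(age, gestation, flags), collapse_lt34=True)
    assert a.cause is not Cause.BIRTH_ASPHYXIA
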