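"""Shared fixtures: the study's printed contingency counts and accuracy values."""
import pandas as pd
import pytest

from neoval import Cause

# Per-cause 2x2 counts (tp, fp, tn, fn) of VA against the hospital reference,
# over 626 paired deaths.  "severe_infection" groups sepsis, meningitis,
# pneumonia and diarrhea.
TABLE5_COUNTS = {
    "congenital_anomalies": (8, 5, 607, 6),
    "prematurity_complications": (209, 20, 382, 15),
    "birth_asphyxia": (147, 41, 409, 29),
    "tetanus": (6, 3, 614, 3),
    "severe_infection": (138, 27, 424, 37),
}

# Printed accuracy percentages (sens, spec, ppv, npv), one decimal.
TABLE5_ACCURACY = {
    "congenital_anomalies": (57.1, 99.2, 61.5, 99.0),
    "prematurity_complications": (93.3, 95.0, 91.3, 96.2),
    "birth_asphyxia": (83.5, 90.9, 78.2, 93.4),
    "tetanus": (66.7, 99.5, 66.7, 99.5),
    "severe_infection": (78.9, 94.0, 83.6, 92.0),
}

# Printed 95% CI bounds in percent: (sens_lo, sens_hi, spec_lo, spec_hi).
TABLE5_CI = {
    "congenital_anomalies": (32.6, 78.6, 98.1, 99.6),
    "prematurity_complications": (89.2, 95.9, 92.4, 96.7),
    "birth_asphyxia": (77.3, 88.3, 87.8, 93.2),
    "tetanus": (35.4, 87.9, 98.6, 99.8),
    "severe_infection": (72.2, 84.3, 91.4, 95.9),
}

# Reference / VA cause counts over the 626 deaths, with printed percentages.
TABLE4_COUNTS = {
    "congenital_anomalies": (14, 13),
    "prematurity_complications": (224, 229),
    "birth_asphyxia": (176, 188),
    "tetanus": (9, 9),
    "pneumonia": (11, 13),
    "meningitis": (1, 3),
    "diarrhea": (1, 0),
    "sepsis": (162, 149),
    "unexplained": (17, 16),
    "other_specific": (11, 6),
}
TABLE4_PCT = {
    "congenital_anomalies": (2.2, 2.1),
    "prematurity_complications": (35.8, 36.6),
    "birth_asphyxia": (28.1, 30.0),
    "tetanus": (1.4, 1.4),
    "pneumonia": (1.8, 2.1),
    "meningitis": (0.2, 0.5),
    "diarrhea": (0.2, 0.0),
    "sepsis": (25.9, 23.8),
    "unexplained": (2.7, 2.6),
    "other_specific": (1.8, 1.0),
}


@pytest.fixture(scope="session")
def table5_counts():
    return TABLE5_COUNTS


@pytest.fixture(scope="session")
def table4_counts():
    return TABLE4_COUNTS


def label_multiset(column: int) -> list[str]:
    """Expand the study's cause counts into a flat list of labels."""
    out = []
    for cause, counts in TABLE4_COUNTS.items():
        out.extend([cause] * counts[column])
    return out


@pytest.fixture()
def tiny_pairs() -> pd.DataFrame:
    """Six hand-labelled pairs used against brute-force oracles."""
    return pd.DataFrame(
        {
            "case_id": [f"c{i}" for i in range(6)],
            "reference_cause": [
                Cause.SEPSIS.value,
                Cause.SEPSIS.value,
                Cause.BIRTH_ASPHYXIA.value,
                Cause.PREMATURITY_COMPLICATIONS.value,
                Cause.TETANUS.value,
                Cause.UNEXPLAINED.value,
            ],
            "va_cause": [
                Cause.SEPSIS.value,
                Cause.PNEUMONIA.value,
                Cause.PREMATURITY_COMPLICATIONS.value,
                Cause.PREMATURITY_COMPLICATIONS.value,
                Cause.BIRTH_ASPHYXIA.value,
                Cause.SEPSIS.value,
            ],
        }
    )
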