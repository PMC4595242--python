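"""Hierarchical assignment of a single primary cause of neonatal death.

Cases are stratified by age at death (< 3 vs >= 3 completed days) and
gestation (< 32 vs >= 32 weeks).  Each of the four strata carries an ordered
list of candidate causes; the first cause whose case-definition eligibility
flag is true (and whose age condition, if any, holds) becomes the primary
cause.  If no listed cause is eligible the death is ``UNEXPLAINED``.

Age is in completed days, so "< 3 days" means days 0-2 and "< 7 days" means
days 0-6.  Exactly 32.0 weeks falls in the >= 32 band.  The serious-infection
slot is a composite: it fires on the first eligible member in the fixed order
sepsis > meningitis > pneumonia > diarrhea, and that member is the returned
label.

An optional collapse rule re-labels an assigned birth asphyxia as
prematurity complications when gestation is below 34 weeks (asphyxia is hard
to establish in very preterm babies that may simply not have breathed at
birth).  It is off by default.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Union

from .causes import ASSIGNABLE, SEVERE_INFECTION, Cause

#: Age-at-death band boundary (completed days).
AGE_BAND_THRESHOLD_DAYS = 3
#: Gestation band boundary (weeks); exactly 32.0 goes to the upper band.
GESTATION_BAND_THRESHOLD_WEEKS = 32.0
#: Asphyxia age condition in the older-age strata: eligible only below this.
ASPHYXIA_AGE_LIMIT_DAYS = 7
#: Gestation below which the optional collapse rule relabels asphyxia.
COLLAPSE_GESTATION_THRESHOLD_WEEKS = 34.0
#: Gestation defining "prematurity" in mortality-fraction reporting.  Kept as
#: a separate constant from the 32-week stratum boundary and the 34-week
#: collapse cutoff: the three thresholds serve different roles and are not
#: interchangeable.
PREMATURITY_DEFINITION_WEEKS = 33.0

MAX_NEONATAL_AGE_DAYS = 28


class AgeBand(str, Enum):
    LT3_DAYS = "lt3_days"
    GE3_DAYS = "ge3_days"


class GestationBand(str, Enum):
    LT32_WEEKS = "lt32_weeks"
    GE32_WEEKS = "ge32_weeks"


class MissingGestationPolicy(str, Enum):
    """What to do when a case has no recorded gestation.

    ``ERROR`` (default) refuses to assign; the two ``ASSUME_*`` policies place
    the case in the stated gestation band without imputing a numeric value.
    """

    ERROR = "error"
    ASSUME_GE32 = "assume_ge32"
    ASSUME_LT32 = "assume_lt32"


@dataclass(frozen=True)
class HierarchyEntry:
    """One slot in a stratum's ordered cause list.

    ``max_age_days`` expresses an "if age < N days" condition.
    """

    cause: Cause
    max_age_days: Optional[int] = None

    def eligible(self, eligibility: Mapping[Cause, bool], age_days: int) -> bool:
        if not eligibility.get(self.cause, False):
            return False
        if self.max_age_days is not None and age_days >= self.max_age_days:
            return False
        return True


@dataclass(frozen=True)
class HierarchyStratum:
    age_band: AgeBand
    gestation_band: GestationBand
    ordered_causes: tuple[HierarchyEntry, ...]


def _entries(*items: Union[Cause, HierarchyEntry, tuple]) -> tuple[HierarchyEntry, ...]:
    out: list[HierarchyEntry] = []
    for item in items:
        if item is _INFECTION_SLOT:
            out.extend(HierarchyEntry(c) for c in SEVERE_INFECTION)
        elif isinstance(item, HierarchyEntry):
            out.append(item)
        else:
            out.append(HierarchyEntry(item))
    return tuple(out)


_INFECTION_SLOT = object()  # expands to the four infection members in order
_ASPHYXIA_LT7 = HierarchyEntry(Cause.BIRTH_ASPHYXIA, max_age_days=ASPHYXIA_AGE_LIMIT_DAYS)

#: The four strata.  Within each, causes are tried top to bottom.
STRATA: dict[tuple[AgeBand, GestationBand], HierarchyStratum] = {
    (AgeBand.LT3_DAYS, GestationBand.LT32_WEEKS): HierarchyStratum(
        AgeBand.LT3_DAYS,
        GestationBand.LT32_WEEKS,
        _entries(
            Cause.CONGENITAL_ANOMALIES,
            Cause.INJURIES,
            Cause.BIRTH_ASPHYXIA,
            Cause.PREMATURITY_COMPLICATIONS,
        ),
    ),
    (AgeBand.GE3_DAYS, GestationBand.LT32_WEEKS): HierarchyStratum(
        AgeBand.GE3_DAYS,
        GestationBand.LT32_WEEKS,
        _entries(
            Cause.CONGENITAL_ANOMALIES,
            Cause.INJURIES,
            _ASPHYXIA_LT7,
            Cause.TETANUS,
            _INFECTION_SLOT,
            Cause.PREMATURITY_COMPLICATIONS,
        ),
    ),
    (AgeBand.LT3_DAYS, GestationBand.GE32_WEEKS): HierarchyStratum(
        AgeBand.LT3_DAYS,
        GestationBand.GE32_WEEKS,
        _entries(
            Cause.CONGENITAL_ANOMALIES,
            Cause.INJURIES,
            Cause.BIRTH_ASPHYXIA,
            _INFECTION_SLOT,
            Cause.PREMATURITY_COMPLICATIONS,
            Cause.OTHER_SPECIFIC,
        ),
    ),
    (AgeBand.GE3_DAYS, GestationBand.GE32_WEEKS): HierarchyStratum(
        AgeBand.GE3_DAYS,
        GestationBand.GE32_WEEKS,
        _entries(
            Cause.CONGENITAL_ANOMALIES,
            Cause.INJURIES,
            _ASPHYXIA_LT7,
            Cause.TETANUS,
            _INFECTION_SLOT,
            Cause.PREMATURITY_COMPLICATIONS,
            Cause.OTHER_SPECIFIC,
        ),
    ),
}


@dataclass
class CaseRecord:
    """One deceased neonate.

    ``eligibility`` maps assignable cause codes to "case definition met"
    booleans; causes absent from the mapping are treated as not met.
    Gestation may be missing (``None``); age at death is completed days 0-28.
    """

    case_id: str
    age_at_death_days: int
    gestation_weeks: Optional[float] = None
    sex: str = "unknown"
    birth_weight_g: Optional[float] = None
    eligibility: Mapping[Cause, bool] = field(default_factory=dict)
    source: str = "hospital"

    def __post_init__(self) -> None:
        age = self.age_at_death_days
        if not (0 <= int(age) <= MAX_NEONATAL_AGE_DAYS):
            raise ValueError(
                f"case {self.case_id!r}: age_at_death_days must be in "
                f"0-{MAX_NEONATAL_AGE_DAYS}, got {age}"
            )
        if self.gestation_weeks is not None:
            g = float(self.gestation_weeks)
            if math.isnan(g):
                self.gestation_weeks = None
            elif g <= 0:
                raise ValueError(
                    f"case {self.case_id!r}: gestation_weeks must be positive, got {g}"
                )
        for cause in self.eligibility:
            if cause not in ASSIGNABLE:
                raise ValueError(
                    f"case {self.case_id!r}: eligibility flag for "
                    f"non-assignable cause {cause!r}"
                )


def stratum_of(
    age_at_death_days: int,
    gestation_weeks: Optional[float],
    *,
    missing_gestation: MissingGestationPolicy | str = MissingGestationPolicy.ERROR,
) -> HierarchyStratum:
    """Return the hierarchy stratum containing the given age and gestation.

    Boundaries: age 3 completed days falls in the >= 3 band, gestation exactly
    32.0 weeks in the >= 32 band.  Missing gestation raises unless a fallback
    band policy is configured.
    """
    if age_at_death_days < 0:
        raise ValueError(f"age_at_death_days must be >= 0, got {age_at_death_days}")
    age_band = (
        AgeBand.LT3_DAYS
        if age_at_death_days < AGE_BAND_THRESHOLD_DAYS
        else AgeBand.GE3_DAYS
    )

    policy = MissingGestationPolicy(missing_gestation)
    if gestation_weeks is None or (
        isinstance(gestation_weeks, float) and math.isnan(gestation_weeks)
    ):
        if policy is MissingGestationPolicy.ERROR:
            raise ValueError(
                "gestation_weeks is missing and missing_gestation policy is 'error'"
            )
        gest_band = (
            GestationBand.GE32_WEEKS
            if policy is MissingGestationPolicy.ASSUME_GE32
            else GestationBand.LT32_WEEKS
        )
    else:
        if gestation_weeks <= 0:
            raise ValueError(f"gestation_weeks must be > 0, got {gestation_weeks}")
        gest_band = (
            GestationBand.LT32_WEEKS
            if gestation_weeks < GESTATION_BAND_THRESHOLD_WEEKS
            else GestationBand.GE32_WEEKS
        )
    return STRATA[(age_band, gest_band)]


@dataclass(frozen=True)
class Assignment:
    """Result of running one case through the hierarchy."""

    case_id: str
    cause: Cause
    stratum: HierarchyStratum
    collapse_applied: bool = False


def assign_primary_cause(
    record: CaseRecord,
    *,
    collapse_lt34: bool = False,
    missing_gestation: MissingGestationPolicy | str = MissingGestationPolicy.ERROR,
) -> Assignment:
    """Assign the primary cause of death for one case.

    Scans the case's stratum top to bottom and returns the first eligible
    cause; ``UNEXPLAINED`` if none.  With ``collapse_lt34`` on, an assigned
    birth asphyxia is re-labeled prematurity complications when gestation is
    below :data:`COLLAPSE_GESTATION_THRESHOLD_WEEKS` (or when the missing-
    gestation policy places the case below 32 weeks).
    """
    stratum = stratum_of(
        record.age_at_death_days,
        record.gestation_weeks,
        missing_gestation=missing_gestation,
    )
    cause = Cause.UNEXPLAINED
    for entry in stratum.ordered_causes:
        if entry.eligible(record.eligibility, record.age_at_death_days):
            cause = entry.cause
            break

    collapse_applied = False
    if collapse_lt34 and cause is Cause.BIRTH_ASPHYXIA:
        if record.gestation_weeks is not None:
            below = record.gestation_weeks < COLLAPSE_GESTATION_THRESHOLD_WEEKS
        else:
            below = stratum.gestation_band is GestationBand.LT32_WEEKS
        if below:
            cause = Cause.PREMATURITY_COMPLICATIONS
            collapse_applied = True

    return Assignment(record.case_id, cause, stratum, collapse_applied)


def assign_cases(
    records: list[CaseRecord],
    *,
    collapse_lt34: bool = False,
    missing_gestation: MissingGestationPolicy | str = MissingGestationPolicy.ERROR,
):
    """Assign every case; returns a pandas DataFrame (one row per case)."""
    import pandas as pd

    rows = []
    for rec in records:
        a = assign_primary_cause(
            rec, collapse_lt34=collapse_lt34, missing_gestation=missing_gestation
        )
        rows.append(
            {
                "case_id": a.case_id,
                "assigned_cause": a.cause.value,
                "stratum": f"{a.stratum.age_band.value}/{a.stratum.gestation_band.value}",
                "collapse_applied": a.collapse_applied,
            }
        )
    df = pd.DataFrame(rows, columns=["case_id", "assigned_cause", "stratum", "collapse_applied"])
    if df["case_id"].duplicated().any():
        dups = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        warnings.warn(f"duplicate case ids in input: {dups}")
    return df
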