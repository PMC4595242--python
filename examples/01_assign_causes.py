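"""Assign primary causes of death through the age/gestation hierarchy.

Each case carries boolean case-definition eligibility flags; the hierarchy
picks the first eligible cause in its stratum's fixed order.
"""
from neoval import CaseRecord, Cause, assign_primary_cause

cases = [
    # very preterm early death: asphyxia not flagged, prematurity wins
    CaseRecord("n01", age_at_death_days=1, gestation_weeks=30.0,
               eligibility={Cause.PREMATURITY_COMPLICATIONS: True}),
    # day-10 death: asphyxia only counts before day 7, so tetanus wins
    CaseRecord("n02", age_at_death_days=10, gestation_weeks=36.0,
               eligibility={Cause.BIRTH_ASPHYXIA: True, Cause.TETANUS: True}),
    # sepsis outranks pneumonia within the serious-infection slot
    CaseRecord("n03", age_at_death_days=5, gestation_weeks=38.0,
               eligibility={Cause.PNEUMONIA: True, Cause.SEPSIS: True}),
    # no case definition met
    CaseRecord("n04", age_at_death_days=4, gestation_weeks=39.0),
]

for rec in cases:
    a = assign_primary_cause(rec)
    print(f"{rec.case_id}: day {rec.age_at_death_days}, "
          f"{rec.gestation_weeks} wk -> {a.cause.value} "
          f"({a.stratum.age_band.value}/{a.stratum.gestation_band.value})")

# The optional collapse rule: below 34 weeks an asphyxia call is folded into
# prematurity complications (the baby may simply not have breathed at birth).
preterm = CaseRecord("n05", age_at_death_days=1, gestation_weeks=33.0,
                     eligibility={Cause.BIRTH_ASPHYXIA: True})
a = assign_primary_cause(preterm, collapse_lt34=True)
print(f"{preterm.case_id}: asphyxia at 33 wk with collapse -> {a.cause.value} "
      f"(collapse_applied={a.collapse_applied})")
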