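"""Cause-of-death taxonomy for neonatal verbal-autopsy validation.

A fixed ten-category taxonomy of assignable causes plus two terminal labels:
``UNEXPLAINED`` (no case definition met) and ``UNCLASSIFIABLE`` (three
reviewers disagreed).  ``SEVERE_INFECTION`` is a derived reporting group, not
a member code.
"""
from __future__ import annotations

from enum import Enum


class Cause(str, Enum):
    """A single primary cause of neonatal death."""

    CONGENITAL_ANOMALIES = "congenital_anomalies"
    INJURIES = "injuries"
    BIRTH_ASPHYXIA = "birth_asphyxia"
    TETANUS = "tetanus"
    SEPSIS = "sepsis"
    MENINGITIS = "meningitis"
    PNEUMONIA = "pneumonia"
    DIARRHEA = "diarrhea"
    PREMATURITY_COMPLICATIONS = "prematurity_complications"
    OTHER_SPECIFIC = "other_specific"
    UNEXPLAINED = "unexplained"
    UNCLASSIFIABLE = "unclassifiable"

    def __str__(self) -> str:  # CSV round-trips use the bare value
        return self.value

    @classmethod
    def parse(cls, text: str) -> "Cause":
        """Parse a cause code, raising ``ValueError`` naming the bad value."""
        try:
            return cls(str(text).strip().lower())
        except ValueError:
            raise ValueError(f"unknown cause code: {text!r}") from None


#: Terminal labels: outcomes of the pipeline, never inputs to the hierarchy.
TERMINAL: tuple[Cause, ...] = (Cause.UNEXPLAINED, Cause.UNCLASSIFIABLE)

#: Causes a reviewer (or the hierarchy) may assign from case definitions.
ASSIGNABLE: tuple[Cause, ...] = tuple(c for c in Cause if c not in TERMINAL)

#: Derived reporting group, in fixed internal priority order.
SEVERE_INFECTION: tuple[Cause, ...] = (
    Cause.SEPSIS,
    Cause.MENINGITIS,
    Cause.PNEUMONIA,
    Cause.DIARRHEA,
)

DISPLAY_NAMES: dict[Cause, str] = {
    Cause.CONGENITAL_ANOMALIES: "Congenital malformations",
    Cause.INJURIES: "Injuries (not birth related)",
    Cause.BIRTH_ASPHYXIA: "Birth asphyxia",
    Cause.TETANUS: "Tetanus",
    Cause.SEPSIS: "Sepsis",
    Cause.MENINGITIS: "Meningitis",
    Cause.PNEUMONIA: "Pneumonia",
    Cause.DIARRHEA: "Diarrhea",
    Cause.PREMATURITY_COMPLICATIONS: "Prematurity complications",
    Cause.OTHER_SPECIFIC: "Other specific cause",
    Cause.UNEXPLAINED: "Unexplained neonatal death",
    Cause.UNCLASSIFIABLE: "Unclassifiable",
}
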