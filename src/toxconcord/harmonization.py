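"""Harmonization of CTCAE grades and EORTC severities onto a common scale.

The two instruments are aligned through a fixed pairing: CTCAE grade 0
with severity 1, grade 1 with severity 2, grade 2 with severity 3, and
grades 3 and 4 combined with severity 4.  Collapsing grades 3/4 gives a
0-3 clinician scale g such that g + 1 is directly comparable to the
1-4 patient severity.  Each complete pair is then classified as

* agreement     — severity == g + 1
* underreport   — clinician grade below the patient severity
* overestimate  — clinician grade above the patient severity

and, for the binary analysis, recoded as none-vs-any on both sides
(clinician: grade >= 1; patient: severity >= 2), yielding the 2x2 cells
"reported by neither / clinician only / patient only / both".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .domains import validate_grade, validate_response


class ConcordanceClass(str, Enum):
    AGREEMENT = "agreement"
    UNDERREPORT = "underreport"
    OVERESTIMATE = "overestimate"


class BinaryCell(str, Enum):
    NEITHER = "neither"
    CLINICIAN_ONLY = "clinician_only"
    PATIENT_ONLY = "patient_only"
    BOTH = "both"


def collapse_ctcae_grade(grade: int) -> int:
    """Collapse CTCAE 0-4 onto 0-3 (grades 3 and 4 combined)."""
    g = validate_grade(grade)
    if g is None:
        raise ValueError("grade must be present")
    return min(g, 3)


def classify_concordance(grade: int, severity: int) -> ConcordanceClass:
    """Classify one complete pair on the harmonized 4-level scale.

    A raw grade 4 against severity 4 is agreement (grades 3/4 are one
    level), never overestimation.
    """
    g = collapse_ctcae_grade(grade)
    s = validate_response(severity)
    if s is None:
        raise ValueError("severity must be present")
    if s == g + 1:
        return ConcordanceClass.AGREEMENT
    if g + 1 < s:
        return ConcordanceClass.UNDERREPORT
    return ConcordanceClass.OVERESTIMATE


@dataclass(frozen=True)
class BinaryPair:
    clinician_any: bool
    patient_any: bool

    @property
    def cell(self) -> BinaryCell:
        if self.clinician_any and self.patient_any:
            return BinaryCell.BOTH
        if self.clinician_any:
            return BinaryCell.CLINICIAN_ONLY
        if self.patient_any:
            return BinaryCell.PATIENT_ONLY
        return BinaryCell.NEITHER


def binarize_pair(grade: int, severity: int) -> BinaryPair:
    """None-vs-any recoding of one complete pair."""
    g = validate_grade(grade)
    s = validate_response(severity)
    if g is None or s is None:
        raise ValueError("both members of the pair must be present")
    return BinaryPair(clinician_any=g >= 1, patient_any=s >= 2)
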