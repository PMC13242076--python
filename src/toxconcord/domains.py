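"""Core domain model: symptom domains, clinician and patient records.

The analysis compares two instruments on six symptom domains that have a
direct conceptual overlap:

* clinician side — CTCAE toxicity grades on an ordinal 0 (none) to 4
  (life-threatening) scale, recorded per patient, treatment arm and
  assessment time point (mid- and end-of-treatment);
* patient side — EORTC QLQ-C30 / QLQ-BR23 symptom items answered on a
  4-point Likert scale (1 "not at all" ... 4 "very much").

Four domains map to a single questionnaire item; pain maps to two items
and fatigue to three, which are summarised by the EORTC scale-scoring
rules before they can be compared with a CTCAE grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class ValidationError(ValueError):
    """Raised when an input value violates the instrument contracts."""


class Arm(str, Enum):
    A = "A"
    B = "B"


class Timepoint(str, Enum):
    MID = "mid"
    END = "end"


@dataclass(frozen=True)
class SymptomDomain:
    """A symptom domain with its EORTC item mapping.

    Every domain corresponds one-to-one to a CTCAE toxicity term; the
    ``eortc_items`` list holds the questionnaire item identifiers that
    feed the patient-side severity for this domain.
    """

    name: str
    eortc_items: tuple[str, ...]

    @property
    def multi_item(self) -> bool:
        return len(self.eortc_items) > 1

    @property
    def n_items(self) -> int:
        return len(self.eortc_items)

    def __post_init__(self) -> None:
        if not self.eortc_items:
            raise ValidationError(f"domain {self.name!r} has no EORTC items")


# The a-priori instrument mapping: single items for diarrhea, nausea,
# vomiting and mucositis (dry mouth); a 2-item scale for pain and the
# 3-item fatigue scale.
DIARRHEA = SymptomDomain("diarrhea", ("diarrhea",))
NAUSEA = SymptomDomain("nausea", ("nauseated",))
VOMITING = SymptomDomain("vomiting", ("vomited",))
MUCOSITIS = SymptomDomain("mucositis", ("dry_mouth",))
PAIN = SymptomDomain("pain", ("pain", "pain_interfered"))
FATIGUE = SymptomDomain("fatigue", ("need_rest", "felt_weak", "tired"))

DOMAINS: dict[str, SymptomDomain] = {
    d.name: d for d in (DIARRHEA, NAUSEA, VOMITING, MUCOSITIS, PAIN, FATIGUE)
}

ITEM_TO_DOMAIN: dict[str, SymptomDomain] = {
    item: d for d in DOMAINS.values() for item in d.eortc_items
}


def get_domain(name: str) -> SymptomDomain:
    try:
        return DOMAINS[name]
    except KeyError:
        raise ValidationError(
            f"unknown symptom domain {name!r}; expected one of {sorted(DOMAINS)}"
        ) from None


def validate_grade(grade: Optional[int]) -> Optional[int]:
    """CTCAE grade: integer 0-4, or None for missing."""
    if grade is None:
        return None
    g = int(grade)
    if g != grade or not 0 <= g <= 4:
        raise ValidationError(f"CTCAE grade must be an integer in 0-4, got {grade!r}")
    return g


def validate_response(response: Optional[int]) -> Optional[int]:
    """EORTC Likert response: integer 1-4, or None for missing."""
    if response is None:
        return None
    r = int(response)
    if r != response or not 1 <= r <= 4:
        raise ValidationError(
            f"EORTC response must be an integer in 1-4, got {response!r}"
        )
    return r


@dataclass(frozen=True)
class CtcaeRecord:
    """One clinician toxicity assessment (patient x time point x domain)."""

    patient_id: str
    arm: Arm
    timepoint: Timepoint
    domain: SymptomDomain
    grade: Optional[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "grade", validate_grade(self.grade))


@dataclass(frozen=True)
class EortcResponse:
    """One patient questionnaire item response."""

    patient_id: str
    timepoint: Timepoint
    item_id: str
    response: Optional[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "response", validate_response(self.response))


@dataclass(frozen=True)
class MatchedObservation:
    """A pairwise-complete clinician/patient pair for one domain.

    Both members are guaranteed present: the CTCAE grade (0-4) and the
    patient severity level (1-4) derived from the EORTC items.
    """

    patient_id: str
    arm: Arm
    timepoint: Timepoint
    domain: SymptomDomain
    ctcae_grade: int
    eortc_severity: int

    def __post_init__(self) -> None:
        g = validate_grade(self.ctcae_grade)
        s = validate_response(self.eortc_severity)
        if g is None or s is None:
            raise ValidationError("matched observations must be complete pairs")
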