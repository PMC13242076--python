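"""EORTC symptom-scale scoring.

Single items are used directly as a 1-4 severity level.  Multi-item
scales (pain: 2 items, fatigue: 3 items) follow the EORTC scoring
convention: the raw score is the mean of the answered items, computed
only when at least half of the scale's items are answered (the
"half-rule"; equivalent to imputing each missing item with the mean of
the answered ones), then linearly transformed to a 0-100 symptom score

    transformed = (raw_mean - 1) / 3 * 100

and finally re-categorised into four severity levels so that multi-item
scales become comparable with single-item scales.

The four-level categorisation assigns the level whose anchor score
(0, 33.33, 66.67, 100 — the transformed images of raw 1..4) is nearest,
with ties going to the higher severity.  On the raw 1-4 scale this is
exactly "round half-up to the nearest integer", which is how it is
implemented (no floating-point boundary artifacts).  The rule makes the
single-item and multi-item pathways exactly consistent: a single item r
always categorises back to level r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .domains import (
    EortcResponse,
    SymptomDomain,
    Timepoint,
    ValidationError,
    validate_response,
)


@dataclass(frozen=True)
class RawScaleScore:
    """Raw (1-4) scale mean with answered/total item bookkeeping."""

    domain: SymptomDomain
    raw_mean: Optional[float]
    n_answered: int
    n_items: int


def score_single_item(response: Optional[int]) -> Optional[int]:
    """Severity of a single-item domain: the Likert response itself."""
    return validate_response(response)


def score_multi_item_scale(
    responses: Iterable[Optional[int]], domain: SymptomDomain
) -> RawScaleScore:
    """Apply the half-rule and compute the raw scale mean.

    ``responses`` must supply one entry (value or None) per scale item.
    The raw mean is present iff at least ceil(n_items / 2) items are
    answered.
    """
    values = [validate_response(r) for r in responses]
    n_items = domain.n_items
    if len(values) != n_items:
        raise ValidationError(
            f"domain {domain.name!r} expects {n_items} responses, got {len(values)}"
        )
    answered = [v for v in values if v is not None]
    n_answered = len(answered)
    if n_answered >= math.ceil(n_items / 2):
        raw_mean: Optional[float] = sum(answered) / n_answered
    else:
        raw_mean = None
    return RawScaleScore(domain, raw_mean, n_answered, n_items)


def transform_symptom_scale(raw_mean: Optional[float]) -> Optional[float]:
    """Linear 0-100 transformation of a raw 1-4 symptom mean."""
    if raw_mean is None:
        return None
    if not 1.0 <= raw_mean <= 4.0:
        raise ValidationError(f"raw scale mean must lie in [1, 4], got {raw_mean!r}")
    return (raw_mean - 1.0) / 3.0 * 100.0


def categorize_severity_raw(raw_mean: Optional[float]) -> Optional[int]:
    """Four-level severity from a raw 1-4 mean: round half-up, clamp to 1-4."""
    if raw_mean is None:
        return None
    if not 1.0 <= raw_mean <= 4.0:
        raise ValidationError(f"raw scale mean must lie in [1, 4], got {raw_mean!r}")
    return min(4, max(1, math.floor(raw_mean + 0.5)))


def categorize_severity(transformed: Optional[float]) -> Optional[int]:
    """Four-level severity from a 0-100 score (nearest anchor, ties up)."""
    if transformed is None:
        return None
    if not 0.0 <= transformed <= 100.0:
        raise ValidationError(f"transformed score must lie in [0, 100], got {transformed!r}")
    return categorize_severity_raw(transformed / 100.0 * 3.0 + 1.0)


def domain_severity(
    domain: SymptomDomain, responses: dict[str, Optional[int]]
) -> Optional[int]:
    """Severity level 1-4 for one domain from its item responses.

    ``responses`` maps item_id -> Likert value (items absent from the
    mapping count as missing).  Returns None when the half-rule fails
    (or, for single items, when the item is missing).
    """
    if not domain.multi_item:
        return score_single_item(responses.get(domain.eortc_items[0]))
    raw = score_multi_item_scale(
        [responses.get(item) for item in domain.eortc_items], domain
    )
    return categorize_severity_raw(raw.raw_mean)


def score_severities(
    responses: Iterable[EortcResponse], domains: Iterable[SymptomDomain]
) -> dict[tuple[str, Timepoint, str], int]:
    """Score all patients: (patient_id, timepoint, domain name) -> severity.

    Only non-missing severities are returned; patient/time-point visits
    with no responses at all simply do not appear.
    """
    by_visit: dict[tuple[str, Timepoint], dict[str, Optional[int]]] = {}
    for r in responses:
        by_visit.setdefault((r.patient_id, r.timepoint), {})[r.item_id] = r.response
    out: dict[tuple[str, Timepoint, str], int] = {}
    for (pid, tp), items in by_visit.items():
        for domain in domains:
            sev = domain_severity(domain, items)
            if sev is not None:
                out[(pid, tp, domain.name)] = sev
    return out
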