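"""Pairwise-complete matching of clinician grades to patient severities.

Matching is pairwise per domain and time point: a pair enters the
analysis only when BOTH the CTCAE grade and the scored EORTC severity
are present, so the matched n legitimately differs across domains
within the same arm and time point (multi-item scales lose more visits
to the half-rule than single items do).
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .domains import (
    CtcaeRecord,
    MatchedObservation,
    SymptomDomain,
    Timepoint,
)


def match_observations(
    ctcae: Iterable[CtcaeRecord],
    severities: Mapping[tuple[str, Timepoint, str], int],
    domain: SymptomDomain,
    timepoint: Timepoint,
) -> list[MatchedObservation]:
    """Return the pairwise-complete pairs for one domain and time point.

    ``severities`` is the mapping produced by
    :func:`toxconcord.scoring.score_severities`.
    """
    matched: list[MatchedObservation] = []
    for rec in ctcae:
        if rec.domain != domain or rec.timepoint != timepoint or rec.grade is None:
            continue
        sev = severities.get((rec.patient_id, timepoint, domain.name))
        if sev is None:
            continue
        matched.append(
            MatchedObservation(
                patient_id=rec.patient_id,
                arm=rec.arm,
                timepoint=timepoint,
                domain=domain,
                ctcae_grade=rec.grade,
                eortc_severity=sev,
            )
        )
    return matched
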