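"""Discordance quantification and testing.

Beyond chance-corrected agreement, the analysis asks *in which
direction* clinicians and patients disagree: the underreport rate (the
clinician grade below the patient severity on the harmonized scale),
the overestimate rate, an exact binomial test for predominance of
underreporting among discordant pairs, McNemar's paired test for the
mid-to-end change in discordance within an arm, and pooled two-sample
z-tests for between-arm comparisons of proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .domains import MatchedObservation, ValidationError
from .harmonization import ConcordanceClass, classify_concordance

#: Default two-sided significance threshold for the predominance tests;
#: accounts for multiplicity across the 12 symptom x arm x time strata.
DEFAULT_ALPHA = 0.004

#: Below this many status switches McNemar falls back to the exact
#: binomial version of the test.
MCNEMAR_EXACT_THRESHOLD = 25


@dataclass(frozen=True)
class DiscordanceSummary:
    n: int
    n_agree: int
    n_under: int
    n_over: int

    @property
    def rate_under(self) -> float:
        return self.n_under / self.n

    @property
    def rate_over(self) -> float:
        return self.n_over / self.n

    @property
    def rate_agree(self) -> float:
        return self.n_agree / self.n


@dataclass(frozen=True)
class TestResult:
    statistic: Optional[float]
    p_value: float
    method: str
    significant: Optional[bool] = None
    degenerate: bool = False


@dataclass(frozen=True)
class PairedDiscordance:
    """Discordance status at both time points for one patient/domain."""

    patient_id: str
    discordant_mid: bool
    discordant_end: bool


def discordance_summary(pairs: Iterable[MatchedObservation]) -> DiscordanceSummary:
    """Count agreement / underreport / overestimate over matched pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("cannot summarize zero matched pairs")
    counts = {c: 0 for c in ConcordanceClass}
    for p in pairs:
        counts[classify_concordance(p.ctcae_grade, p.eortc_severity)] += 1
    return DiscordanceSummary(
        n=len(pairs),
        n_agree=counts[ConcordanceClass.AGREEMENT],
        n_under=counts[ConcordanceClass.UNDERREPORT],
        n_over=counts[ConcordanceClass.OVERESTIMATE],
    )


def exact_binomial_predominance(
    n_under: int, n_over: int, alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Exact two-sided binomial test of P(underreport | discordant) = 0.5.

    Agreements are excluded; the two-sided p sums the probabilities of
    all outcomes no more probable than the observed one.
    """
    if n_under < 0 or n_over < 0:
        raise ValidationError("discordant counts must be non-negative")
    n = n_under + n_over
    if n == 0:
        raise ValidationError("predominance test requires at least one discordant pair")
    res = stats.binomtest(n_under, n, p=0.5, alternative="two-sided")
    return TestResult(
        statistic=float(n_under),
        p_value=float(res.pvalue),
        method="exact-binomial",
        significant=res.pvalue < alpha,
    )


def mcnemar_paired_change(
    paired: Iterable[PairedDiscordance], exact: Optional[bool] = None
) -> TestResult:
    """McNemar's test on the mid-to-end switch in discordance status.

    Uses the continuity-corrected chi-square statistic
    (|b - c| - 1)^2 / (b + c) on the switch counts b (discordant at mid
    only) and c (discordant at end only), falling back to the exact
    binomial version when b + c < 25.  ``exact`` forces one variant.
    """
    paired = list(paired)
    b = sum(1 for p in paired if p.discordant_mid and not p.discordant_end)
    c = sum(1 for p in paired if p.discordant_end and not p.discordant_mid)
    if b + c == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="mcnemar", degenerate=True)
    if exact is None:
        exact = (b + c) < MCNEMAR_EXACT_THRESHOLD
    # counts off the b/c diagonal are irrelevant to the statistic
    table = [[0, b], [c, 0]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="mcnemar-exact" if exact else "mcnemar-cc",
    )


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, correction: bool = False
) -> TestResult:
    """Pooled two-sample z-test for proportions, two-sided.

    Without continuity correction (the default) the squared statistic
    equals the Pearson chi-square of the underlying 2x2 table exactly.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("both sample sizes must be at least 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("successes must lie within their sample sizes")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult(statistic=0.0, p_value=1.0, method="two-prop-z", degenerate=True)
    diff = x1 / n1 - x2 / n2
    if correction:
        diff = np.sign(diff) * max(0.0, abs(diff) - 0.5 * (1 / n1 + 1 / n2))
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = diff / se
    return TestResult(
        statistic=float(z),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        method="two-prop-z-cc" if correction else "two-prop-z",
    )


def build_paired_discordance(
    mid_pairs: Iterable[MatchedObservation],
    end_pairs: Iterable[MatchedObservation],
) -> list[PairedDiscordance]:
    """Restrict to patients matched at BOTH time points; flag discordance.

    A pair is "discordant" when the clinician underreports (the
    directional discrepancy the change analysis tracks).
    """

    def under(p: MatchedObservation) -> bool:
        cls = classify_concordance(p.ctcae_grade, p.eortc_severity)
        return cls == ConcordanceClass.UNDERREPORT

    mid = {p.patient_id: under(p) for p in mid_pairs}
    end = {p.patient_id: under(p) for p in end_pairs}
    common = sorted(set(mid) & set(end))
    return [PairedDiscordance(pid, mid[pid], end[pid]) for pid in common]


@dataclass(frozen=True)
class DiscordanceChange:
    n_paired: int
    rate_mid: float
    rate_end: float
    delta_pct_points: float
    test: TestResult


def discordance_change(
    mid_pairs: Iterable[MatchedObservation],
    end_pairs: Iterable[MatchedObservation],
) -> DiscordanceChange:
    """Mid-to-end change in the underreport rate, on the paired subset.

    Both the rates and McNemar's test use only patients with complete
    pairs at both time points; the delta is in percentage points,
    positive when discordance is higher at end-of-treatment.
    """
    paired = build_paired_discordance(mid_pairs, end_pairs)
    if not paired:
        raise ValidationError("no patients have complete pairs at both time points")
    n = len(paired)
    rate_mid = sum(p.discordant_mid for p in paired) / n
    rate_end = sum(p.discordant_end for p in paired) / n
    return DiscordanceChange(
        n_paired=n,
        rate_mid=rate_mid,
        rate_end=rate_end,
        delta_pct_points=100.0 * (rate_end - rate_mid),
        test=mcnemar_paired_change(paired),
    )
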