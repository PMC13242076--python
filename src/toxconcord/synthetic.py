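"""Synthetic two-arm trial generator with a known discordance mechanism.

No per-patient data from the motivating trial are deposited, so the
pipeline is exercised on simulated cohorts whose generative truth is
known exactly.  The generator emulates a two-arm adjuvant-chemotherapy
trial with two assessment time points (mid- and end-of-treatment), six
symptom domains, and the following mechanism per patient x domain x
time point:

1. a latent ordinal severity ``s`` in 1-4 is drawn from a configurable
   per-domain marginal (optionally drifting at end-of-treatment);
2. the clinician grade is generated on the collapsed 0-3 scale so that
   "perfect concordance" aligns exactly with the harmonized pairing
   (grade = s - 1): with probability ``u`` the clinician underreports
   by a random depth of 1-3 levels (floored at 0), with probability
   ``v`` overestimates by one level (capped), otherwise reports
   concordantly;
3. each of the domain's questionnaire items equals the Likert value of
   ``s`` perturbed by symmetric +/-1 noise (clamped to 1-4);
4. items go missing independently, and whole questionnaire visits go
   missing, at configurable rates — exercising the half-rule and the
   pairwise matching downstream.

:func:`true_parameters` computes the exact expected summaries under
this mechanism by full enumeration over the finite outcome space
(latent severity x mechanism x downgrade depth x item noise x answered
item subsets), and serves as the parameter-recovery oracle.

All randomness flows from a single ``numpy`` Generator seeded from the
config; for a fixed seed the cohort is bit-reproducible.  The draw
order is fixed (arm, patient, time point, domain; within a cell:
severity, mechanism, depth, then per item noise indicator, direction,
missingness; visit missingness is drawn once per patient/time point
before the domain loop) and the same number of variates is consumed on
every branch, so cohorts are stable under config changes that do not
alter the loop structure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agreement import ContingencyTable, WeightScheme, disagreement_weights
from .domains import (
    DOMAINS,
    Arm,
    CtcaeRecord,
    EortcResponse,
    SymptomDomain,
    Timepoint,
    ValidationError,
)
from .scoring import categorize_severity_raw

SEVERITIES = (1, 2, 3, 4)

#: Per-domain latent severity marginals at mid-treatment (P(s=1..4)).
#: Chosen to emulate the prevalence ordering seen during adjuvant
#: anthracycline/taxane chemotherapy: fatigue nearly universal,
#: mucositis/dry mouth and nausea common, pain intermediate, diarrhea
#: and vomiting least prevalent.
DEFAULT_MID_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "diarrhea": (0.70, 0.18, 0.08, 0.04),
    "nausea": (0.40, 0.30, 0.20, 0.10),
    "vomiting": (0.80, 0.12, 0.05, 0.03),
    "mucositis": (0.25, 0.35, 0.25, 0.15),
    "pain": (0.45, 0.30, 0.15, 0.10),
    "fatigue": (0.10, 0.35, 0.35, 0.20),
}

#: Domains whose burden eases by end-of-treatment (antiemetic-responsive
#: symptoms); the rest drift toward higher severity.
IMPROVING_DOMAINS = frozenset({"nausea", "vomiting"})


def _shift_marginal(p: Sequence[float], drift: float) -> tuple[float, ...]:
    """Move a fraction ``drift`` of each category's mass one level up
    (down for negative drift), clamped at the scale ends."""
    p = list(p)
    out = [0.0] * 4
    for i, mass in enumerate(p):
        j = min(3, i + 1) if drift >= 0 else max(0, i - 1)
        out[i] += mass * (1 - abs(drift))
        out[j] += mass * abs(drift)
    return tuple(out)


def _validate_prob_vector(p: Sequence[float], what: str, length: int) -> tuple[float, ...]:
    p = tuple(float(x) for x in p)
    if len(p) != length:
        raise ValidationError(f"{what} must have {length} entries, got {len(p)}")
    if any(x < 0 for x in p):
        raise ValidationError(f"{what} entries must be non-negative")
    if not math.isclose(sum(p), 1.0, abs_tol=1e-9):
        raise ValidationError(f"{what} must sum to 1, got {sum(p)!r}")
    return p


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Generative parameters of a synthetic two-arm trial.

    Parameters
    ----------
    n_per_arm : patients per treatment arm (default 700, the order of
        magnitude of a large phase III per-arm cohort).
    underreport_prob : probability ``u`` that the clinician grade is
        downgraded below the concordant level.
    underreport_depth : probability vector over downgrade steps 1-3.
    overestimate_prob : probability ``v`` of a one-level clinician
        overestimate; ``u + v <= 1`` is enforced at the pair level.
    item_noise : probability that a questionnaire item deviates +/-1
        from the latent level.
    missing_item_prob, missing_visit_prob : independent missingness of
        single items and of whole questionnaire visits.
    end_drift : fraction of severity mass shifted one level at
        end-of-treatment (upward for worsening domains, downward for
        nausea/vomiting).
    severity_marginals : optional override, keyed
        (domain_name, arm, timepoint) -> P(s = 1..4); unspecified
        strata fall back to the defaults + drift.
    """

    n_per_arm: int = 700
    domains: tuple[SymptomDomain, ...] = tuple(DOMAINS.values())
    underreport_prob: float = 0.35
    underreport_depth: tuple[float, float, float] = (0.65, 0.25, 0.10)
    overestimate_prob: float = 0.03
    item_noise: float = 0.10
    missing_item_prob: float = 0.02
    missing_visit_prob: float = 0.05
    end_drift: float = 0.15
    severity_marginals: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValidationError("n_per_arm must be positive")
        for p, what in (
            (self.underreport_prob, "underreport_prob"),
            (self.overestimate_prob, "overestimate_prob"),
            (self.item_noise, "item_noise"),
            (self.missing_item_prob, "missing_item_prob"),
            (self.missing_visit_prob, "missing_visit_prob"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{what} must lie in [0, 1], got {p!r}")
        if self.underreport_prob + self.overestimate_prob > 1.0 + 1e-12:
            raise ValidationError("underreport_prob + overestimate_prob must be <= 1")
        if not -1.0 <= self.end_drift <= 1.0:
            raise ValidationError("end_drift must lie in [-1, 1]")
        object.__setattr__(
            self,
            "underreport_depth",
            _validate_prob_vector(self.underreport_depth, "underreport_depth", 3),
        )
        if self.severity_marginals:
            for key, vec in self.severity_marginals.items():
                _validate_prob_vector(vec, f"severity_marginals[{key!r}]", 4)

    def marginal(
        self, domain: SymptomDomain, arm: Arm, timepoint: Timepoint
    ) -> tuple[float, ...]:
        """Latent severity marginal P(s = 1..4) for one stratum."""
        if self.severity_marginals:
            key = (domain.name, arm, timepoint)
            if key in self.severity_marginals:
                return _validate_prob_vector(
                    self.severity_marginals[key], f"severity_marginals[{key!r}]", 4
                )
        base = DEFAULT_MID_MARGINALS[domain.name]
        if timepoint == Timepoint.MID or self.end_drift == 0.0:
            return base
        drift = -self.end_drift if domain.name in IMPROVING_DOMAINS else self.end_drift
        return _shift_marginal(base, drift)


@dataclass
class SyntheticCohort:
    ctcae: list[CtcaeRecord]
    eortc: list[EortcResponse]
    truth: pd.DataFrame
    config: SyntheticTrialConfig


def _item_pmf(s: int, noise: float) -> np.ndarray:
    """pmf over Likert 1-4 of one item given latent severity s."""
    pmf = np.zeros(4)
    pmf[s - 1] += 1.0 - noise
    pmf[max(1, s - 1) - 1] += noise / 2.0
    pmf[min(4, s + 1) - 1] += noise / 2.0
    return pmf


def _clinician_grade(s: int, mech: str, depth: int) -> int:
    if mech == "under":
        return max(0, (s - 1) - depth)
    if mech == "over":
        return min(4, s)
    return s - 1


def generate_cohort(config: SyntheticTrialConfig) -> SyntheticCohort:
    """Draw one fully reproducible synthetic cohort."""
    rng = np.random.default_rng(config.seed)
    u, v = config.underreport_prob, config.overestimate_prob
    depth_p = np.asarray(config.underreport_depth)
    ctcae: list[CtcaeRecord] = []
    eortc: list[EortcResponse] = []
    truth_rows: list[dict] = []

    for arm in (Arm.A, Arm.B):
        for i in range(config.n_per_arm):
            pid = f"{arm.value}{i + 1:04d}"
            for tp in (Timepoint.MID, Timepoint.END):
                visit_missing = rng.random() < config.missing_visit_prob
                for domain in config.domains:
                    marg = np.asarray(config.marginal(domain, arm, tp))
                    s = int(rng.choice(SEVERITIES, p=marg / marg.sum()))
                    mech_u = rng.random()
                    depth = int(rng.choice((1, 2, 3), p=depth_p))
                    if mech_u < u:
                        mech = "under"
                    elif mech_u < u + v:
                        mech = "over"
                    else:
                        mech = "concordant"
                    grade = _clinician_grade(s, mech, depth)
                    ctcae.append(CtcaeRecord(pid, arm, tp, domain, grade))
                    for item in domain.eortc_items:
                        noise_hit = rng.random() < config.item_noise
                        direction = 1 if rng.random() < 0.5 else -1
                        item_missing = rng.random() < config.missing_item_prob
                        value = s + direction if noise_hit else s
                        value = min(4, max(1, value))
                        response = (
                            None if (visit_missing or item_missing) else value
                        )
                        eortc.append(EortcResponse(pid, tp, item, response))
                    truth_rows.append(
                        {
                            "patient_id": pid,
                            "arm": arm.value,
                            "timepoint": tp.value,
                            "domain": domain.name,
                            "latent_severity": s,
                            "mechanism": mech,
                            "ctcae_grade": grade,
                        }
                    )
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(ctcae=ctcae, eortc=eortc, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Exact expectations under the generative mechanism (enumeration oracle)
# ---------------------------------------------------------------------------


def _severity_given_latent(
    domain: SymptomDomain, s: int, noise: float, miss: float
) -> tuple[np.ndarray, float]:
    """(pmf over observed severity 1-4 given the scale is scorable,
    P(scale scorable)) for one domain and latent severity.

    Enumerates answered-item subsets (the half-rule) and item-value
    combinations exactly.
    """
    n = domain.n_items
    need = math.ceil(n / 2)
    item_pmf = _item_pmf(s, noise)
    sev = np.zeros(4)
    p_scorable = 0.0
    for a in range(need, n + 1):  # number of answered items
        p_subset = math.comb(n, a) * (1 - miss) ** a * miss ** (n - a)
        for values in itertools.product(SEVERITIES, repeat=a):
            p_values = float(np.prod([item_pmf[val - 1] for val in values]))
            if p_values == 0.0:
                continue
            level = categorize_severity_raw(sum(values) / a)
            sev[level - 1] += p_subset * p_values
        p_scorable += p_subset
    if p_scorable > 0:
        sev = sev / p_scorable
    return sev, p_scorable


def _grade_given_latent(
    s: int, u: float, v: float, depth_p: Sequence[float]
) -> np.ndarray:
    """pmf over the collapsed clinician grade 0-3 given latent severity."""
    pmf = np.zeros(4)
    pmf[min(s - 1, 3)] += 1.0 - u - v  # concordant
    pmf[min(s, 3)] += v  # overestimate (cap collapses at 3)
    for step, p_step in zip((1, 2, 3), depth_p):
        pmf[max(0, s - 1 - step)] += u * p_step
    return pmf


def _kappa_from_probs(joint: np.ndarray, scheme: WeightScheme) -> Optional[float]:
    row = joint.sum(axis=1)
    col = joint.sum(axis=0)
    d = disagreement_weights(joint.shape[0], scheme)
    expected = float((d * np.outer(row, col)).sum())
    if expected == 0.0:
        return None
    return 1.0 - float((d * joint).sum()) / expected


@dataclass(frozen=True)
class StratumExpectation:
    """Exact expected summaries for one domain x arm x time point."""

    joint: np.ndarray  # P(collapsed grade 0-3, observed severity 1-4)
    p_pair_complete: float
    rate_under: float
    rate_over: float
    rate_agree: float
    binary_cells: dict[str, float]
    expected_kappa_quadratic: Optional[float]
    expected_kappa_binary: Optional[float]
    kappa_defined: bool


def stratum_expectation(
    config: SyntheticTrialConfig,
    domain: SymptomDomain,
    arm: Arm,
    timepoint: Timepoint,
) -> StratumExpectation:
    marg = config.marginal(domain, arm, timepoint)
    joint = np.zeros((4, 4))
    p_scorable_total = 0.0
    for s, p_s in zip(SEVERITIES, marg):
        if p_s == 0.0:
            continue
        sev_pmf, p_scorable = _severity_given_latent(
            domain, s, config.item_noise, config.missing_item_prob
        )
        grade_pmf = _grade_given_latent(
            s,
            config.underreport_prob,
            config.overestimate_prob,
            config.underreport_depth,
        )
        joint += p_s * p_scorable * np.outer(grade_pmf, sev_pmf)
        p_scorable_total += p_s * p_scorable
    p_complete = (1.0 - config.missing_visit_prob) * p_scorable_total
    if p_scorable_total > 0:
        joint = joint / p_scorable_total  # condition on a complete pair
    g_idx, s_idx = np.indices((4, 4))
    harmonized_patient = s_idx  # severity - 1 on the collapsed scale
    rate_under = float(joint[g_idx < harmonized_patient].sum())
    rate_over = float(joint[g_idx > harmonized_patient].sum())
    rate_agree = float(joint[g_idx == harmonized_patient].sum())
    clin_any = g_idx >= 1
    pat_any = s_idx >= 1  # severity >= 2
    binary_cells = {
        "neither": float(joint[~clin_any & ~pat_any].sum()),
        "clinician_only": float(joint[clin_any & ~pat_any].sum()),
        "patient_only": float(joint[~clin_any & pat_any].sum()),
        "both": float(joint[clin_any & pat_any].sum()),
    }
    kq = _kappa_from_probs(joint, WeightScheme.QUADRATIC)
    binary_joint = np.array(
        [
            [binary_cells["neither"], binary_cells["patient_only"]],
            [binary_cells["clinician_only"], binary_cells["both"]],
        ]
    )
    kb = _kappa_from_probs(binary_joint, WeightScheme.UNWEIGHTED)
    return StratumExpectation(
        joint=joint,
        p_pair_complete=p_complete,
        rate_under=rate_under,
        rate_over=rate_over,
        rate_agree=rate_agree,
        binary_cells=binary_cells,
        expected_kappa_quadratic=kq,
        expected_kappa_binary=kb,
        kappa_defined=kq is not None,
    )


def true_parameters(
    config: SyntheticTrialConfig,
) -> dict[tuple[str, str, str], StratumExpectation]:
    """Exact expected summaries for every domain x arm x time point."""
    out: dict[tuple[str, str, str], StratumExpectation] = {}
    for domain in config.domains:
        for arm in (Arm.A, Arm.B):
            for tp in (Timepoint.MID, Timepoint.END):
                out[(domain.name, arm.value, tp.value)] = stratum_expectation(
                    config, domain, arm, tp
                )
    return out


def overall_underreport_rate(config: SyntheticTrialConfig) -> float:
    """Expected underreport rate pooled over all strata.

    Strata are weighted by their pair-completeness probability (the
    per-arm patient count is constant, so only completeness differs).
    """
    expectations = true_parameters(config)
    weight_sum = 0.0
    acc = 0.0
    for exp in expectations.values():
        acc += exp.p_pair_complete * exp.rate_under
        weight_sum += exp.p_pair_complete
    return acc / weight_sum
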