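"""Contingency tables and Cohen's kappa (weighted and unweighted).

The 4-level analysis crosses the collapsed clinician grade (0-3) with
the patient severity (1-4), aligned to indices 0-3; agreement is
quantified with Cohen's kappa under quadratic weights.  The binary
analysis crosses none-vs-any on both sides and uses unweighted kappa.

Kappa is computed in the disagreement-weight form

    kappa = 1 - sum(d_ij * o_ij) / sum(d_ij * e_ij)

with observed proportions ``o_ij``, expected-under-independence
proportions ``e_ij = row_i * col_j``, and disagreement weights

    unweighted: d_ij = 1 if i != j else 0
    quadratic:  d_ij = (i - j)^2 / (k - 1)^2

For k = 2 the quadratic weights are identical to the 0/1 weights, so
quadratic-weighted kappa on a 2x2 table equals unweighted kappa.

The p-value tests H0: kappa = 0 with the large-sample standard error of
weighted kappa under the null (Fleiss-Cohen-Everitt form) and a normal
reference, two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .domains import MatchedObservation, ValidationError
from .harmonization import BinaryCell, binarize_pair, collapse_ctcae_grade

#: Sample sizes below this trip the small-sample warning flag on the
#: asymptotic kappa test.
SMALL_SAMPLE_N = 30


class WeightScheme(str, Enum):
    UNWEIGHTED = "unweighted"
    QUADRATIC = "quadratic"


class DegenerateTableError(ValidationError):
    """Kappa is undefined: the expected disagreement is zero."""


def round_half_up(value: float, ndigits: int) -> float:
    """Presentation rounding: round half away from zero, fixed decimals."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """k x k cross-classification; rows = clinician, columns = patient."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValidationError("contingency table must be square")
        if (counts < 0).any():
            raise ValidationError("contingency table counts must be non-negative")
        if counts.sum() < 1:
            raise ValidationError("contingency table must contain at least one pair")
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    scheme: WeightScheme
    n: int
    p_value: Optional[float]
    label: str
    small_sample: bool = False


def build_contingency_table(
    pairs: Iterable[MatchedObservation], mode: str = "ordinal4"
) -> ContingencyTable:
    """Cross-tabulate matched pairs.

    ``mode='ordinal4'``: collapsed grade 0-3 vs severity 1-4 on indices
    0-3.  ``mode='binary'``: none-vs-any on both sides (index 0 = none).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("cannot build a contingency table from zero pairs")
    if mode == "ordinal4":
        counts = np.zeros((4, 4), dtype=np.int64)
        for p in pairs:
            counts[collapse_ctcae_grade(p.ctcae_grade), p.eortc_severity - 1] += 1
    elif mode == "binary":
        counts = np.zeros((2, 2), dtype=np.int64)
        for p in pairs:
            b = binarize_pair(p.ctcae_grade, p.eortc_severity)
            counts[int(b.clinician_any), int(b.patient_any)] += 1
    else:
        raise ValidationError(f"unknown table mode {mode!r}")
    return ContingencyTable(counts)


def disagreement_weights(k: int, scheme: WeightScheme) -> np.ndarray:
    i, j = np.indices((k, k))
    if scheme == WeightScheme.UNWEIGHTED:
        return (i != j).astype(float)
    return (i - j) ** 2 / (k - 1) ** 2


def _kappa_value(table: ContingencyTable, scheme: WeightScheme) -> float:
    o = table.counts / table.n
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    e = np.outer(row, col)
    d = disagreement_weights(table.k, scheme)
    expected_disagreement = float((d * e).sum())
    if expected_disagreement == 0.0:
        raise DegenerateTableError(
            "kappa undefined: degenerate margins give zero expected disagreement"
        )
    return 1.0 - float((d * o).sum()) / expected_disagreement


def kappa_null_se(table: ContingencyTable, scheme: WeightScheme) -> float:
    """Large-sample SE of (weighted) kappa under H0: kappa = 0."""
    o = table.counts / table.n
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    w = 1.0 - disagreement_weights(table.k, scheme)  # agreement weights
    pe = float(row @ w @ col)
    if pe >= 1.0:
        raise DegenerateTableError("null SE undefined: expected agreement is 1")
    w_row = w @ col          # E[w | clinician level i] under independence
    w_col = row @ w          # E[w | patient level j] under independence
    outer = np.outer(row, col)
    var = (outer * (w - (w_row[:, None] + w_col[None, :])) ** 2).sum() - pe**2
    return float(np.sqrt(var / table.n) / (1.0 - pe))


def kappa_p_value(table: ContingencyTable, scheme: WeightScheme) -> float:
    """Two-sided asymptotic p-value for H0: kappa = 0."""
    kappa = _kappa_value(table, scheme)
    se = kappa_null_se(table, scheme)
    if se == 0.0:
        return 1.0 if kappa == 0.0 else 0.0
    z = kappa / se
    return float(2.0 * stats.norm.sf(abs(z)))


def interpret_kappa(kappa: float) -> str:
    """Conventional interpretation bands on the 2-dp rounded kappa."""
    if not -1.0 <= kappa <= 1.0 + 1e-12:
        raise ValidationError(f"kappa must lie in [-1, 1], got {kappa!r}")
    k = round_half_up(kappa, 2)
    if k < 0.21:
        return "no agreement"
    if k < 0.40:
        return "minimal"
    if k < 0.60:
        return "weak"
    if k < 0.80:
        return "moderate"
    if k <= 0.90:
        return "strong"
    return "almost perfect"


def cohen_kappa(
    table: ContingencyTable, scheme: WeightScheme = WeightScheme.QUADRATIC
) -> KappaResult:
    """Cohen's kappa with the requested weighting and a null-test p-value.

    Requires at least two occupied levels in both margins; degenerate
    tables raise :class:`DegenerateTableError` rather than returning 0
    or NaN silently.
    """
    scheme = WeightScheme(scheme)
    kappa = _kappa_value(table, scheme)
    p = kappa_p_value(table, scheme)
    return KappaResult(
        kappa=kappa,
        scheme=scheme,
        n=table.n,
        p_value=p,
        label=interpret_kappa(kappa),
        small_sample=table.n < SMALL_SAMPLE_N,
    )


def binary_concordance_summary(pairs: Iterable[MatchedObservation]) -> dict:
    """One binary-analysis report row: four cells, percentages, kappa.

    Percentages are computed on the domain-specific matched n and
    rounded to one decimal place, kappa to two.
    """
    pairs = list(pairs)
    table = build_contingency_table(pairs, mode="binary")
    n = table.n
    cells = {
        BinaryCell.NEITHER.value: int(table.counts[0, 0]),
        BinaryCell.CLINICIAN_ONLY.value: int(table.counts[1, 0]),
        BinaryCell.PATIENT_ONLY.value: int(table.counts[0, 1]),
        BinaryCell.BOTH.value: int(table.counts[1, 1]),
    }
    row = {"n": n}
    for name, count in cells.items():
        row[name] = count
        row[f"{name}_pct"] = round_half_up(100.0 * count / n, 1)
    try:
        result = cohen_kappa(table, WeightScheme.UNWEIGHTED)
        row["kappa"] = round_half_up(result.kappa, 2)
        row["kappa_label"] = result.label
        row["p_value"] = result.p_value
    except DegenerateTableError:
        row["kappa"] = None
        row["kappa_label"] = "undefined"
        row["p_value"] = None
    return row
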