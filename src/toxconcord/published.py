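"""Published binary concordance counts used as reference inputs.

These are the complete 2x2 cell counts of the none-vs-any analysis
reported for a randomized phase III adjuvant breast-cancer chemotherapy
trial (two arms, mid- and end-of-treatment, six symptom domains),
together with the unweighted kappa printed alongside them.  They let
the binary-analysis pathway be validated end-to-end against published
numbers: reconstructing per-patient pairs from the cells and running
the pipeline must reproduce the printed kappa (2 dp) and cell
percentages (1 dp).

Cell order: (neither, clinician_only, patient_only, both).
"""

from __future__ import annotations

from dataclasses import dataclass

from .domains import Arm, MatchedObservation, Timepoint, get_domain


@dataclass(frozen=True)
class PublishedBinaryRow:
    domain: str
    arm: str
    timepoint: str
    neither: int
    clinician_only: int
    patient_only: int
    both: int
    kappa: float  # printed, 2 dp
    pct: tuple[float, float, float, float]  # printed cell percentages, 1 dp

    @property
    def n(self) -> int:
        return self.neither + self.clinician_only + self.patient_only + self.both

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.neither, self.clinician_only, self.patient_only, self.both)


# One printed percentage (diarrhea, arm B, end-of-treatment, "both")
# appears as 11.1 although 78/696 = 11.2%; the count, which is what the
# statistics consume, is internally consistent (the row sums to 696).
_ROWS = [
    # domain, arm, timepoint, neither, clin_only, pat_only, both, kappa, pcts
    ("diarrhea", "A", "mid", 495, 27, 95, 49, 0.35, (74.3, 4.1, 14.3, 7.4)),
    ("nausea", "A", "mid", 149, 76, 155, 287, 0.29, (22.3, 11.4, 23.2, 43.0)),
    ("vomiting", "A", "mid", 522, 55, 64, 30, 0.23, (77.8, 8.2, 9.5, 4.5)),
    ("mucositis", "A", "mid", 95, 37, 265, 267, 0.13, (14.3, 5.6, 39.9, 40.2)),
    ("fatigue", "A", "mid", 38, 73, 129, 413, 0.09, (5.8, 11.2, 19.8, 63.2)),
    ("pain", "A", "mid", 310, 95, 145, 108, 0.20, (47.1, 14.4, 22.0, 16.4)),
    ("diarrhea", "B", "mid", 504, 46, 114, 41, 0.21, (71.5, 6.5, 16.2, 5.8)),
    ("nausea", "B", "mid", 206, 182, 98, 219, 0.22, (29.2, 25.8, 13.9, 31.1)),
    ("vomiting", "B", "mid", 573, 69, 41, 26, 0.24, (80.8, 9.7, 5.8, 3.7)),
    ("mucositis", "B", "mid", 150, 54, 303, 197, 0.09, (21.3, 7.7, 43.0, 28.0)),
    ("fatigue", "B", "mid", 104, 116, 165, 313, 0.12, (14.9, 16.6, 23.6, 44.8)),
    ("pain", "B", "mid", 365, 108, 153, 71, 0.09, (52.4, 15.5, 22.0, 10.2)),
    ("diarrhea", "A", "end", 326, 26, 147, 88, 0.33, (55.5, 4.4, 25.0, 15.0)),
    ("nausea", "A", "end", 378, 37, 121, 54, 0.25, (64.1, 6.3, 20.5, 9.2)),
    ("vomiting", "A", "end", 551, 8, 23, 7, 0.29, (93.5, 1.4, 3.9, 1.2)),
    ("mucositis", "A", "end", 49, 23, 289, 225, 0.05, (8.4, 3.9, 49.3, 38.4)),
    ("fatigue", "A", "end", 26, 42, 130, 385, 0.08, (4.5, 7.2, 22.3, 66.0)),
    ("pain", "A", "end", 131, 73, 152, 225, 0.22, (22.5, 12.6, 26.2, 38.7)),
    ("diarrhea", "B", "end", 421, 48, 149, 78, 0.27, (60.5, 6.9, 21.4, 11.1)),
    ("nausea", "B", "end", 487, 39, 115, 57, 0.30, (69.8, 5.6, 16.5, 8.2)),
    ("vomiting", "B", "end", 649, 12, 30, 8, 0.25, (92.8, 1.7, 4.3, 1.1)),
    ("mucositis", "B", "end", 106, 64, 300, 218, 0.03, (15.4, 9.3, 43.6, 31.7)),
    ("fatigue", "B", "end", 61, 69, 151, 408, 0.16, (8.9, 10.0, 21.9, 59.2)),
    ("pain", "B", "end", 165, 178, 135, 209, 0.09, (24.0, 25.9, 19.7, 30.4)),
]

PUBLISHED_BINARY_ROWS: tuple[PublishedBinaryRow, ...] = tuple(
    PublishedBinaryRow(*row) for row in _ROWS
)


def reconstruct_pairs(row: PublishedBinaryRow) -> list[MatchedObservation]:
    """Expand one published 2x2 row into per-patient matched pairs.

    The binary statistics depend only on the none-vs-any status, so a
    representative grade/severity is assigned per cell: none -> grade 0
    / severity 1, any -> grade 1 / severity 2.
    """
    domain = get_domain(row.domain)
    arm = Arm(row.arm)
    tp = Timepoint(row.timepoint)
    cells = [
        (row.neither, 0, 1),
        (row.clinician_only, 1, 1),
        (row.patient_only, 0, 2),
        (row.both, 1, 2),
    ]
    pairs: list[MatchedObservation] = []
    i = 0
    for count, grade, severity in cells:
        for _ in range(count):
            i += 1
            pairs.append(
                MatchedObservation(f"R{i:04d}", arm, tp, domain, grade, severity)
            )
    return pairs
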