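"""Long-format CSV readers and writers for the two instrument tables.

Layouts (UTF-8, comma-separated, header row required):

* clinician table: ``patient_id,arm,timepoint,domain,grade``
* patient table:   ``patient_id,timepoint,item_id,response``

Missing values are encoded as empty cells.  Sentinel codes (9, 99, ...)
are rejected by range validation rather than silently treated as
missing; duplicated keys are a hard error.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .domains import (
    Arm,
    CtcaeRecord,
    EortcResponse,
    Timepoint,
    ValidationError,
    get_domain,
)

CTCAE_COLUMNS = ["patient_id", "arm", "timepoint", "domain", "grade"]
EORTC_COLUMNS = ["patient_id", "timepoint", "item_id", "response"]


def _read_csv(path: Union[str, Path], columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {missing}; header must name {columns}"
        )
    return df


def _parse_int(value: str, row: int, path: Path, what: str) -> Optional[int]:
    value = value.strip()
    if value == "":
        return None
    try:
        return int(value)
    except ValueError:
        raise ValidationError(
            f"{path}, row {row}: {what} must be an integer or empty, got {value!r}"
        ) from None


def _check_duplicates(df: pd.DataFrame, keys: list[str], path: Path) -> None:
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].to_dict()
        raise ValidationError(
            f"{path}: duplicated key {first} — one record per {tuple(keys)} required"
        )


def read_ctcae_table(path: Union[str, Path]) -> list[CtcaeRecord]:
    """Read clinician CTCAE records from a long-format CSV."""
    path = Path(path)
    df = _read_csv(path, CTCAE_COLUMNS)
    _check_duplicates(df, ["patient_id", "timepoint", "domain"], path)
    records: list[CtcaeRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            domain = get_domain(row.domain.strip())
            rec = CtcaeRecord(
                patient_id=row.patient_id.strip(),
                arm=Arm(row.arm.strip()),
                timepoint=Timepoint(row.timepoint.strip()),
                domain=domain,
                grade=_parse_int(row.grade, i, path, "grade"),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from None
        records.append(rec)
    return records


def read_eortc_responses(path: Union[str, Path]) -> list[EortcResponse]:
    """Read patient EORTC item responses from a long-format CSV."""
    path = Path(path)
    df = _read_csv(path, EORTC_COLUMNS)
    _check_duplicates(df, ["patient_id", "timepoint", "item_id"], path)
    records: list[EortcResponse] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = EortcResponse(
                patient_id=row.patient_id.strip(),
                timepoint=Timepoint(row.timepoint.strip()),
                item_id=row.item_id.strip(),
                response=_parse_int(row.response, i, path, "response"),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from None
        records.append(rec)
    return records


def write_ctcae_table(records: Iterable[CtcaeRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "arm": r.arm.value,
            "timepoint": r.timepoint.value,
            "domain": r.domain.name,
            "grade": "" if r.grade is None else r.grade,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CTCAE_COLUMNS).to_csv(path, index=False)


def write_eortc_responses(
    records: Iterable[EortcResponse], path: Union[str, Path]
) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "timepoint": r.timepoint.value,
            "item_id": r.item_id,
            "response": "" if r.response is None else r.response,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=EORTC_COLUMNS).to_csv(path, index=False)
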