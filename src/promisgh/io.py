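"""CSV dialects for respondent data and truth files.

Respondent CSV: header ``respondent_id,age,gender,education,region,
ethnicity,global01,...,global10``; an empty cell is a missing response.
Validation is strict and errors carry row numbers.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import pandas as pd

from promisgh.instrument import (
    ITEM_IDS,
    InstrumentError,
    InstrumentSpec,
    ResponseRecord,
    load_default_instrument,
)

_DEMO_COLS = ("respondent_id", "age", "gender", "education", "region", "ethnicity")
_ITEM_COLS = tuple(i.lower() for i in ITEM_IDS)
HEADER = _DEMO_COLS + _ITEM_COLS


class ResponseFileError(ValueError):
    pass


def read_responses(
    path: str | Path, spec: InstrumentSpec | None = None
) -> list[ResponseRecord]:
    """Read and validate a respondent CSV; raises with row context."""
    spec = spec or load_default_instrument()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ResponseFileError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != HEADER:
            raise ResponseFileError(
                f"{path}: malformed header; expected {','.join(HEADER)}"
            )
        records: list[ResponseRecord] = []
        seen: set[str] = set()
        errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(HEADER):
                errors.append(f"row {lineno}: {len(row)} fields, expected {len(HEADER)}")
                continue
            rid = row[0].strip()
            if rid in seen:
                errors.append(f"row {lineno}: duplicate respondent id {rid!r}")
                continue
            try:
                age = int(row[1])
            except ValueError:
                errors.append(f"row {lineno}: non-integer age {row[1]!r}")
                continue
            responses = {}
            row_ok = True
            for item_id, cell in zip(ITEM_IDS, row[len(_DEMO_COLS):]):
                cell = cell.strip()
                if cell == "":
                    responses[item_id] = None
                    continue
                try:
                    responses[item_id] = int(cell)
                except ValueError:
                    errors.append(f"row {lineno}: non-integer value {cell!r} for {item_id}")
                    row_ok = False
            if not row_ok:
                continue
            try:
                rec = ResponseRecord(
                    respondent_id=rid,
                    age=age,
                    gender=row[2].strip() or None,
                    education=row[3].strip() or None,
                    region=row[4].strip() or None,
                    ethnicity=row[5].strip() or None,
                    raw_responses=responses,
                )
                rec.validate_against(spec)
            except InstrumentError as exc:
                errors.append(f"row {lineno}: {exc}")
                continue
            seen.add(rid)
            records.append(rec)
        if errors:
            raise ResponseFileError(
                f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors[:20])
            )
    return records


def write_responses(records: Sequence[ResponseRecord], path: str | Path) -> None:
    """Write records in the respondent CSV dialect (missing -> empty cell)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(HEADER)
        for r in records:
            writer.writerow(
                [
                    r.respondent_id,
                    r.age,
                    r.gender or "",
                    r.education or "",
                    r.region or "",
                    r.ethnicity or "",
                ]
                + [
                    "" if r.raw_responses.get(i) is None else r.raw_responses[i]
                    for i in ITEM_IDS
                ]
            )


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
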