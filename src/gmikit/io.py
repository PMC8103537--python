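"""Delimited-text ingest and export of patient records.

The canonical dialect is one row per therapy line, UTF-8, header required.
The index (trial) therapy is the row with ``line_number == 0``; prior
systemic lines use ``line_number >= 1``.  Dates are ISO-8601 with ``??`` for
missing month/day components (prior lines only; index dates must be
complete).  Columns:

=====================  =====================================================
patient_id             opaque string, groups rows into one patient
tumour_type            free text (index row)
line_number            0 for the index therapy, 1..k for prior lines
category               prior-line therapy class (see TherapyCategory)
start_date             ISO date, partial allowed on prior lines
end_date               ISO date, partial allowed; empty if index ongoing
ongoing                true/false (index row only)
best_response          CR | PR | SD | PD | non_CR_non_PD | NE | unknown
discontinuation_reason prior lines: primary_resistance | progressive_disease
                       | toxicity | course_completed | other
progression_date       optional ISO date on prior lines
pfs_event_date         index row: progression/death date (or empty)
pfs_censor_date        index row: censoring date (or empty)
cns_metastases         true/false (index row)
=====================  =====================================================
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

from .dates import PartialDate, PartialDateError
from .records import (
    DiscontinuationReason,
    PatientRecord,
    RecordValidationError,
    ResponseCategory,
    TherapyCategory,
    TherapyLine,
)

__all__ = ["COLUMNS", "read_patients", "write_patients", "SchemaError"]

logger = logging.getLogger(__name__)

COLUMNS = [
    "patient_id",
    "tumour_type",
    "line_number",
    "category",
    "start_date",
    "end_date",
    "ongoing",
    "best_response",
    "discontinuation_reason",
    "progression_date",
    "pfs_event_date",
    "pfs_censor_date",
    "cns_metastases",
]

_RESPONSE_TOKENS = {c.value: c for c in ResponseCategory}
_CATEGORY_TOKENS = {c.value: c for c in TherapyCategory}
_REASON_TOKENS = {c.value: c for c in DiscontinuationReason}


class SchemaError(ValueError):
    """The input file does not conform to the documented column schema."""


def _token(
    raw: str, vocab: Dict[str, object], what: str, row: int
) -> object:
    raw = raw.strip()
    if raw not in vocab:
        raise SchemaError(
            f"row {row}: unknown {what} {raw!r}; allowed: "
            + ", ".join(sorted(vocab))
        )
    return vocab[raw]


def _bool(raw: str, row: int, col: str) -> bool:
    v = raw.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise SchemaError(f"row {row}: column {col} must be true/false, got {raw!r}")


def _partial(raw: str, row: int, col: str) -> Optional[PartialDate]:
    raw = raw.strip()
    if not raw:
        return None
    try:
        return PartialDate.parse(raw)
    except PartialDateError as exc:
        raise SchemaError(f"row {row}: column {col}: {exc}") from exc


def _full_date(raw: str, row: int, col: str):
    pd_ = _partial(raw, row, col)
    if pd_ is None:
        return None
    if not pd_.is_complete:
        raise SchemaError(
            f"row {row}: column {col} must be a complete date, got {raw!r}"
        )
    return pd_.to_date()


def read_patients(path: Union[str, Path]) -> List[PatientRecord]:
    """Read and validate patient records from the canonical CSV dialect.

    Rows failing invariants are reported with their 1-based row number
    (header is row 1).  Records whose dates lack even a year are excluded
    with a logged warning.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError("empty file: header row required")
        missing = [c for c in COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        by_patient: Dict[str, Dict[str, object]] = {}
        order: List[str] = []
        for i, row in enumerate(reader, start=2):
            pid = row["patient_id"].strip()
            if not pid:
                raise SchemaError(f"row {i}: empty patient_id")
            if pid not in by_patient:
                by_patient[pid] = {"index": None, "priors": []}
                order.append(pid)
            try:
                line_no = int(row["line_number"])
            except ValueError as exc:
                raise SchemaError(
                    f"row {i}: line_number must be an integer, got "
                    f"{row['line_number']!r}"
                ) from exc
            if line_no == 0:
                by_patient[pid]["index"] = (i, row)
            else:
                by_patient[pid]["priors"].append((i, line_no, row))

    patients: List[PatientRecord] = []
    for pid in order:
        entry = by_patient[pid]
        if entry["index"] is None:
            raise SchemaError(
                f"patient {pid}: no index-therapy row (line_number=0)"
            )
        i, idx = entry["index"]
        rec = PatientRecord(
            patient_id=pid,
            tumour_type=idx["tumour_type"].strip(),
            index_start=_full_date(idx["start_date"], i, "start_date"),
            index_end=_full_date(idx["end_date"], i, "end_date"),
            index_ongoing=_bool(idx["ongoing"], i, "ongoing"),
            index_pfs_event_date=_full_date(
                idx["pfs_event_date"], i, "pfs_event_date"
            ),
            index_pfs_censor_date=_full_date(
                idx["pfs_censor_date"], i, "pfs_censor_date"
            ),
            index_best_response=_token(
                idx["best_response"], _RESPONSE_TOKENS, "best_response", i
            ),
            cns_metastases=_bool(idx["cns_metastases"], i, "cns_metastases"),
        )
        if rec.index_start is None:
            raise SchemaError(f"row {i}: index start_date is required")
        for j, line_no, row in sorted(entry["priors"], key=lambda t: t[1]):
            start = _partial(row["start_date"], j, "start_date")
            end = _partial(row["end_date"], j, "end_date")
            if start is None or end is None:
                logger.warning(
                    "row %d (patient %s, line %d): date missing entirely "
                    "(no year); line excluded",
                    j, pid, line_no,
                )
                continue
            reason_raw = row["discontinuation_reason"].strip()
            reason = (
                _token(reason_raw, _REASON_TOKENS, "discontinuation_reason", j)
                if reason_raw
                else None
            )
            line = TherapyLine(
                line_number=line_no,
                category=_token(
                    row["category"], _CATEGORY_TOKENS, "category", j
                ),
                start=start,
                end=end,
                best_response=_token(
                    row["best_response"], _RESPONSE_TOKENS, "best_response", j
                ),
                discontinuation_reason=reason,
                progression_date=_partial(
                    row["progression_date"], j, "progression_date"
                ),
            )
            rec.prior_lines.append(line)
        try:
            rec.validate()
        except RecordValidationError as exc:
            raise SchemaError(f"row {i} (patient {pid}): {exc}") from exc
        patients.append(rec)
    return patients


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, PartialDate):
        return value.isoformat()
    if hasattr(value, "isoformat"):
        return value.isoformat()
    if hasattr(value, "value"):
        return value.value
    return str(value)


def write_patients(
    patients: Iterable[PatientRecord],
    path: Union[str, Path],
    extra_columns: Optional[Dict[str, Dict[str, str]]] = None,
) -> None:
    """Write records in the canonical dialect (inverse of read_patients).

    ``extra_columns`` maps column name -> {patient_id: value}; used e.g. to
    append a cohort_label column to a validated-cohort export.
    """
    extra = extra_columns or {}
    cols = COLUMNS + list(extra)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for p in patients:
            tail = [extra[c].get(p.patient_id, "") for c in extra]
            writer.writerow(
                [
                    p.patient_id,
                    p.tumour_type,
                    0,
                    "",
                    _fmt(p.index_start),
                    _fmt(p.index_end),
                    _fmt(p.index_ongoing),
                    _fmt(p.index_best_response),
                    "",
                    "",
                    _fmt(p.index_pfs_event_date),
                    _fmt(p.index_pfs_censor_date),
                    _fmt(p.cns_metastases),
                ]
                + tail
            )
            for line in p.prior_lines:
                writer.writerow(
                    [
                        p.patient_id,
                        p.tumour_type,
                        line.line_number,
                        _fmt(line.category),
                        _fmt(line.start),
                        _fmt(line.end),
                        "",
                        _fmt(line.best_response),
                        _fmt(line.discontinuation_reason),
                        _fmt(line.progression_date),
                        "",
                        "",
                        "",
                    ]
                    + tail
                )
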