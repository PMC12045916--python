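"""Radiology-order records: data model, delimited-file I/O, deduplication.

Files are header-first delimited text (comma by default, tab selectable),
UTF-8 with replacement on decode errors. Canonical columns: ``scan_id``,
``patient_id``, ``exam_date`` (ISO 8601), ``cpt_codes`` (semicolon-separated
within the cell), ``setting`` (outpatient/ed/inpatient), ``procedure_name``,
``reason_for_exam``, ``clinical_history``, ``sampling_weight``,
``lcs_eligible``, ``gold_label``. A column mapping adapts foreign headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RadiologyOrder",
    "SETTINGS",
    "GOLD_LABELS",
    "SchemaError",
    "RowError",
    "OrderValidationError",
    "read_orders",
    "write_orders",
    "deduplicate",
]

logger = logging.getLogger(__name__)

SETTINGS = ("outpatient", "ed", "inpatient")
GOLD_LABELS = ("screening", "non_screening", "unknown")

REQUIRED_COLUMNS = ("scan_id", "patient_id", "exam_date", "cpt_codes", "setting")
OPTIONAL_COLUMNS = (
    "procedure_name",
    "reason_for_exam",
    "clinical_history",
    "sampling_weight",
    "lcs_eligible",
    "gold_label",
)
ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS


class SchemaError(ValueError):
    """A required column is missing from the input file."""


@dataclass(frozen=True)
class RowError:
    row: int  # 1-based data-row number (header not counted)
    message: str


class OrderValidationError(ValueError):
    """One or more rows failed validation; carries every row's error."""

    def __init__(self, errors: Sequence[RowError]):
        self.errors = list(errors)
        lines = "; ".join(f"row {e.row}: {e.message}" for e in self.errors[:20])
        more = "" if len(self.errors) <= 20 else f" (+{len(self.errors) - 20} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


@dataclass(frozen=True)
class RadiologyOrder:
    """One imaging study as ordered.

    ``sampling_weight`` defaults to 1 (self-weighting). ``lcs_eligible`` and
    ``gold_label`` are supplied externally when available; the classifier
    never reads them.
    """

    scan_id: str
    patient_id: str
    exam_date: date
    cpt_codes: frozenset[str]
    setting: str
    procedure_name: str = ""
    reason_for_exam: str = ""
    clinical_history: str = ""
    sampling_weight: float = 1.0
    lcs_eligible: bool | None = None
    gold_label: str | None = None

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}, got {self.setting!r}")
        if not self.cpt_codes:
            raise ValueError("cpt_codes must contain at least one code")
        if not self.sampling_weight > 0:
            raise ValueError(f"sampling_weight must be > 0, got {self.sampling_weight}")
        if self.gold_label is not None and self.gold_label not in GOLD_LABELS:
            raise ValueError(f"gold_label must be one of {GOLD_LABELS}, got {self.gold_label!r}")


def _parse_row(row: Mapping[str, str], rownum: int, errors: list[RowError]) -> RadiologyOrder | None:
    def fail(msg: str) -> None:
        errors.append(RowError(rownum, msg))

    try:
        exam_date = date.fromisoformat(row["exam_date"].strip())
    except ValueError:
        fail(f"unparseable exam_date {row['exam_date']!r}")
        return None
    cpt = frozenset(c.strip() for c in row["cpt_codes"].split(";") if c.strip())
    if not cpt:
        fail("cpt_codes is empty")
        return None
    setting = row["setting"].strip().lower()
    if setting not in SETTINGS:
        fail(f"setting {row['setting']!r} not one of {SETTINGS}")
        return None
    weight_raw = row.get("sampling_weight", "").strip()
    weight = 1.0
    if weight_raw:
        try:
            weight = float(weight_raw)
        except ValueError:
            fail(f"sampling_weight {weight_raw!r} is not a number")
            return None
        if not weight > 0:
            fail(f"sampling_weight must be > 0, got {weight_raw!r}")
            return None
    eligible_raw = row.get("lcs_eligible", "").strip().lower()
    eligible: bool | None = None
    if eligible_raw:
        if eligible_raw in ("true", "1", "yes"):
            eligible = True
        elif eligible_raw in ("false", "0", "no"):
            eligible = False
        else:
            fail(f"lcs_eligible {eligible_raw!r} is not a boolean")
            return None
    gold_raw = row.get("gold_label", "").strip().lower()
    gold: str | None = gold_raw or None
    if gold is not None and gold not in GOLD_LABELS:
        fail(f"gold_label {gold_raw!r} not one of {GOLD_LABELS}")
        return None
    return RadiologyOrder(
        scan_id=row["scan_id"].strip(),
        patient_id=row["patient_id"].strip(),
        exam_date=exam_date,
        cpt_codes=cpt,
        setting=setting,
        procedure_name=row.get("procedure_name", ""),
        reason_for_exam=row.get("reason_for_exam", ""),
        clinical_history=row.get("clinical_history", ""),
        sampling_weight=weight,
        lcs_eligible=eligible,
        gold_label=gold,
    )


def read_orders(
    path: str | Path,
    mapping: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[RadiologyOrder]:
    """Read one :class:`RadiologyOrder` per data row.

    ``mapping`` translates canonical column names to the file's headers
    (e.g. ``{"scan_id": "AccessionNo"}``); unmapped canonical names are
    looked up verbatim. Missing optional columns yield defaults. Rows that
    fail validation are collected and reported together via
    :class:`OrderValidationError`, never silently dropped.
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
        encoding_errors="replace",
    )
    mapping = dict(mapping or {})
    colmap = {canon: mapping.get(canon, canon) for canon in ALL_COLUMNS}
    missing = [colmap[c] for c in REQUIRED_COLUMNS if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing} (have {list(df.columns)})")

    orders: list[RadiologyOrder] = []
    errors: list[RowError] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        row = {canon: str(rec.get(col, "")) for canon, col in colmap.items()}
        order = _parse_row(row, i, errors)
        if order is not None:
            orders.append(order)
    if errors:
        raise OrderValidationError(errors)
    logger.info("read %d orders from %s", len(orders), path)
    return orders


def write_orders(orders: Iterable[RadiologyOrder], path: str | Path, delimiter: str = ",") -> None:
    """Write orders as delimited text using the canonical columns; inverse of
    :func:`read_orders` for well-formed data."""
    rows = []
    for o in orders:
        rows.append(
            {
                "scan_id": o.scan_id,
                "patient_id": o.patient_id,
                "exam_date": o.exam_date.isoformat(),
                "cpt_codes": ";".join(sorted(o.cpt_codes)),
                "setting": o.setting,
                "procedure_name": o.procedure_name,
                "reason_for_exam": o.reason_for_exam,
                "clinical_history": o.clinical_history,
                "sampling_weight": repr(o.sampling_weight),
                "lcs_eligible": "" if o.lcs_eligible is None else str(o.lcs_eligible).lower(),
                "gold_label": o.gold_label or "",
            }
        )
    pd.DataFrame(rows, columns=list(ALL_COLUMNS)).to_csv(path, sep=delimiter, index=False)


def deduplicate(orders: Sequence[RadiologyOrder]) -> tuple[list[RadiologyOrder], int]:
    """Collapse orders sharing (patient_id, exam_date, cpt_codes,
    procedure_name) to the first occurrence, preserving input order.

    Returns the deduplicated list and the number removed. The key is the most
    conservative one that cannot merge two distinct same-day studies of a
    different type; every removal is logged.
    """
    seen: set[tuple] = set()
    kept: list[RadiologyOrder] = []
    removed = 0
    for o in orders:
        key = (o.patient_id, o.exam_date, o.cpt_codes, o.procedure_name)
        if key in seen:
            removed += 1
            logger.info("removing duplicate scan %s (patient %s, %s)", o.scan_id, o.patient_id, o.exam_date)
            continue
        seen.add(key)
        kept.append(o)
    return kept, removed
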