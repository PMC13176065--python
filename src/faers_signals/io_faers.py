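"""Reading/writing FAERS-dialect ASCII tables and the FDA deduplication protocol.

The public FAERS quarterly files are ``$``-delimited text with a single header
line. Spontaneous reports are versioned: the same case may appear once per
quarter as follow-up information arrives, so any analysis starts by keeping a
single version per case — the one with the most recent FDA receipt date,
breaking ties by the highest PRIMARYID.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from pathlib import Path
from typing import Iterable, List, Sequence, Union

from .records import (
    DrugEntry,
    PartialDate,
    ReactionEntry,
    ReportRecord,
    TherapyEntry,
)

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: Required columns per table kind, in canonical write order.
SCHEMAS = {
    "DEMO": [
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "occp_cod",
        "reporter_country",
    ],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "pt"],
    "THER": ["primaryid", "dsg_drug_seq", "start_dt"],
}

AnyRecord = Union[ReportRecord, DrugEntry, ReactionEntry, TherapyEntry]


class FaersFormatError(ValueError):
    """Raised when a FAERS table file violates the expected layout."""


def _opt(value: str) -> str | None:
    value = value.strip()
    return value if value else None


def _parse_partial(value: str, where: str) -> PartialDate | None:
    try:
        return PartialDate.parse(value)
    except ValueError:
        logger.warning("unparseable date %r in %s; treated as missing", value, where)
        return None


def _parse_float(value: str, where: str) -> float | None:
    value = value.strip()
    if not value:
        return None
    try:
        return float(value)
    except ValueError:
        logger.warning("non-numeric value %r in %s; treated as missing", value, where)
        return None


def read_table(path: str | Path, schema: str, quarter: str | None = None) -> List[AnyRecord]:
    """Read one FAERS-dialect table.

    Parameters
    ----------
    path
        ``$``-delimited text file whose first line is the header.
    schema
        One of ``DEMO``, ``DRUG``, ``REAC``, ``THER``.
    quarter
        Optional source-quarter label stamped onto DEMO records.

    Unknown columns are preserved in each record's ``extra`` mapping; missing
    fields become ``None`` (never empty-string sentinels). Unparseable dates
    are logged and set to missing — the row is kept.
    """
    schema = schema.upper()
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    required = SCHEMAS[schema]
    path = Path(path)
    records: List[AnyRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=DELIMITER)
        try:
            header = next(reader)
        except StopIteration:
            raise FaersFormatError(f"{path}: empty file, expected a header line")
        header = [h.strip().lower() for h in header]
        missing = [col for col in required if col not in header]
        if missing:
            raise FaersFormatError(
                f"{path}: malformed header, missing required column(s) {', '.join(missing)}"
            )
        extra_cols = [h for h in header if h not in required]
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                row = row + [""] * (len(header) - len(row))
            fields = dict(zip(header, row))
            where = f"{path.name}:{lineno}"
            extra = {c: _opt(fields[c]) for c in extra_cols}
            records.append(_build_record(schema, fields, extra, where, quarter))
    return records


def _build_record(schema, fields, extra, where, quarter) -> AnyRecord:
    if schema == "DEMO":
        fda = _parse_partial(fields["fda_dt"], where)
        if fda is None or not fda.is_complete:
            raise FaersFormatError(
                f"{where}: fda_dt {fields['fda_dt']!r} is not a complete valid date"
            )
        return ReportRecord(
            primary_id=fields["primaryid"].strip(),
            case_id=fields["caseid"].strip(),
            fda_receipt_date=fda.to_date(),
            event_date=_parse_partial(fields["event_dt"], where),
            sex=_opt(fields["sex"]),
            age_value=_parse_float(fields["age"], where),
            age_code=_opt(fields["age_cod"]),
            occupation_code=_opt(fields["occp_cod"]),
            reporter_country=_opt(fields["reporter_country"]),
            report_quarter=extra.pop("quarter", None) or quarter,
            extra=extra,
        )
    if schema == "DRUG":
        return DrugEntry(
            primary_id=fields["primaryid"].strip(),
            drug_seq=fields["drug_seq"].strip(),
            drug_name=_opt(fields["drugname"]),
            active_ingredient=_opt(fields["prod_ai"]),
            role_code=_opt(fields["role_cod"]),
            extra=extra,
        )
    if schema == "REAC":
        return ReactionEntry(
            primary_id=fields["primaryid"].strip(),
            pt=fields["pt"].strip(),
            extra=extra,
        )
    return TherapyEntry(
        primary_id=fields["primaryid"].strip(),
        drug_seq=fields["dsg_drug_seq"].strip(),
        start_date=_parse_partial(fields["start_dt"], where),
        extra=extra,
    )


def _emit_fields(record: AnyRecord, schema: str) -> dict:
    def date_str(d) -> str:
        if d is None:
            return ""
        if isinstance(d, _dt.date):
            return f"{d.year:04d}{d.month:02d}{d.day:02d}"
        return d.faers_str()

    def s(v) -> str:
        return "" if v is None else str(v)

    def num(v) -> str:
        if v is None:
            return ""
        return str(int(v)) if float(v).is_integer() else repr(float(v))

    if schema == "DEMO":
        return {
            "primaryid": record.primary_id,
            "caseid": record.case_id,
            "fda_dt": date_str(record.fda_receipt_date),
            "event_dt": date_str(record.event_date),
            "age": num(record.age_value),
            "age_cod": s(record.age_code),
            "sex": s(record.sex),
            "occp_cod": s(record.occupation_code),
            "reporter_country": s(record.reporter_country),
        }
    if schema == "DRUG":
        return {
            "primaryid": record.primary_id,
            "drug_seq": record.drug_seq,
            "role_cod": s(record.role_code),
            "drugname": s(record.drug_name),
            "prod_ai": s(record.active_ingredient),
        }
    if schema == "REAC":
        return {"primaryid": record.primary_id, "pt": record.pt}
    return {
        "primaryid": record.primary_id,
        "dsg_drug_seq": record.drug_seq,
        "start_dt": date_str(record.start_date),
    }


def write_table(records: Sequence[AnyRecord], path: str | Path, schema: str) -> Path:
    """Write records of one schema as a ``$``-delimited FAERS-dialect file.

    ``read_table(write_table(x))`` is the identity on the typed fields.
    """
    schema = schema.upper()
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    columns = list(SCHEMAS[schema])
    extra_cols: List[str] = []
    for rec in records:
        for key in rec.extra:
            if key not in extra_cols:
                extra_cols.append(key)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=DELIMITER, lineterminator="\n")
        writer.writerow(columns + extra_cols)
        for rec in records:
            fields = _emit_fields(rec, schema)
            row = [fields[c] for c in columns]
            row += ["" if rec.extra.get(c) is None else str(rec.extra.get(c)) for c in extra_cols]
            writer.writerow(row)
    return path


def _primary_id_key(pid: str, numeric: bool):
    return int(pid) if numeric else pid


def deduplicate(reports: Iterable[ReportRecord]) -> List[ReportRecord]:
    """Keep one version per case: latest FDA receipt date, then highest PRIMARYID.

    PRIMARYIDs are compared numerically when every contender is all-digits,
    else lexicographically. Output is sorted by ``case_id`` (numeric-aware) so
    downstream results are order-independent. Idempotent.
    """
    by_case: dict[str, List[ReportRecord]] = {}
    for rec in reports:
        by_case.setdefault(rec.case_id, []).append(rec)
    survivors: List[ReportRecord] = []
    for case_id, group in by_case.items():
        numeric = all(r.primary_id.isdigit() for r in group)
        best = max(
            group,
            key=lambda r: (r.fda_receipt_date, _primary_id_key(r.primary_id, numeric)),
        )
        survivors.append(best)
    survivors.sort(key=lambda r: (int(r.case_id) if r.case_id.isdigit() else -1, r.case_id))
    return survivors
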