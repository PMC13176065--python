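"""Core record types for FAERS-style spontaneous report tables.

FAERS quarterly extracts split each safety report across four ASCII tables:
DEMO (one row per report version, with demographics and receipt dates),
DRUG (one row per reported drug, with a suspect/concomitant role code),
REAC (one row per MedDRA Preferred Term) and THER (therapy start dates per
drug). Dates in FAERS are frequently partial — a bare year or year-month —
and the types here keep that partiality explicit rather than imputing.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

#: FAERS drug role codes: primary suspect, secondary suspect, concomitant,
#: interacting.
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: FAERS age unit codes.
AGE_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date that may lack month and/or day (FAERS allows
    YYYY, YYYYMM and YYYYMMDD)."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.year <= 9999:
            raise ValueError(f"year out of range: {self.year}")
        if self.month is None and self.day is not None:
            raise ValueError("day given without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # delegate day-of-month validation to datetime
            _dt.date(self.year, self.month, self.day)

    @property
    def is_complete(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> _dt.date:
        if not self.is_complete:
            raise ValueError(f"partial date {self} has no day resolution")
        return _dt.date(self.year, self.month, self.day)

    @classmethod
    def from_date(cls, d: _dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    @classmethod
    def parse(cls, text: str) -> Optional["PartialDate"]:
        """Parse a FAERS date field. Empty/blank -> None; malformed -> ValueError."""
        text = text.strip()
        if not text:
            return None
        if not text.isdigit() or len(text) not in (4, 6, 8):
            raise ValueError(f"unparseable date {text!r}")
        year = int(text[:4])
        month = int(text[4:6]) if len(text) >= 6 else None
        day = int(text[6:8]) if len(text) == 8 else None
        return cls(year, month, day)

    def faers_str(self) -> str:
        s = f"{self.year:04d}"
        if self.month is not None:
            s += f"{self.month:02d}"
        if self.day is not None:
            s += f"{self.day:02d}"
        return s


@dataclass
class ReportRecord:
    """One safety report version (a DEMO row).

    ``primary_id`` identifies a report *version*; ``case_id`` identifies the
    case and is shared by successive versions of the same report. After
    deduplication both are unique.
    """

    primary_id: str
    case_id: str
    fda_receipt_date: _dt.date
    event_date: Optional[PartialDate] = None
    sex: Optional[str] = None
    age_value: Optional[float] = None
    age_code: Optional[str] = None
    occupation_code: Optional[str] = None
    reporter_country: Optional[str] = None
    report_quarter: Optional[str] = None
    extra: dict = field(default_factory=dict)


@dataclass
class DrugEntry:
    """One DRUG row: a drug reported on one report version."""

    primary_id: str
    drug_seq: str
    drug_name: Optional[str] = None
    active_ingredient: Optional[str] = None
    role_code: Optional[str] = None
    extra: dict = field(default_factory=dict)


@dataclass
class ReactionEntry:
    """One REAC row: a MedDRA Preferred Term reported on one report version."""

    primary_id: str
    pt: str = ""
    extra: dict = field(default_factory=dict)


@dataclass
class TherapyEntry:
    """One THER row: therapy start date for one drug of one report version."""

    primary_id: str
    drug_seq: str
    start_date: Optional[PartialDate] = None
    extra: dict = field(default_factory=dict)
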