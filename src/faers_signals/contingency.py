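"""2x2 contingency tables for drug-event disproportionality.

For a target drug and one adverse-event term the table is

              term   other terms
    target     a         b
    other      c         d

with N = a + b + c + d. Two margin conventions are supported: counting
drug-event *records* (one (report, term) pair each — the default, which makes
the SOC-level case counts partition the cohort's record total) or counting
distinct *reports*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Optional

from .meddra import UNMAPPED_SOC, PtSocMap, assign_soc
from .records import ReactionEntry, ReportRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of one term-vs-drug 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        if self.n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class MarginConvention:
    """How cells are counted: by (report, term) record or by distinct report,
    at PT or SOC aggregation level."""

    unit: str = "drug_event_record"
    level: str = "PT"

    def __post_init__(self) -> None:
        if self.unit not in ("drug_event_record", "report"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.level not in ("PT", "SOC"):
            raise ValueError(f"unknown level {self.level!r}")


def term_records(
    reports: Iterable[ReportRecord],
    reactions: Iterable[ReactionEntry],
    mapping: Optional[PtSocMap] = None,
    level: str = "PT",
) -> Dict[str, FrozenSet[str]]:
    """Per-report distinct term sets at PT or SOC level.

    Duplicate PTs within a report collapse to one; at SOC level a report
    contributes each SOC once however many of its PTs map there. PTs absent
    from the mapping aggregate under the ``<unmapped>`` pseudo-SOC so counts
    still reconcile.
    """
    if level not in ("PT", "SOC"):
        raise ValueError(f"unknown level {level!r}")
    if level == "SOC" and mapping is None:
        raise ValueError("SOC-level aggregation requires a PT->SOC mapping")
    sets: Dict[str, set] = {r.primary_id: set() for r in reports}
    for reac in reactions:
        if reac.primary_id not in sets:
            continue
        if level == "PT":
            sets[reac.primary_id].add(reac.pt)
        else:
            hit = assign_soc(reac.pt, mapping)
            sets[reac.primary_id].add(hit[1] if hit is not None else UNMAPPED_SOC)
    return {pid: frozenset(terms) for pid, terms in sets.items()}


def build_tables(
    term_sets: Mapping[str, FrozenSet[str]],
    cohort_ids: Iterable[str],
    convention: MarginConvention = MarginConvention(),
) -> Dict[str, ContingencyTable]:
    """One 2x2 table per term appearing anywhere in the data.

    With ``unit="drug_event_record"`` the margins count (report, term) pairs;
    with ``unit="report"`` they count distinct reports. Terms with a = 0
    (absent from the cohort) are included here for descriptive completeness;
    signal scoring applies its own eligibility cut on cell a.
    """
    cohort = set(cohort_ids)
    if not cohort:
        logger.warning("empty cohort: no contingency tables built")
        return {}
    a_counts: Dict[str, int] = {}
    c_counts: Dict[str, int] = {}
    cohort_reports = 0
    bg_reports = 0
    cohort_pairs = 0
    bg_pairs = 0
    for pid, terms in term_sets.items():
        if pid in cohort:
            cohort_reports += 1
            cohort_pairs += len(terms)
            for t in terms:
                a_counts[t] = a_counts.get(t, 0) + 1
        else:
            bg_reports += 1
            bg_pairs += len(terms)
            for t in terms:
                c_counts[t] = c_counts.get(t, 0) + 1
    if convention.unit == "drug_event_record":
        drug_margin, bg_margin = cohort_pairs, bg_pairs
    else:
        drug_margin, bg_margin = cohort_reports, bg_reports
    tables: Dict[str, ContingencyTable] = {}
    for term in sorted(set(a_counts) | set(c_counts)):
        a = a_counts.get(term, 0)
        c = c_counts.get(term, 0)
        tables[term] = ContingencyTable(a=a, b=drug_margin - a, c=c, d=bg_margin - c)
    return tables


def eligible_tables(
    tables: Mapping[str, ContingencyTable], min_a: int = 3
) -> Dict[str, ContingencyTable]:
    """Tables meeting the >= min_a case-count eligibility cut for scoring."""
    return {t: tab for t, tab in tables.items() if tab.a >= min_a}
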