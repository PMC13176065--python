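"""Time-to-onset: days from first target-drug therapy start to event onset.

Only reports with a complete event date and at least one complete therapy
start date for a matching primary-suspect drug entry are evaluable; partial
dates and negative intervals are excluded with tallied reasons, mirroring how
spontaneous-report analyses handle FAERS's pervasive date missingness.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .cohort import CohortSpec, match_drug
from .records import DrugEntry, ReportRecord, TherapyEntry

#: Onset-interval histogram bins in days (upper edges inclusive; last open).
DEFAULT_BINS: Tuple[Tuple[str, int, float], ...] = (
    ("0-30", 0, 30),
    ("31-90", 31, 90),
    ("91-180", 91, 180),
    ("181-365", 181, 365),
    ("366-730", 366, 730),
    (">730", 731, float("inf")),
)


@dataclass(frozen=True)
class TTORecord:
    primary_id: str
    onset_days: int


@dataclass
class TTOSummary:
    n_evaluable: int
    mean_days: float
    median_days: float
    q1_days: float
    q3_days: float
    within_365_count: int
    within_365_pct: float
    histogram: List[Tuple[str, int]]


def compute_onsets(
    reports: Iterable[ReportRecord],
    therapies: Iterable[TherapyEntry],
    drugs: Iterable[DrugEntry],
    spec: CohortSpec,
    cohort_ids: Iterable[str] | None = None,
) -> Tuple[List[TTORecord], Dict[str, int]]:
    """Onset intervals for cohort reports, with exclusion-reason tallies.

    Therapy start is the *earliest* complete start date among the report's
    therapy rows whose drug sequence matches a primary-suspect entry for the
    target drug (first exposure). Returns ``(records, exclusions)`` where
    exclusions counts missing_event_date, partial_event_date,
    missing_start_date, partial_start_date and negative_interval; the totals
    reconcile with the cohort size.
    """
    cohort = set(cohort_ids) if cohort_ids is not None else None
    matching_seqs: Dict[str, set] = {}
    for entry in drugs:
        if match_drug(entry, spec):
            matching_seqs.setdefault(entry.primary_id, set()).add(entry.drug_seq)
    ther_by_pid: Dict[str, List[TherapyEntry]] = {}
    for th in therapies:
        ther_by_pid.setdefault(th.primary_id, []).append(th)

    records: List[TTORecord] = []
    exclusions: Counter = Counter()
    for rep in reports:
        pid = rep.primary_id
        if cohort is not None and pid not in cohort:
            continue
        if pid not in matching_seqs:
            continue
        if rep.event_date is None:
            exclusions["missing_event_date"] += 1
            continue
        if not rep.event_date.is_complete:
            exclusions["partial_event_date"] += 1
            continue
        candidates = [
            th.start_date
            for th in ther_by_pid.get(pid, [])
            if th.drug_seq in matching_seqs[pid] and th.start_date is not None
        ]
        complete = [d for d in candidates if d.is_complete]
        if not candidates:
            exclusions["missing_start_date"] += 1
            continue
        if not complete:
            exclusions["partial_start_date"] += 1
            continue
        start = min(d.to_date() for d in complete)
        onset = (rep.event_date.to_date() - start).days
        if onset < 0:
            exclusions["negative_interval"] += 1
            continue
        records.append(TTORecord(primary_id=pid, onset_days=onset))
    return records, dict(exclusions)


def summarize(
    onsets: Sequence[TTORecord] | Sequence[int],
    year_cutoff: int = 365,
    bins: Sequence[Tuple[str, int, float]] = DEFAULT_BINS,
) -> TTOSummary:
    """Summarize onset intervals: mean, median/IQR (inclusive linear
    interpolation), within-one-year proportion (onset <= ``year_cutoff`` days,
    percentage rounded to 2 dp for display), and a binned histogram."""
    days = np.array(
        [r.onset_days if isinstance(r, TTORecord) else int(r) for r in onsets],
        dtype=float,
    )
    if days.size == 0:
        raise ValueError("no evaluable TTO records")
    q1, med, q3 = np.quantile(days, [0.25, 0.5, 0.75], method="linear")
    within = int(np.sum(days <= year_cutoff))
    hist = [(label, int(np.sum((days >= lo) & (days <= hi)))) for label, lo, hi in bins]
    return TTOSummary(
        n_evaluable=int(days.size),
        mean_days=float(np.mean(days)),
        median_days=float(med),
        q1_days=float(q1),
        q3_days=float(q3),
        within_365_count=within,
        within_365_pct=round(100.0 * within / days.size, 2),
        histogram=hist,
    )
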