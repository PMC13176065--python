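"""Target-drug cohort selection and demographic plausibility screening.

A report enters the cohort when it lists the target drug as primary suspect
(role code PS), matched case-insensitively against a synonym list that covers
brand and generic names. Demographic plausibility (age in [0, 120] years, sex
reported as M or F) gates *descriptive* tabulations only — implausible or
missing demographics never remove a report from disproportionality counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from .records import DrugEntry, ReportRecord

logger = logging.getLogger(__name__)

#: Age unit code -> multiplicative factor to years.
AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


def normalize_name(name: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return " ".join(name.split()).casefold()


@dataclass
class CohortSpec:
    """Defines the target-drug cohort and the descriptive plausibility window."""

    drug_synonyms: Sequence[str]
    role_required: str = "PS"
    age_bounds: Tuple[float, float] = (0.0, 120.0)
    require_known_sex_for_descriptives: bool = True

    def __post_init__(self) -> None:
        if not self.drug_synonyms:
            raise ValueError("drug_synonyms must be non-empty")
        lo, hi = self.age_bounds
        if lo > hi:
            raise ValueError(f"age_bounds out of order: {self.age_bounds}")
        self._normalized = frozenset(normalize_name(s) for s in self.drug_synonyms)

    @property
    def normalized_synonyms(self) -> frozenset:
        return self._normalized


def load_synonyms(path) -> List[str]:
    """Read a one-synonym-per-line text file (blank lines and # comments skipped)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def match_drug(entry: DrugEntry, spec: CohortSpec) -> bool:
    """True iff the entry has the required role and its name (verbatim or
    active ingredient) matches a synonym after normalization."""
    if entry.role_code != spec.role_required:
        return False
    for name in (entry.drug_name, entry.active_ingredient):
        if name is not None and normalize_name(name) in spec.normalized_synonyms:
            return True
    return False


def build_cohort(
    reports: Iterable[ReportRecord],
    drugs: Iterable[DrugEntry],
    spec: CohortSpec,
) -> List[str]:
    """IDs of deduplicated reports with >= 1 matching primary-suspect entry.

    A report with several matching entries counts once. Returns a stable
    sorted list; an empty match set is a warning, not an error.
    """
    matching_pids = {e.primary_id for e in drugs if match_drug(e, spec)}
    report_ids = {r.primary_id for r in reports}
    cohort = sorted(
        matching_pids & report_ids,
        key=lambda p: (int(p) if p.isdigit() else -1, p),
    )
    if not cohort:
        logger.warning("cohort is empty: no report matched %s", list(spec.drug_synonyms))
    return cohort


def age_in_years(age_value: Optional[float], age_code: Optional[str]) -> Optional[float]:
    """Convert a reported (value, unit-code) age to years.

    Missing value or missing/unknown unit code -> missing. Negative inputs
    are returned as-is so the plausibility filter can flag them.
    """
    if age_value is None or age_code is None:
        return None
    factor = AGE_FACTORS.get(age_code.upper())
    if factor is None:
        return None
    return age_value * factor


@dataclass
class FilterDecision:
    keep: bool
    exclude_reason: Optional[str] = None


def demographic_filter(report: ReportRecord, spec: CohortSpec | None = None) -> FilterDecision:
    """Plausibility screen for descriptive tabulations.

    Excludes reports with missing/implausible age (outside [0, 120] years by
    default) or unreported sex. Signal detection is unaffected by this filter.
    """
    spec = spec or CohortSpec(drug_synonyms=["-"])
    lo, hi = spec.age_bounds
    age = age_in_years(report.age_value, report.age_code)
    if age is None:
        return FilterDecision(False, "age_missing")
    if not lo <= age <= hi:
        return FilterDecision(False, "age_implausible")
    if spec.require_known_sex_for_descriptives and report.sex not in ("M", "F"):
        return FilterDecision(False, "sex_unknown")
    return FilterDecision(True)
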