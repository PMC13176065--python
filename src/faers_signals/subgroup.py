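"""Stratified re-analysis of disproportionality signals by age group and sex.

Each stratum reruns the full pipeline on its own slice: both the target-drug
cohort and the background are restricted to reports satisfying the stratum
predicate (children are compared to children), and the MGPS prior is refitted
within the stratum. Reports on which the predicate cannot be evaluated
(e.g. unknown age for an age stratum) are excluded from that stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .cohort import age_in_years
from .contingency import MarginConvention, build_tables, term_records
from .dpa import BcpnnPriors, SignalStats, score_tables
from .meddra import PtSocMap
from .records import ReactionEntry, ReportRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StratumSpec:
    """A demographic stratum: age_lt / age_ge (years) or sex = M / F.

    The age boundary is half-open as in the usual pediatric split:
    ``age_lt 18`` takes strictly-under-18s and ``age_ge 18`` takes everyone
    18 and older (exactly-18-year-olds are adults).
    """

    name: str
    kind: str  # "age_lt" | "age_ge" | "sex"
    value: object

    def __post_init__(self) -> None:
        if self.kind not in ("age_lt", "age_ge", "sex"):
            raise ValueError(f"unknown stratum kind {self.kind!r}")

    def evaluate(self, report: ReportRecord) -> Optional[bool]:
        """True/False membership, or None when the required field is unknown."""
        if self.kind == "sex":
            if report.sex not in ("M", "F"):
                return None
            return report.sex == self.value
        age = age_in_years(report.age_value, report.age_code)
        if age is None:
            return None
        return age < float(self.value) if self.kind == "age_lt" else age >= float(self.value)


DEFAULT_STRATA = (
    StratumSpec("age_lt_18", "age_lt", 18),
    StratumSpec("age_ge_18", "age_ge", 18),
    StratumSpec("sex_M", "sex", "M"),
    StratumSpec("sex_F", "sex", "F"),
)


def stratify_and_rescore(
    reports: Sequence[ReportRecord],
    reactions: Sequence[ReactionEntry],
    cohort_ids: Iterable[str],
    strata: Sequence[StratumSpec] = DEFAULT_STRATA,
    mapping: Optional[PtSocMap] = None,
    convention: MarginConvention = MarginConvention(),
    min_a: int = 3,
    z: float = 1.96,
    yates: bool = False,
    priors: BcpnnPriors = BcpnnPriors(),
    mgps_mode: str = "empirical_bayes",
    restrict_background: bool = True,
) -> Dict[str, List[SignalStats]]:
    """Signal tables per stratum, with within-stratum background by default.

    With ``restrict_background=False`` only the cohort side is restricted and
    the comparator stays the full background. A stratum with no cohort member
    yields an empty table with a warning.
    """
    cohort = set(cohort_ids)
    out: Dict[str, List[SignalStats]] = {}
    for stratum in strata:
        member = {r.primary_id: stratum.evaluate(r) for r in reports}
        if restrict_background:
            kept = [r for r in reports if member[r.primary_id] is True]
        else:
            kept = [
                r
                for r in reports
                if member[r.primary_id] is True or r.primary_id not in cohort
            ]
        stratum_cohort = {r.primary_id for r in kept} & cohort
        if not stratum_cohort:
            logger.warning("stratum %s has no cohort members", stratum.name)
            out[stratum.name] = []
            continue
        sets = term_records(kept, reactions, mapping=mapping, level=convention.level)
        tables = build_tables(sets, stratum_cohort, convention)
        out[stratum.name] = score_tables(
            tables,
            level=convention.level,
            min_a=min_a,
            z=z,
            yates=yates,
            priors=priors,
            mgps_mode=mgps_mode,
        )
    return out
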