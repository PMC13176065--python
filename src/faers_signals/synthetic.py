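"""FAERS-like synthetic data with known ground truth.

Generates DEMO/DRUG/REAC/THER record collections (and a matching PT->SOC
vocabulary) whose statistical structure matches what the disproportionality
pipeline assumes: versioned duplicate cases, primary-suspect vs concomitant
drug roles, multiple PTs per report, planted drug-event associations with a
known relative risk, demographic missingness and implausible ages, and
partial/missing therapy-start and event dates. Event occurrence is
independent Bernoulli per PT given exposure — the independence the 2x2
statistics assume — so planted relative risks are directly comparable to the
pipeline's reporting odds ratios in calibration studies.

Defaults emulate a pediatric, heavily male target-drug cohort (98.5% male,
62% under 18) with a delayed onset profile (log-normal, median 253 days) and
enough date missingness that roughly a third of cohort reports carry complete
onset information.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .records import DrugEntry, PartialDate, ReactionEntry, ReportRecord, TherapyEntry
from . import io_faers

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DrugSpec:
    name: str
    exposure_prob: float
    ps_prob: float = 0.9  # probability the role is PS given exposure


@dataclass(frozen=True)
class EventSpec:
    pt: str
    soc: str
    background_prob: float


@dataclass(frozen=True)
class PlantedAssociation:
    """A drug-event pair whose event probability is multiplied by
    ``relative_risk`` (capped at 1) when the drug is the primary suspect."""

    drug: str
    pt: str
    relative_risk: float


@dataclass(frozen=True)
class DemographicModel:
    male_prob: float = 0.985
    female_prob: float = 0.003  # remainder is unknown sex
    pediatric_prob: float = 0.62
    age_missing_prob: float = 0.04
    implausible_age_prob: float = 0.01


@dataclass(frozen=True)
class TtoModel:
    """Log-normal onset model parameterized by its median in days."""

    median_days: float = 253.0
    sigma: float = 1.0
    start_missing_prob: float = 0.35
    event_missing_prob: float = 0.35
    partial_date_prob: float = 0.05
    negative_interval_prob: float = 0.02


@dataclass(frozen=True)
class SyntheticConfig:
    n_reports: int
    drugs: Sequence[DrugSpec]
    events: Sequence[EventSpec]
    planted: Sequence[PlantedAssociation] = ()
    #: every report draws k ~ zero-truncated Poisson(mean) filler PTs from a
    #: disjoint background vocabulary, guaranteeing >= 1 reaction per report
    #: without perturbing the configured events' relative reporting rates
    pts_per_report_mean: float = 1.2
    n_filler_pts: int = 30
    duplicate_rate: float = 0.08
    demographics: DemographicModel = DemographicModel()
    tto: TtoModel = TtoModel()
    seed: int = 0
    base_year: int = 2021

    def __post_init__(self) -> None:
        for d in self.drugs:
            if not 0 <= d.exposure_prob <= 1 or not 0 <= d.ps_prob <= 1:
                raise ValueError(f"probability out of range for drug {d.name}")
        for e in self.events:
            if not 0 <= e.background_prob <= 1:
                raise ValueError(f"probability out of range for PT {e.pt}")
        for p in self.planted:
            if p.relative_risk <= 0:
                raise ValueError("relative_risk must be positive")
        if not 0 <= self.duplicate_rate <= 1:
            raise ValueError("duplicate_rate out of range")


@dataclass
class SyntheticDataset:
    demo: List[ReportRecord]
    drugs: List[DrugEntry]
    reactions: List[ReactionEntry]
    therapies: List[TherapyEntry]
    pt_soc_rows: List[Tuple[str, int, str]]
    config: SyntheticConfig

    def write(self, out_dir: str | Path) -> Dict[str, Path]:
        """Write the four FAERS-dialect tables plus the PT->SOC map TSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "DEMO": io_faers.write_table(self.demo, out_dir / "DEMO.txt", "DEMO"),
            "DRUG": io_faers.write_table(self.drugs, out_dir / "DRUG.txt", "DRUG"),
            "REAC": io_faers.write_table(self.reactions, out_dir / "REAC.txt", "REAC"),
            "THER": io_faers.write_table(self.therapies, out_dir / "THER.txt", "THER"),
        }
        map_path = out_dir / "pt_soc_map.tsv"
        with map_path.open("w", encoding="utf-8") as fh:
            fh.write("pt\tsoc_code\tsoc_name\n")
            for pt, code, name in self.pt_soc_rows:
                fh.write(f"{pt}\t{code}\t{name}\n")
        paths["PT_SOC_MAP"] = map_path
        return paths


TARGET_DRUG = "CASIMERSEN"
TARGET_SYNONYMS = ("CASIMERSEN", "AMONDYS 45")


def default_events() -> List[EventSpec]:
    """A small PT vocabulary spread over SOC-like groups, with background
    reporting probabilities spanning common to rare."""
    return [
        EventSpec("Poor venous access", "Vascular disorders", 0.002),
        EventSpec("Hypotension", "Vascular disorders", 0.02),
        EventSpec("Infusion site extravasation", "General disorders", 0.003),
        EventSpec("Pyrexia", "General disorders", 0.08),
        EventSpec("Fatigue", "General disorders", 0.10),
        EventSpec("Illness", "General disorders", 0.01),
        EventSpec("Product dose omission issue", "Injury and procedural complications", 0.01),
        EventSpec("Underdose", "Injury and procedural complications", 0.005),
        EventSpec("Fall", "Injury and procedural complications", 0.03),
        EventSpec("Exposure to SARS-CoV-2", "Injury and procedural complications", 0.002),
        EventSpec("Device issue", "Product issues", 0.008),
        EventSpec("Device occlusion", "Product issues", 0.003),
        EventSpec("COVID-19", "Infections", 0.01),
        EventSpec("Influenza", "Infections", 0.012),
        EventSpec("Upper respiratory tract infection", "Infections", 0.025),
        EventSpec("Dehydration", "Metabolism and nutrition disorders", 0.012),
        EventSpec("Nausea", "Gastrointestinal disorders", 0.09),
        EventSpec("Diarrhoea", "Gastrointestinal disorders", 0.07),
        EventSpec("Headache", "Nervous system disorders", 0.09),
        EventSpec("Dizziness", "Nervous system disorders", 0.05),
        EventSpec("Proteinuria", "Renal and urinary disorders", 0.004),
        EventSpec("Chromaturia", "Renal and urinary disorders", 0.002),
        EventSpec("Insurance issue", "Social circumstances", 0.003),
        EventSpec("Rash", "Skin disorders", 0.05),
    ]


def default_config(n_reports: int = 20_000, seed: int = 0) -> SyntheticConfig:
    """Study-shaped defaults: a rare pediatric target drug with planted
    administration-related signals against a mixed background."""
    return SyntheticConfig(
        n_reports=n_reports,
        drugs=[
            DrugSpec(TARGET_DRUG, 0.02, 0.9),
            DrugSpec("DRUG_B", 0.30, 0.5),
            DrugSpec("DRUG_C", 0.25, 0.5),
            DrugSpec("DRUG_D", 0.20, 0.4),
        ],
        events=default_events(),
        planted=[
            PlantedAssociation(TARGET_DRUG, "Poor venous access", 20.0),
            PlantedAssociation(TARGET_DRUG, "Infusion site extravasation", 12.0),
            PlantedAssociation(TARGET_DRUG, "Product dose omission issue", 8.0),
            PlantedAssociation(TARGET_DRUG, "Proteinuria", 6.0),
        ],
        seed=seed,
    )


def filler_events(n: int) -> List[EventSpec]:
    """The disjoint background vocabulary used for the per-report filler draw."""
    return [
        EventSpec(f"Background term {i + 1:02d}", f"Background SOC {i % 6 + 1}", 0.0)
        for i in range(n)
    ]


def calibration_config(seed: int, relative_risk: float = 20.0) -> SyntheticConfig:
    """The standard planted-signal calibration scenario: one drug-event pair
    with a known relative risk (default 20) planted at background probability
    0.005 for a target drug with exposure 0.02 in 50,000 reports. The pipeline
    ROR for the planted PT should be an approximately unbiased estimate of the
    planted relative risk."""
    events = [EventSpec("Planted PT", "Planted SOC", 0.005)] + [
        EventSpec(f"Null PT {i:02d}", f"Null SOC {i % 4 + 1}", p)
        for i, p in enumerate(
            [0.05, 0.03, 0.02, 0.01, 0.008, 0.004, 0.002, 0.06, 0.015, 0.025]
        )
    ]
    return SyntheticConfig(
        n_reports=50_000,
        drugs=[DrugSpec(TARGET_DRUG, 0.02, 0.9), DrugSpec("DRUG_B", 0.30, 0.5)],
        events=events,
        planted=[PlantedAssociation(TARGET_DRUG, "Planted PT", relative_risk)],
        duplicate_rate=0.0,
        seed=seed,
    )


def null_config(n_reports: int = 50_000, seed: int = 0) -> SyntheticConfig:
    """Study-shaped defaults with no planted association (all RR = 1)."""
    return replace(default_config(n_reports=n_reports, seed=seed), planted=())


def soc_map_rows(
    events: Sequence[EventSpec], n_filler_pts: int = 0
) -> List[Tuple[str, int, str]]:
    all_events = list(events) + filler_events(n_filler_pts)
    socs = sorted({e.soc for e in all_events})
    codes = {soc: 10_000_001 + i for i, soc in enumerate(socs)}
    return [(e.pt, codes[e.soc], e.soc) for e in all_events]


def _zt_poisson(rng: np.random.Generator, mean: float) -> int:
    k = 0
    while k == 0:
        k = int(rng.poisson(mean))
    return k


def _emit_date(
    rng: np.random.Generator, d: _dt.date, missing_prob: float, partial_prob: float
) -> Optional[PartialDate]:
    u = rng.random()
    if u < missing_prob:
        return None
    if u < missing_prob + partial_prob:
        return PartialDate(d.year, d.month)  # drop the day
    return PartialDate.from_date(d)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the four FAERS-style tables. Deterministic under config.seed."""
    rng = np.random.default_rng(config.seed)
    dm, tm = config.demographics, config.tto
    for p in config.planted:
        bg = next((e.background_prob for e in config.events if e.pt == p.pt), None)
        if bg is not None and bg * p.relative_risk > 1:
            logger.warning(
                "planted (%s, %s): RR x background = %.3g capped at 1",
                p.drug,
                p.pt,
                bg * p.relative_risk,
            )
    planted_by_drug: Dict[str, Dict[str, float]] = {}
    for p in config.planted:
        planted_by_drug.setdefault(p.drug, {})[p.pt] = p.relative_risk
    fillers = filler_events(config.n_filler_pts)
    base = _dt.date(config.base_year, 1, 1)
    mu_onset = math.log(tm.median_days)

    demo: List[ReportRecord] = []
    drugs: List[DrugEntry] = []
    reactions: List[ReactionEntry] = []
    therapies: List[TherapyEntry] = []

    for i in range(config.n_reports):
        case_num = 1_000_000 + i
        case_id = str(case_num)
        pid = str(case_num * 10 + 1)

        u = rng.random()
        sex = "M" if u < dm.male_prob else ("F" if u < dm.male_prob + dm.female_prob else None)
        u = rng.random()
        if u < dm.age_missing_prob:
            age_value, age_code = None, None
        elif u < dm.age_missing_prob + dm.implausible_age_prob:
            age_value, age_code = float(rng.integers(121, 160)), "YR"
        elif rng.random() < dm.pediatric_prob:
            age_value, age_code = float(rng.integers(4, 18)), "YR"
        else:
            age_value, age_code = float(rng.integers(18, 66)), "YR"
        occupation = str(rng.choice(["PH", "MD", "CN", "OT"], p=[0.85, 0.05, 0.08, 0.02]))
        country = "US" if rng.random() < 0.995 else "CA"

        # drug exposures and roles
        report_drugs: List[Tuple[str, str]] = []  # (name, role)
        ps_drugs = set()
        for spec in config.drugs:
            if rng.random() < spec.exposure_prob:
                if rng.random() < spec.ps_prob:
                    role = "PS"
                    ps_drugs.add(spec.name)
                else:
                    role = "SS" if rng.random() < 0.5 else "C"
                report_drugs.append((spec.name, role))

        # reactions: every report draws filler PTs (>= 1 reaction guaranteed),
        # then independent Bernoulli per configured PT with planted RR when
        # the planted drug is the primary suspect
        k = _zt_poisson(rng, config.pts_per_report_mean)
        k = min(k, len(fillers))
        idx = rng.choice(len(fillers), size=k, replace=False)
        pts: List[str] = [fillers[j].pt for j in sorted(idx)]
        for ev in config.events:
            p = ev.background_prob
            for drug_name in ps_drugs:
                rr = planted_by_drug.get(drug_name, {}).get(ev.pt)
                if rr is not None:
                    p = min(1.0, p * rr)
            if rng.random() < p:
                pts.append(ev.pt)

        # dates: therapy start, log-normal onset, event, receipt
        start = base + _dt.timedelta(days=int(rng.integers(0, 1095)))
        onset = max(0, int(round(rng.lognormal(mu_onset, tm.sigma))))
        if rng.random() < tm.negative_interval_prob:
            event = start - _dt.timedelta(days=int(rng.integers(1, 120)))
        else:
            event = start + _dt.timedelta(days=onset)
        fda = max(event, start) + _dt.timedelta(days=int(rng.integers(1, 90)))
        event_emitted = _emit_date(rng, event, tm.event_missing_prob, tm.partial_date_prob)
        start_emitted = _emit_date(rng, start, tm.start_missing_prob, tm.partial_date_prob)

        versions = [(pid, fda)]
        if rng.random() < config.duplicate_rate:
            versions.append(
                (str(case_num * 10 + 2), fda + _dt.timedelta(days=int(rng.integers(10, 100))))
            )
        for v_pid, v_fda in versions:
            demo.append(
                ReportRecord(
                    primary_id=v_pid,
                    case_id=case_id,
                    fda_receipt_date=v_fda,
                    event_date=event_emitted,
                    sex=sex,
                    age_value=age_value,
                    age_code=age_code,
                    occupation_code=occupation,
                    reporter_country=country,
                )
            )
            for seq, (name, role) in enumerate(report_drugs, start=1):
                drugs.append(
                    DrugEntry(
                        primary_id=v_pid,
                        drug_seq=str(seq),
                        drug_name=name,
                        active_ingredient=name,
                        role_code=role,
                    )
                )
                therapies.append(
                    TherapyEntry(primary_id=v_pid, drug_seq=str(seq), start_date=start_emitted)
                )
            for pt in pts:
                reactions.append(ReactionEntry(primary_id=v_pid, pt=pt))

    return SyntheticDataset(
        demo=demo,
        drugs=drugs,
        reactions=reactions,
        therapies=therapies,
        pt_soc_rows=soc_map_rows(config.events, config.n_filler_pts),
        config=config,
    )


# ---------------------------------------------------------------------------
# Worked example: a hand-checkable 11-row dataset with hand-computed answers
# ---------------------------------------------------------------------------

def worked_example() -> Tuple[SyntheticDataset, Dict]:
    """A tiny hand-enumerable dataset and its hand-computed expected outputs.

    Ten cases: four with DRUGX as primary suspect (the cohort), six
    background; case 1 has a stale duplicate version to exercise
    deduplication. Expected 2x2 tables (drug_event_record unit, PT level) and
    ROR/PRR/chi-square values were computed by hand from the cell counts and
    are frozen in the returned dict.
    """
    d = _dt.date

    def rep(pid, case, fda, event=None, sex="M", age=12.0, start=None):
        return ReportRecord(
            primary_id=pid,
            case_id=case,
            fda_receipt_date=fda,
            event_date=event,
            sex=sex,
            age_value=age,
            age_code="YR",
            occupation_code="PH",
            reporter_country="US",
        )

    demo = [
        # case 100001: two versions; the 2023-06-01 one must survive dedup
        rep("1000011", "100001", d(2023, 1, 15)),
        rep("1000012", "100001", d(2023, 6, 1), event=PartialDate(2023, 9, 11)),
        rep("1000021", "100002", d(2023, 2, 1), event=PartialDate(2023, 5, 15)),
        rep("1000031", "100003", d(2023, 3, 1), event=PartialDate(2023, 1, 10)),
        rep("1000041", "100004", d(2023, 4, 1), event=PartialDate(2023, 8, 1)),
        rep("1000051", "100005", d(2023, 5, 1), sex="F", age=30.0),
        rep("1000061", "100006", d(2023, 6, 1), sex=None),
        rep("1000071", "100007", d(2023, 7, 1), age=130.0),
        rep("1000081", "100008", d(2023, 8, 1)),
        rep("1000091", "100009", d(2023, 9, 1), age=45.0),
        rep("1000101", "100010", d(2023, 10, 1)),
    ]
    cohort_cases = ["1000012", "1000021", "1000031", "1000041"]
    bg_cases = ["1000051", "1000061", "1000071", "1000081", "1000091", "1000101"]
    drugs = []
    therapies = []
    for pid in cohort_cases + ["1000011"]:
        drugs.append(
            DrugEntry(pid, "1", drug_name="DrugX 45", active_ingredient="DRUGX", role_code="PS")
        )
    for pid in bg_cases:
        drugs.append(
            DrugEntry(pid, "1", drug_name="OTHERDRUG", active_ingredient="OTHERDRUG", role_code="PS")
        )
    # therapy starts: survivor of case 1 -> complete (onset 253 d);
    # case 2 -> partial start; case 3 -> event precedes start; case 4 -> missing
    therapies.append(TherapyEntry("1000012", "1", start_date=PartialDate(2023, 1, 1)))
    therapies.append(TherapyEntry("1000021", "1", start_date=PartialDate(2023, 1)))
    therapies.append(TherapyEntry("1000031", "1", start_date=PartialDate(2023, 2, 1)))

    reac = {
        "1000011": ["Pyrexia"],  # stale version; must not count
        "1000012": ["Pyrexia", "Pyrexia", "Cough"],  # duplicate PT collapses
        "1000021": ["Pyrexia"],
        "1000031": ["Pyrexia", "Headache"],
        "1000041": ["Cough"],
        "1000051": ["Pyrexia"],
        "1000061": ["Cough"],
        "1000071": ["Headache"],
        "1000081": ["Headache", "Cough"],
        "1000091": ["Pyrexia", "Headache"],
        "1000101": ["Headache"],
    }
    reactions = [ReactionEntry(pid, pt) for pid, pts in reac.items() for pt in pts]
    events = [
        EventSpec("Pyrexia", "General disorders", 0.1),
        EventSpec("Cough", "Respiratory disorders", 0.1),
        EventSpec("Headache", "Nervous system disorders", 0.1),
    ]
    config = SyntheticConfig(
        n_reports=10,
        drugs=[DrugSpec("DRUGX", 0.4, 1.0), DrugSpec("OTHERDRUG", 0.6, 1.0)],
        events=events,
        seed=0,
    )
    dataset = SyntheticDataset(
        demo=demo,
        drugs=drugs,
        reactions=reactions,
        therapies=therapies,
        pt_soc_rows=soc_map_rows(events),
        config=config,
    )
    # Hand-computed from the table above: cohort record margin 6, background 8.
    expected = {
        "cohort_ids": cohort_cases,
        "n_deduplicated": 10,
        "unit": "drug_event_record",
        "level": "PT",
        "tables": {
            "Pyrexia": (3, 3, 2, 6),
            "Cough": (2, 4, 2, 6),
            "Headache": (1, 5, 4, 4),
        },
        "ror": {"Pyrexia": 3.0, "Cough": 1.5, "Headache": 0.2},
        "prr": {"Pyrexia": 2.0, "Cough": 4.0 / 3.0, "Headache": 1.0 / 3.0},
        "chi2": {
            "Pyrexia": 14 * 144 / 2160,
            "Cough": 14 * 16 / 1920,
            "Headache": 14 * 256 / 2160,
        },
        "tto": {
            "onsets": {"1000012": 253},
            "exclusions": {
                "partial_start_date": 1,
                "negative_interval": 1,
                "missing_start_date": 1,
            },
        },
    }
    return dataset, expected
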