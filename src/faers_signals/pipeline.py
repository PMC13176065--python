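"""End-to-end pipeline: ingest -> dedup -> cohort -> tables -> signals -> TTO
-> subgroups, with publication-style TSV outputs and a run manifest.

The run emits, under the configured output directory:

* ``demographics.tsv`` — descriptive counts (sex, age bands, occupation,
  country, receipt year) over the cohort after the plausibility screen, with
  exclusions itemized;
* ``signals_pt.tsv`` / ``signals_soc.tsv`` — the full signal tables, ranked
  by EBGM descending (ties: case count descending, then term);
* ``overlap.tsv`` — per-algorithm and intersection signal counts;
* ``tto_summary.tsv`` / ``tto_records.tsv`` — time-to-onset results;
* ``strata/<name>_<level>.tsv`` — per-stratum signal tables;
* ``unmapped_pts.tsv`` and ``manifest.json`` (config hash, versions,
  row-count reconciliation).

All TSVs carry full precision; display rounding is the report renderer's job.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, build_cohort, demographic_filter, age_in_years, load_synonyms
from .contingency import ContingencyTable, MarginConvention, build_tables, term_records
from .dpa import ALGORITHMS, BcpnnPriors, SignalStats, overlap_counts, score_tables
from .io_faers import deduplicate, read_table
from .meddra import PtSocMap, load_map, unmapped_report, write_unmapped_report
from .records import DrugEntry, ReactionEntry, ReportRecord, TherapyEntry
from .subgroup import DEFAULT_STRATA, StratumSpec, stratify_and_rescore
from .synthetic import SyntheticConfig, SyntheticDataset, generate
from .tto import TTORecord, TTOSummary, compute_onsets, summarize

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class EmptyCohortError(RuntimeError):
    """No report matched the target-drug cohort specification."""


@dataclass
class DpaOptions:
    min_a: int = 3
    z: float = 1.96
    yates: bool = False
    mgps_mode: str = "empirical_bayes"
    bcpnn_priors: BcpnnPriors = field(default_factory=BcpnnPriors)


@dataclass
class PipelineConfig:
    cohort: CohortSpec
    inputs: Optional[Dict[str, str]] = None  # paths: demo/drug/reac/ther/pt_soc_map
    synthetic: Optional[SyntheticConfig] = None
    unit: str = "drug_event_record"
    dpa: DpaOptions = field(default_factory=DpaOptions)
    tto_year_cutoff: int = 365
    strata: Sequence[StratumSpec] = DEFAULT_STRATA
    restrict_background: bool = True
    output_dir: str = "results/run"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ConfigError("exactly one of 'inputs' or 'synthetic' must be given")
        if self.unit not in ("drug_event_record", "report"):
            raise ConfigError(f"unknown margin unit {self.unit!r}")


_TOP_KEYS = {
    "cohort",
    "inputs",
    "synthetic",
    "unit",
    "dpa",
    "tto_year_cutoff",
    "strata",
    "restrict_background",
    "output_dir",
    "seed",
    "log_level",
}


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build and validate a PipelineConfig from a plain dict (YAML content).

    Unknown keys are rejected so config typos fail loudly.
    """
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "cohort" not in raw:
        raise ConfigError("missing required 'cohort' section")
    co = dict(raw["cohort"])
    unknown = set(co) - {
        "drug_synonyms",
        "synonyms_file",
        "role_required",
        "age_bounds",
        "require_known_sex_for_descriptives",
    }
    if unknown:
        raise ConfigError(f"unknown cohort key(s): {', '.join(sorted(unknown))}")
    synonyms = list(co.get("drug_synonyms") or [])
    if "synonyms_file" in co:
        synonyms += load_synonyms(co["synonyms_file"])
    try:
        cohort = CohortSpec(
            drug_synonyms=synonyms,
            role_required=co.get("role_required", "PS"),
            age_bounds=tuple(co.get("age_bounds", (0.0, 120.0))),
            require_known_sex_for_descriptives=co.get(
                "require_known_sex_for_descriptives", True
            ),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    dpa_raw = dict(raw.get("dpa", {}))
    priors_raw = dpa_raw.pop("bcpnn_priors", {})
    unknown = set(dpa_raw) - {"min_a", "z", "yates", "mgps_mode"}
    if unknown:
        raise ConfigError(f"unknown dpa key(s): {', '.join(sorted(unknown))}")
    dpa = DpaOptions(bcpnn_priors=BcpnnPriors(**priors_raw), **dpa_raw)
    if dpa.mgps_mode not in ("empirical_bayes", "simplified"):
        raise ConfigError(f"unknown mgps_mode {dpa.mgps_mode!r}")

    strata_raw = raw.get("strata", "default")
    if strata_raw == "default":
        strata: Sequence[StratumSpec] = DEFAULT_STRATA
    else:
        strata = tuple(
            StratumSpec(s["name"], s["kind"], s["value"]) for s in strata_raw
        )

    synthetic = None
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = raw["synthetic"]
        if isinstance(syn, SyntheticConfig):
            synthetic = syn
        else:
            from .synthetic import default_config

            base = default_config(
                n_reports=syn.get("n_reports", 20_000), seed=syn.get("seed", raw.get("seed", 0))
            )
            synthetic = base

    return PipelineConfig(
        cohort=cohort,
        inputs=raw.get("inputs"),
        synthetic=synthetic,
        unit=raw.get("unit", "drug_event_record"),
        dpa=dpa,
        tto_year_cutoff=raw.get("tto_year_cutoff", 365),
        strata=strata,
        restrict_background=raw.get("restrict_background", True),
        output_dir=raw.get("output_dir", "results/run"),
        seed=raw.get("seed", 0),
        log_level=raw.get("log_level", "INFO"),
    )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# Result container and run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: PipelineConfig
    reports: List[ReportRecord]
    cohort_ids: List[str]
    mapping: PtSocMap
    tables_pt: Dict[str, ContingencyTable]
    tables_soc: Dict[str, ContingencyTable]
    signals_pt: List[SignalStats]
    signals_soc: List[SignalStats]
    overlap: Dict[str, int]
    demographics: pd.DataFrame
    tto_records: List[TTORecord]
    tto_exclusions: Dict[str, int]
    tto_summary: Optional[TTOSummary]
    strata_signals: Dict[str, List[SignalStats]]
    manifest: Dict


def _rank_signals(stats: List[SignalStats]) -> List[SignalStats]:
    """EBGM descending; ties by case count descending, then term name."""

    def key(s: SignalStats):
        ebgm = s.ebgm if not math.isnan(s.ebgm) else -math.inf
        return (-ebgm, -s.a, s.term)

    return sorted(stats, key=key)


def signals_frame(stats: Sequence[SignalStats]) -> pd.DataFrame:
    rows = []
    for s in stats:
        row = {
            "term": s.term,
            "level": s.level,
            "n_cases": s.a,
            "ror": s.ror,
            "ror_lo": s.ror_lo,
            "ror_hi": s.ror_hi,
            "prr": s.prr,
            "chi2": s.chi2,
            "ic": s.ic,
            "ic025": s.ic025,
            "expected": s.expected,
            "ebgm": s.ebgm,
            "eb05": s.eb05,
            "eligible": s.eligible,
        }
        for alg in ALGORITHMS:
            row[f"flag_{alg.lower()}"] = s.flags.get(alg, False)
        row["consensus"] = s.consensus
        rows.append(row)
    return pd.DataFrame(rows)


def demographics_frame(
    reports: Sequence[ReportRecord], cohort_ids: Sequence[str], spec: CohortSpec
) -> pd.DataFrame:
    """Descriptive characteristics of the cohort after the plausibility screen.

    Rows are (section, category, count); excluded reports are itemized under
    the ``exclusion`` section so n's reconcile with the cohort size.
    """
    cohort = {r.primary_id: r for r in reports if r.primary_id in set(cohort_ids)}
    kept: List[ReportRecord] = []
    exclusions: Dict[str, int] = {}
    for rec in cohort.values():
        decision = demographic_filter(rec, spec)
        if decision.keep:
            kept.append(rec)
        else:
            exclusions[decision.exclude_reason] = exclusions.get(decision.exclude_reason, 0) + 1
    rows: List[Tuple[str, str, int]] = [("total", "cohort_reports", len(cohort))]
    rows.append(("total", "descriptive_n", len(kept)))
    for reason in sorted(exclusions):
        rows.append(("exclusion", reason, exclusions[reason]))

    def count_by(section: str, keyfn) -> None:
        counts: Dict[str, int] = {}
        for rec in kept:
            k = keyfn(rec)
            counts[k] = counts.get(k, 0) + 1
        for k in sorted(counts):
            rows.append((section, k, counts[k]))

    count_by("sex", lambda r: r.sex or "UNK")
    count_by(
        "age_group",
        lambda r: "<18" if age_in_years(r.age_value, r.age_code) < 18 else ">=18",
    )
    count_by("occupation", lambda r: r.occupation_code or "UNK")
    count_by("country", lambda r: r.reporter_country or "UNK")
    count_by("year", lambda r: str(r.fda_receipt_date.year))
    return pd.DataFrame(rows, columns=["section", "category", "count"])


def _load_inputs(
    config: PipelineConfig,
) -> Tuple[List[ReportRecord], List[DrugEntry], List[ReactionEntry], List[TherapyEntry], PtSocMap]:
    if config.synthetic is not None:
        ds: SyntheticDataset = generate(
            dataclasses.replace(config.synthetic, seed=config.synthetic.seed or config.seed)
        )
        mapping = PtSocMap.from_rows(ds.pt_soc_rows, version_label="synthetic")
        return ds.demo, ds.drugs, ds.reactions, ds.therapies, mapping
    paths = config.inputs
    required = {"demo", "drug", "reac", "ther", "pt_soc_map"}
    missing = required - set(paths)
    if missing:
        raise ConfigError(f"inputs missing path(s): {', '.join(sorted(missing))}")
    demo = read_table(paths["demo"], "DEMO")
    drugs = read_table(paths["drug"], "DRUG")
    reac = read_table(paths["reac"], "REAC")
    ther = read_table(paths["ther"], "THER")
    mapping = load_map(paths["pt_soc_map"])
    return demo, drugs, reac, ther, mapping


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (frozenset, set, tuple)):
            return sorted(map(str, o)) if isinstance(o, (frozenset, set)) else list(o)
        return str(o)

    payload = dataclasses.asdict(config)
    # run-local fields don't alter the scientific configuration
    payload.pop("output_dir", None)
    payload.pop("log_level", None)
    blob = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(
    config: PipelineConfig,
    dataset: Optional[SyntheticDataset] = None,
    write_outputs: bool = True,
) -> RunResult:
    """Execute the full pipeline; optionally skip writing files.

    ``dataset`` overrides input loading (used for in-memory runs on the
    worked example and in tests).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if dataset is not None:
        demo, drugs, reac, ther = dataset.demo, dataset.drugs, dataset.reactions, dataset.therapies
        mapping = PtSocMap.from_rows(dataset.pt_soc_rows, version_label="provided")
    else:
        demo, drugs, reac, ther, mapping = _load_inputs(config)

    n_raw = len(demo)
    reports = deduplicate(demo)
    logger.info("deduplicated %d raw rows -> %d cases", n_raw, len(reports))
    cohort_ids = build_cohort(reports, drugs, config.cohort)
    if not cohort_ids:
        raise EmptyCohortError(
            f"no report matched synonyms {list(config.cohort.drug_synonyms)}"
        )
    logger.info("cohort: %d reports", len(cohort_ids))

    conv_pt = MarginConvention(unit=config.unit, level="PT")
    conv_soc = MarginConvention(unit=config.unit, level="SOC")
    sets_pt = term_records(reports, reac, mapping=mapping, level="PT")
    sets_soc = term_records(reports, reac, mapping=mapping, level="SOC")
    tables_pt = build_tables(sets_pt, cohort_ids, conv_pt)
    tables_soc = build_tables(sets_soc, cohort_ids, conv_soc)

    dpa_kwargs = dict(
        min_a=config.dpa.min_a,
        z=config.dpa.z,
        yates=config.dpa.yates,
        priors=config.dpa.bcpnn_priors,
        mgps_mode=config.dpa.mgps_mode,
    )
    signals_pt = _rank_signals(score_tables(tables_pt, level="PT", **dpa_kwargs))
    signals_soc = _rank_signals(score_tables(tables_soc, level="SOC", **dpa_kwargs))
    overlap = overlap_counts(signals_pt)

    demographics = demographics_frame(reports, cohort_ids, config.cohort)

    tto_records, tto_exclusions = compute_onsets(
        reports, ther, drugs, config.cohort, cohort_ids=cohort_ids
    )
    tto_summary = (
        summarize(tto_records, year_cutoff=config.tto_year_cutoff) if tto_records else None
    )

    strata_signals = stratify_and_rescore(
        reports,
        reac,
        cohort_ids,
        strata=config.strata,
        mapping=mapping,
        convention=conv_pt,
        restrict_background=config.restrict_background,
        **dpa_kwargs,
    )

    cohort_set = set(cohort_ids)
    soc_record_total = sum(len(sets_soc[p]) for p in cohort_set)
    soc_a_sum = sum(t.a for t in tables_soc.values())
    unmapped = unmapped_report((r.pt for r in reac if r.primary_id in sets_pt), mapping)
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "counts": {
            "raw_demo_rows": n_raw,
            "deduplicated_reports": len(reports),
            "cohort_reports": len(cohort_ids),
            "cohort_pt_records": sum(len(sets_pt[p]) for p in cohort_set),
            "cohort_soc_records": soc_record_total,
            "soc_a_sum": soc_a_sum,
            "soc_partition_ok": soc_a_sum == soc_record_total,
            "tto_evaluable": len(tto_records),
            "tto_exclusions": tto_exclusions,
            "unmapped_pts": len(unmapped),
        },
    }

    result = RunResult(
        config=config,
        reports=reports,
        cohort_ids=list(cohort_ids),
        mapping=mapping,
        tables_pt=tables_pt,
        tables_soc=tables_soc,
        signals_pt=signals_pt,
        signals_soc=signals_soc,
        overlap=overlap,
        demographics=demographics,
        tto_records=tto_records,
        tto_exclusions=tto_exclusions,
        tto_summary=tto_summary,
        strata_signals=strata_signals,
        manifest=manifest,
    )
    if write_outputs:
        write_result(result, Path(config.output_dir), unmapped)
    return result


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_result(result: RunResult, out_dir: Path, unmapped: Dict[str, int] | None = None) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(signals_frame(result.signals_pt), out_dir / "signals_pt.tsv")
    _write_tsv(signals_frame(result.signals_soc), out_dir / "signals_soc.tsv")
    _write_tsv(result.demographics, out_dir / "demographics.tsv")
    overlap = pd.DataFrame(
        sorted(result.overlap.items()), columns=["algorithms", "n_signals"]
    )
    _write_tsv(overlap, out_dir / "overlap.tsv")
    tto_rows = pd.DataFrame(
        [(r.primary_id, r.onset_days) for r in result.tto_records],
        columns=["primary_id", "onset_days"],
    )
    _write_tsv(tto_rows, out_dir / "tto_records.tsv")
    if result.tto_summary is not None:
        s = result.tto_summary
        rows = [
            ("n_evaluable", s.n_evaluable),
            ("mean_days", s.mean_days),
            ("median_days", s.median_days),
            ("q1_days", s.q1_days),
            ("q3_days", s.q3_days),
            ("within_365_count", s.within_365_count),
            ("within_365_pct", s.within_365_pct),
        ]
        rows += [(f"bin_{label}", count) for label, count in s.histogram]
        rows += [(f"excluded_{k}", v) for k, v in sorted(result.tto_exclusions.items())]
        _write_tsv(pd.DataFrame(rows, columns=["quantity", "value"]), out_dir / "tto_summary.tsv")
    strata_dir = out_dir / "strata"
    strata_dir.mkdir(exist_ok=True)
    for name, stats in result.strata_signals.items():
        _write_tsv(signals_frame(_rank_signals(stats)), strata_dir / f"{name}_pt.tsv")
    if unmapped is not None:
        write_unmapped_report(unmapped, out_dir / "unmapped_pts.tsv")
    with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
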