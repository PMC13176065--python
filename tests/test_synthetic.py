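"""The synthetic FAERS generator: determinism, bookkeeping, and calibration
of its empirical frequencies against the configured ground truth."""

import dataclasses

import numpy as np
import pytest

from faers_signals.cohort import CohortSpec, build_cohort
from faers_signals.contingency import MarginConvention, build_tables, term_records
from faers_signals.dpa import prr_chi2, ror_stats
from faers_signals.io_faers import deduplicate, read_table
from faers_signals.synthetic import (
    SyntheticConfig,
    TARGET_SYNONYMS,
    default_config,
    generate,
    worked_example,
)


@pytest.fixture(scope="module")
def small_run():
    config = default_config(n_reports=1_000, seed=3)
    config = dataclasses.replace(config, duplicate_rate=0.1)
    return config, generate(config)


def test_deterministic_under_seed(small_run, tmp_path):
    config, ds = small_run
    again = generate(config)
    assert ds.demo == again.demo
    assert ds.drugs == again.drugs
    assert ds.reactions == again.reactions
    assert ds.therapies == again.therapies
    p1 = ds.write(tmp_path / "a")
    p2 = again.write(tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()


def test_different_seeds_differ(small_run):
    config, ds = small_run
    other = generate(dataclasses.replace(config, seed=4))
    assert ds.demo != other.demo


def test_duplicate_bookkeeping(small_run):
    """~10% of cases re-versioned; dedup restores exactly n_reports cases."""
    config, ds = small_run
    n = config.n_reports
    extra = len(ds.demo) - n
    sd = np.sqrt(n * 0.1 * 0.9)
    assert abs(extra - 0.1 * n) < 3 * sd
    deduped = deduplicate(ds.demo)
    assert len(deduped) == n
    # survivors are the re-versioned rows where a duplicate exists
    by_case = {}
    for r in ds.demo:
        by_case.setdefault(r.case_id, []).append(r)
    for r in deduped:
        assert r.fda_receipt_date == max(x.fda_receipt_date for x in by_case[r.case_id])


def test_written_tables_round_trip_through_io(small_run, tmp_path):
    config, ds = small_run
    paths = ds.write(tmp_path)
    assert read_table(paths["DEMO"], "DEMO") == ds.demo
    assert read_table(paths["REAC"], "REAC") == ds.reactions


def test_every_report_has_at_least_one_reaction(small_run):
    _, ds = small_run
    with_reac = {r.primary_id for r in ds.reactions}
    assert all(rec.primary_id in with_reac for rec in ds.demo)


def test_background_event_frequency_converges():
    """Among reports without the target drug as PS, each configured PT's
    frequency is within 3 binomial SDs of its background probability."""
    config = default_config(n_reports=20_000, seed=5)
    ds = generate(config)
    reports = deduplicate(ds.demo)
    cohort = set(build_cohort(reports, ds.drugs, CohortSpec(list(TARGET_SYNONYMS))))
    background = [r.primary_id for r in reports if r.primary_id not in cohort]
    sets = term_records(reports, ds.reactions, level="PT")
    n = len(background)
    for ev in config.events:
        if any(p.pt == ev.pt for p in config.planted):
            continue
        freq = sum(1 for pid in background if ev.pt in sets[pid]) / n
        sd = np.sqrt(ev.background_prob * (1 - ev.background_prob) / n)
        assert abs(freq - ev.background_prob) < 3 * sd + 1e-4, ev.pt


def test_demographics_match_configured_mixture():
    config = default_config(n_reports=20_000, seed=6)
    ds = generate(config)
    reports = deduplicate(ds.demo)
    n = len(reports)
    male = sum(1 for r in reports if r.sex == "M") / n
    assert abs(male - config.demographics.male_prob) < 0.01
    with_age = [r for r in reports if r.age_value is not None]
    peds = sum(1 for r in with_age if r.age_value < 18) / len(with_age)
    assert abs(peds - config.demographics.pediatric_prob * (1 - 0.01)) < 0.02


class TestWorkedExample:
    def test_regenerates_identically(self):
        a, ea = worked_example()
        b, eb = worked_example()
        assert a.demo == b.demo and a.reactions == b.reactions
        assert ea == eb

    def test_contingency_tables_match_hand_enumeration(self, example, example_spec):
        ds, expected = example
        reports = deduplicate(ds.demo)
        assert len(reports) == expected["n_deduplicated"]
        ids = build_cohort(reports, ds.drugs, example_spec)
        assert ids == expected["cohort_ids"]
        sets = term_records(reports, ds.reactions, level="PT")
        tables = build_tables(sets, ids, MarginConvention())
        assert {t: (v.a, v.b, v.c, v.d) for t, v in tables.items()} == expected["tables"]
        for term, t in tables.items():
            assert ror_stats(t)[0] == pytest.approx(expected["ror"][term])
            prr, chi2 = prr_chi2(t)
            assert prr == pytest.approx(expected["prr"][term])
            assert chi2 == pytest.approx(expected["chi2"][term])

    def test_deleting_one_reaction_changes_exactly_one_table(self, example, example_spec):
        """With report-unit margins, dropping one REAC row moves one count
        from a to b of that term's table and leaves every other table alone."""
        ds, expected = example
        reports = deduplicate(ds.demo)
        ids = build_cohort(reports, ds.drugs, example_spec)
        conv = MarginConvention(unit="report")
        before = build_tables(term_records(reports, ds.reactions, level="PT"), ids, conv)
        reac = [r for r in ds.reactions if not (r.primary_id == "1000041" and r.pt == "Cough")]
        after = build_tables(term_records(reports, reac, level="PT"), ids, conv)
        assert after["Cough"].a == before["Cough"].a - 1
        assert after["Cough"].b == before["Cough"].b + 1
        for term in before:
            if term != "Cough":
                assert after[term] == before[term]
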