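import datetime as dt

import numpy as np
import pytest

from faers_signals.cohort import CohortSpec
from faers_signals.contingency import ContingencyTable
from faers_signals.records import DrugEntry, ReactionEntry, ReportRecord
from faers_signals.synthetic import worked_example


@pytest.fixture(scope="session")
def example():
    """The bundled hand-checkable dataset with its hand-computed answers."""
    dataset, expected = worked_example()
    return dataset, expected


@pytest.fixture(scope="session")
def example_spec():
    return CohortSpec(drug_synonyms=["DRUGX", "DrugX 45"])


def make_report(pid, case=None, fda=dt.date(2023, 1, 1), **kw):
    return ReportRecord(
        primary_id=str(pid), case_id=str(case if case is not None else pid),
        fda_receipt_date=fda, **kw,
    )


def random_tables(rng: np.random.Generator, n: int, a_min=1, a_max=50):
    """Random strictly-positive 2x2 tables for oracle-equivalence checks."""
    out = []
    for _ in range(n):
        out.append(
            ContingencyTable(
                a=int(rng.integers(a_min, a_max)),
                b=int(rng.integers(1, 300)),
                c=int(rng.integers(1, 300)),
                d=int(rng.integers(50, 10_000)),
            )
        )
    return out
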