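from __future__ import annotations

import datetime as dt

import pytest

from bloomloci.datamodel_io import (
    OrfRecord,
    Sample,
    SampleSeries,
    load_function_sets,
)
from bloomloci import synthetic_data as syn


@pytest.fixture(scope="session")
def sets():
    return load_function_sets()


@pytest.fixture(scope="session")
def demo():
    """One noisy demo simulation shared across read-only tests."""
    return syn.demo_dataset(seed=11)


@pytest.fixture
def small_series():
    return SampleSeries(
        [
            Sample("S01", dt.date(2021, 3, 1), 0.1),
            Sample("S02", dt.date(2021, 3, 11), 0.2),
            Sample("S03", dt.date(2021, 3, 21), 1.5),
            Sample("S04", dt.date(2021, 3, 31), 4.0),
        ]
    )


def make_orf(orf_id="o1", contig="c1", start=1, end=900, strand="+", **kw):
    return OrfRecord(orf_id=orf_id, contig_id=contig, start=start, end=end,
                     strand=strand, **kw)


@pytest.fixture
def orf_factory():
    return make_orf
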