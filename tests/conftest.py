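import pytest

from mpmine import (
    SyntheticCorpusSpec,
    expand_counts_to_entries,
    generate_records,
    load_counts_fixture,
    mine_corpus,
)


@pytest.fixture(scope="session")
def calibrated_corpus():
    """Default-calibrated synthetic corpus, 300 explicit-value articles/group."""
    spec = SyntheticCorpusSpec.calibrated(n_per_group=300, seed=17)
    records, truth = generate_records(spec)
    hits = mine_corpus(records)
    return spec, records, truth, hits


@pytest.fixture(scope="session")
def table1_entries():
    return expand_counts_to_entries(
        load_counts_fixture("table1"), "non_ecoli", n_unique=141, prefix="H"
    )


@pytest.fixture(scope="session")
def table2_entries():
    return expand_counts_to_entries(
        load_counts_fixture("table2"), "ecoli", n_unique=72, prefix="E"
    )
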