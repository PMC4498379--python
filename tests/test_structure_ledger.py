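"""Structure-ledger curation: cross-tabs, contributions, tallies."""

import numpy as np
import pandas as pd
import pytest

from mpmine.rounding import pct, percentage_row, round_half_away
from mpmine.structure_ledger import (
    CrossTab,
    CurationError,
    StructureEntry,
    build_crosstab,
    expand_counts_to_entries,
    host_contribution,
    lab_usage_distribution,
    load_counts_fixture,
    load_lab_fixture,
    merge_secondary_accessions,
    read_ledger,
    topology_tally,
    unique_structure_count,
    write_ledger,
)


def _entry(acc, protein="prot", org="non_ecoli", host="BL21(DE3)", promoter="T7", **kw):
    return StructureEntry(acc, protein, org, host, promoter, **kw)


# ---------------------------------------------------------------------------
# rounding rules


def test_percentage_row_sums_to_100_and_stays_within_one_of_plain_rounding():
    rng = np.random.default_rng(0)
    for _ in range(200):
        counts = rng.integers(0, 60, size=rng.integers(2, 8)).tolist()
        if sum(counts) == 0:
            continue
        row = percentage_row(counts)
        assert sum(row) == 100
        total = sum(counts)
        for c, p in zip(counts, row):
            assert abs(p - round_half_away(100 * c / total)) <= 1


# ---------------------------------------------------------------------------
# merging of secondary accessions


def test_secondary_accessions_collapse_onto_primary():
    entries = [
        _entry("1ABC", protein="lacY"),
        _entry("1ABD", protein="lacY", is_secondary=True, primary_accession="1ABC"),
    ]
    merged = merge_secondary_accessions(entries)
    assert [e.accession for e in merged] == ["1ABC"]


def test_same_protein_in_two_expression_systems_keeps_both_records():
    # OmpG-style: one unique structure solved from two host/promoter systems
    entries = [
        _entry("2F1C", protein="ompG", host="C43(DE3)", promoter="ara"),
        _entry("2IWW", protein="ompG", host="C41(DE3)", promoter="T7"),
    ]
    merged = merge_secondary_accessions(entries)
    assert len(merged) == 2
    assert unique_structure_count(merged) == 1


def test_dangling_primary_accession_is_a_curation_error():
    bad = [_entry("1XYZ", is_secondary=True, primary_accession="GONE")]
    with pytest.raises(CurationError, match="1XYZ"):
        merge_secondary_accessions(bad)


def test_merge_of_empty_ledger_is_empty():
    assert merge_secondary_accessions([]) == []


def test_entry_topology_span_invariants():
    with pytest.raises(CurationError):
        _entry("1A", topology="bitopic", tm_spans=2)
    with pytest.raises(CurationError):
        _entry("1B", topology="alpha_monotopic", tm_spans=1)
    with pytest.raises(CurationError):
        _entry("1C", topology="alpha_IMP", tm_spans=1)
    assert _entry("1D", topology="alpha_IMP", tm_spans=7).tm_spans == 7


# ---------------------------------------------------------------------------
# cross-tabulation against the printed tables


def test_heterologous_table_reproduces_printed_totals_and_percentages(table1_entries):
    ct = build_crosstab(merge_secondary_accessions(table1_entries), "non_ecoli")
    assert ct.grand_total == 163
    assert ct.col_labels == ("T7", "ara", "T5", "tet", "tac_trp")
    assert ct.col_totals == (102, 28, 11, 8, 14)
    assert ct.col_percentages == (63, 17, 7, 5, 8)


def test_homologous_table_reproduces_printed_totals_and_percentages(table2_entries):
    order = ["T7", "native", "ara", "tac_trp", "T5", "tet", "other"]
    ct = build_crosstab(table2_entries, "ecoli", col_order=order)
    assert ct.grand_total == 103
    assert ct.col_totals == (62, 19, 8, 9, 2, 1, 2)
    assert ct.col_percentages == (60, 18, 8, 9, 2, 1, 2)


def test_single_entry_crosstab_is_total_one_percent_100():
    ct = build_crosstab([_entry("1A")])
    assert ct.grand_total == 1
    assert ct.col_percentages == (100,)


def test_crosstab_counts_match_bruteforce_double_loop():
    rng = np.random.default_rng(42)
    hosts = ["BL21(DE3)", "C41(DE3)", "C43(DE3)", "XL1-Blue"]
    promoters = ["T7", "ara", "T5"]
    entries = [
        _entry(
            f"E{i}",
            protein=f"p{i}",
            host=hosts[rng.integers(len(hosts))],
            promoter=promoters[rng.integers(len(promoters))],
        )
        for i in range(30)
    ]
    ct = build_crosstab(entries)
    for i, h in enumerate(ct.row_labels):
        for j, p in enumerate(ct.col_labels):
            brute = sum(1 for e in entries if e.host == h and e.promoter == p)
            assert ct.counts[i, j] == brute
    assert ct.grand_total == len(entries)


def test_organism_filter_partitions_the_merged_ledger(table1_entries, table2_entries):
    both = list(table1_entries) + list(table2_entries)
    non_eco = build_crosstab(both, "non_ecoli")
    eco = build_crosstab(both, "ecoli")
    assert non_eco.grand_total + eco.grand_total == len(both)


# ---------------------------------------------------------------------------
# host-group contribution percentages


def test_mutant_hosts_contribute_28_percent_of_heterologous_structures(table1_entries):
    ct = build_crosstab(table1_entries, "non_ecoli")
    assert host_contribution(ct, {"C41(DE3)", "C43(DE3)"}, ct.grand_total) == 28


def test_mutant_hosts_contribute_19_percent_of_homologous_systems(table2_entries):
    ct = build_crosstab(table2_entries, "ecoli")
    # denominator: the stated number of unique expression systems
    assert host_contribution(ct, {"C41(DE3)", "C43(DE3)"}, 111) == 19


def test_contribution_of_all_hosts_is_100_and_monotone(table1_entries):
    ct = build_crosstab(table1_entries, "non_ecoli")
    assert host_contribution(ct, set(ct.row_labels), ct.grand_total) == 100
    acc = []
    prev = 0
    for h in ct.row_labels:
        acc.append(h)
        cur = host_contribution(ct, acc, ct.grand_total)
        assert 0 <= cur <= 100
        assert cur >= prev
        prev = cur


def test_unknown_host_row_is_named_in_the_error(table1_entries):
    ct = build_crosstab(table1_entries, "non_ecoli")
    with pytest.raises(KeyError, match="NOPE"):
        host_contribution(ct, {"NOPE"}, ct.grand_total)


def test_unique_structure_accounting_gives_141_plus_72(table1_entries, table2_entries):
    assert unique_structure_count(table1_entries) == 141
    assert unique_structure_count(table2_entries) == 72
    assert (
        unique_structure_count(table1_entries) + unique_structure_count(table2_entries)
        == 213
    )


# ---------------------------------------------------------------------------
# topology tallies


def test_topology_tally_equals_bruteforce_count():
    rng = np.random.default_rng(7)
    tops = ["alpha_monotopic", "bitopic", "alpha_IMP", "beta_barrel", "unclassified"]
    spans = {"alpha_monotopic": 0, "bitopic": 1, "alpha_IMP": 4, "beta_barrel": 0,
             "unclassified": 0}
    entries = []
    for i in range(10):
        top = tops[rng.integers(len(tops))]
        host = ["C41(DE3)", "C43(DE3)"][rng.integers(2)]
        entries.append(
            _entry(f"T{i}", protein=f"q{i}", host=host, topology=top, tm_spans=spans[top])
        )
    tally = topology_tally(entries, promoter_filter="T7")
    total = sum(sum(v.values()) for v in tally.values())
    assert total == sum(1 for e in entries if e.promoter == "T7")
    for host in {e.host for e in entries}:
        for top in tops:
            brute = sum(1 for e in entries if e.host == host and e.topology == top)
            assert tally[host][top] == brute


def test_topology_tally_respects_promoter_filter_and_unclassified_bucket():
    entries = [
        _entry("A1", host="C43(DE3)", promoter="T7", topology="alpha_IMP", tm_spans=6),
        _entry("A2", host="C43(DE3)", promoter="ara", topology="beta_barrel"),
        _entry("A3", host="C41(DE3)", promoter="T7"),  # unclassified
    ]
    tally = topology_tally(entries, promoter_filter="T7")
    assert tally["C43(DE3)"]["alpha_IMP"] == 1
    assert "ara" not in str(tally) and sum(tally["C43(DE3)"].values()) == 1
    assert tally["C41(DE3)"]["unclassified"] == 1


# ---------------------------------------------------------------------------
# frequent-user plasmid distribution


def test_frequent_user_table_reproduces_printed_percentages():
    cells, article_counts = load_lab_fixture()
    usage = lab_usage_distribution(cells, article_counts)
    assert usage.total_citations == 124
    assert usage.percent == {
        "C41(DE3):pRSET": 35,
        "C41(DE3):pHis/pMW7": 18,
        "C41(DE3):pET": 11,
        "C43(DE3):pET": 13,
    }
    assert usage.percent_of(["C41(DE3):pRSET", "C41(DE3):pHis/pMW7"]) == 53
    assert usage.percent_of(["C43(DE3):pET"]) == 13


def test_negative_citation_counts_are_rejected():
    cells = pd.DataFrame({"C41(DE3):pET": [-1]}, index=["lab"])
    with pytest.raises(ValueError):
        lab_usage_distribution(cells, {"lab": 5})


# ---------------------------------------------------------------------------
# ledger I/O


def test_ledger_roundtrip_comma_and_tab(tmp_path):
    entries = [
        _entry("1A", protein="x", topology="bitopic", tm_spans=1),
        _entry("1B", protein="x", is_secondary=True, primary_accession="1A"),
    ]
    for delim, name in ((",", "ledger.csv"), ("\t", "ledger.tsv")):
        path = tmp_path / name
        write_ledger(entries, path, delimiter=delim)
        back = read_ledger(path)
        assert back == entries


def test_expand_counts_matches_fixture_totals():
    t1 = load_counts_fixture("table1")
    entries = expand_counts_to_entries(t1, "non_ecoli", n_unique=141)
    assert len(entries) == int(t1.to_numpy().sum()) == 163
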