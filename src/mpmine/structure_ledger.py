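"""Curation of membrane-protein structure-provenance records.

A *ledger* holds one row per expression-system record: which bacterial host
and which promoter class produced a deposited membrane-protein structure.
The same unique protein may appear in several rows when it was solved after
production in more than one expression system; duplicate database accessions
for the *same* system (ligand complexes, point mutants, alternative
crystallisation conditions) are secondary accessions and are merged away.

The module computes host x promoter cross-tabulations with integer
percentage rows, host-group contribution percentages, per-host topology
tallies, and the plasmid-usage breakdown of the most frequent user labs.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mpmine.rounding import pct, percentage_row

ORGANISM_CLASSES = ("ecoli", "non_ecoli")
PROMOTERS = ("T7", "ara", "T5", "tet", "tac_trp", "native", "other", "unspecified")
TOPOLOGIES = ("alpha_monotopic", "bitopic", "alpha_IMP", "beta_barrel", "unclassified")
METHODS = ("xray", "nmr", "em", "unspecified")

UNSPECIFIED_HOST_LABEL = "Not specified"


class CurationError(ValueError):
    """Raised when a ledger violates its structural invariants."""


@dataclass(frozen=True)
class StructureEntry:
    """One curated structure-provenance record.

    ``is_secondary`` marks accessions that duplicate a primary entry (same
    protein, same expression system, different ligand/mutant/condition);
    such entries carry the accession of the primary they duplicate.
    """

    accession: str
    protein_name: str
    organism_class: str
    host: str
    promoter: str
    topology: str = "unclassified"
    tm_spans: int = 0
    method: str = "unspecified"
    is_secondary: bool = False
    primary_accession: str = ""

    def __post_init__(self) -> None:
        if self.organism_class not in ORGANISM_CLASSES:
            raise CurationError(f"unknown organism_class {self.organism_class!r}")
        if self.promoter not in PROMOTERS:
            raise CurationError(f"unknown promoter {self.promoter!r}")
        if self.topology not in TOPOLOGIES:
            raise CurationError(f"unknown topology {self.topology!r}")
        if self.method not in METHODS:
            raise CurationError(f"unknown method {self.method!r}")
        if self.tm_spans < 0:
            raise CurationError("tm_spans must be non-negative")
        if self.is_secondary and not self.primary_accession:
            raise CurationError(f"secondary entry {self.accession} lacks a primary_accession")
        # topology classes constrain the transmembrane-span count
        if self.topology == "bitopic" and self.tm_spans != 1:
            raise CurationError(f"{self.accession}: bitopic entries have exactly 1 TM span")
        if self.topology == "alpha_monotopic" and self.tm_spans != 0:
            raise CurationError(f"{self.accession}: monotopic entries have 0 TM spans")
        if self.topology == "alpha_IMP" and self.tm_spans < 2:
            raise CurationError(f"{self.accession}: alpha_IMP entries have >= 2 TM spans")


@dataclass(frozen=True)
class CrossTab:
    """Host x promoter count matrix with column totals and a percentage row.

    The percentage row rounds each cell half away from zero and repairs any
    over/undershoot of 100 on the rightmost rounded cells, so the row sums
    to exactly 100 and each cell is within one point of the plain rounding
    of ``100 * col_total / grand_total``.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # shape (rows, cols), int
    col_totals: tuple[int, ...] = field(init=False)
    col_percentages: tuple[int, ...] = field(init=False)
    grand_total: int = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        totals = counts.sum(axis=0)
        object.__setattr__(self, "col_totals", tuple(int(t) for t in totals))
        object.__setattr__(self, "grand_total", int(totals.sum()))
        if self.grand_total > 0:
            pcts = percentage_row(list(self.col_totals))
        else:
            pcts = [0] * len(self.col_labels)
        object.__setattr__(self, "col_percentages", tuple(pcts))

    def row_total(self, host: str) -> int:
        try:
            i = self.row_labels.index(host)
        except ValueError:
            raise KeyError(f"unknown host row {host!r}") from None
        return int(self.counts[i].sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))
        df.loc["Total"] = list(self.col_totals)
        df.loc["Total (%)"] = list(self.col_percentages)
        return df

    def to_dict(self) -> dict:
        return {
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "counts": self.counts.tolist(),
            "col_totals": list(self.col_totals),
            "col_percentages": list(self.col_percentages),
            "grand_total": self.grand_total,
        }


# ---------------------------------------------------------------------------
# curation operations


def merge_secondary_accessions(entries: Sequence[StructureEntry]) -> list[StructureEntry]:
    """Collapse secondary accessions onto their primary entries.

    Returns the primary entries in input order. A unique protein recorded
    under two different expression systems appears as two primary entries and
    both are retained. A secondary entry whose ``primary_accession`` does not
    resolve to a primary entry is a curation error.
    """
    primaries = {e.accession for e in entries if not e.is_secondary}
    for e in entries:
        if e.is_secondary and e.primary_accession not in primaries:
            raise CurationError(
                f"secondary accession {e.accession} points to unknown primary "
                f"{e.primary_accession!r}"
            )
    return [e for e in entries if not e.is_secondary]


def build_crosstab(
    entries: Sequence[StructureEntry],
    organism_filter: str | None = None,
    col_order: Sequence[str] | None = None,
) -> CrossTab:
    """Cross-tabulate merged entries into a host x promoter count matrix.

    Rows appear in order of first appearance; columns follow ``col_order``
    (default: canonical promoter order restricted to promoters present).
    Entries with an empty host are tallied under a dedicated
    "Not specified" row rather than dropped.
    """
    if organism_filter is not None:
        if organism_filter not in ORGANISM_CLASSES:
            raise CurationError(f"unknown organism_class {organism_filter!r}")
        entries = [e for e in entries if e.organism_class == organism_filter]
    hosts: list[str] = []
    for e in entries:
        label = e.host or UNSPECIFIED_HOST_LABEL
        if label not in hosts:
            hosts.append(label)
    present = {e.promoter for e in entries}
    if col_order is None:
        cols = [p for p in PROMOTERS if p in present]
    else:
        cols = list(col_order)
    counts = np.zeros((len(hosts), len(cols)), dtype=int)
    col_index = {c: j for j, c in enumerate(cols)}
    for e in entries:
        label = e.host or UNSPECIFIED_HOST_LABEL
        if e.promoter not in col_index:
            raise CurationError(f"promoter {e.promoter!r} not in requested column order")
        counts[hosts.index(label), col_index[e.promoter]] += 1
    return CrossTab(tuple(hosts), tuple(cols), counts)


def host_contribution(crosstab: CrossTab, hosts: Iterable[str], denominator: int) -> int:
    """Percentage contribution of a set of host rows, over ``denominator``.

    The numerator sums the named rows over all promoter columns. The
    denominator is explicit because the relevant population (all host-vector
    combinations, or the stated number of unique expression systems) is an
    analysis choice, not derivable from the table alone.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    total = 0
    for h in hosts:
        total += crosstab.row_total(h)  # KeyError names unknown hosts
    return pct(total, denominator)


def topology_tally(
    entries: Sequence[StructureEntry], promoter_filter: str | None = None
) -> dict[str, dict[str, int]]:
    """Per-host counts over topology classes, optionally for one promoter.

    Unclassified entries land in the explicit "unclassified" bucket; the sum
    over hosts and classes equals the number of entries matching the filter.
    """
    tally: dict[str, dict[str, int]] = {}
    for e in entries:
        if promoter_filter is not None and e.promoter != promoter_filter:
            continue
        host = e.host or UNSPECIFIED_HOST_LABEL
        bucket = tally.setdefault(host, {t: 0 for t in TOPOLOGIES})
        bucket[e.topology] += 1
    return tally


def unique_structure_count(entries: Sequence[StructureEntry]) -> int:
    """Number of unique protein structures behind a merged ledger.

    Records of the same protein expressed in two systems contribute two
    ledger rows but one unique structure; deduplication is on protein
    identity.
    """
    return len({e.protein_name for e in entries})


# ---------------------------------------------------------------------------
# frequent-user plasmid distribution (lab x host:plasmid-family table)


@dataclass(frozen=True)
class LabUsage:
    """Plasmid usage of the most frequent user labs of a pair of hosts."""

    cells: pd.DataFrame  # labs x "host:family" citation counts
    article_counts: dict[str, int]
    total_citations: int
    percent: dict[str, int]  # per host:family column, percent of total citations

    def percent_of(self, columns: Iterable[str]) -> int:
        """Combined percentage of several host:family columns."""
        num = int(self.cells[list(columns)].to_numpy().sum())
        return pct(num, self.total_citations)


def lab_usage_distribution(
    cells: pd.DataFrame, article_counts: Mapping[str, int]
) -> LabUsage:
    """Summarise a lab x (host:plasmid-family) citation table.

    ``cells`` has one row per laboratory and one column per host:family
    combination; ``article_counts`` gives each laboratory's total citing
    articles. Total citations is the sum of the article counts, and every
    percentage uses it as denominator.
    """
    if (cells.to_numpy() < 0).any():
        raise ValueError("citation counts must be non-negative")
    total = int(sum(article_counts.values()))
    if total <= 0:
        raise ValueError("no citations")
    percent = {c: pct(int(cells[c].sum()), total) for c in cells.columns}
    return LabUsage(cells=cells, article_counts=dict(article_counts), total_citations=total, percent=percent)


# ---------------------------------------------------------------------------
# ledger I/O and fixtures


def _sniff_delimiter(sample: str) -> str:
    header = sample.splitlines()[0] if sample else ""
    return "\t" if "\t" in header else ","


def read_ledger(path: str | Path) -> list[StructureEntry]:
    """Read a delimited (comma or tab, auto-detected) entry-level ledger.

    The header row is mandatory and must name the StructureEntry fields.
    """
    text = Path(path).read_text(encoding="utf-8")
    delim = _sniff_delimiter(text)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    entries = []
    for row in reader:
        entries.append(
            StructureEntry(
                accession=row["accession"],
                protein_name=row["protein_name"],
                organism_class=row["organism_class"],
                host=row["host"],
                promoter=row["promoter"],
                topology=row.get("topology", "unclassified") or "unclassified",
                tm_spans=int(row.get("tm_spans", 0) or 0),
                method=row.get("method", "unspecified") or "unspecified",
                is_secondary=(row.get("is_secondary", "") or "").strip().lower()
                in ("1", "true", "yes"),
                primary_accession=row.get("primary_accession", "") or "",
            )
        )
    return entries


def write_ledger(entries: Sequence[StructureEntry], path: str | Path, delimiter: str = ",") -> None:
    fields = [
        "accession", "protein_name", "organism_class", "host", "promoter",
        "topology", "tm_spans", "method", "is_secondary", "primary_accession",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(fields)
        for e in entries:
            w.writerow([getattr(e, f) for f in fields])


def _data_path(name: str):
    return resources.files("mpmine.data").joinpath(name)


def load_counts_fixture(which: str) -> pd.DataFrame:
    """Load a shipped host x promoter count matrix ("table1" or "table2")."""
    names = {
        "table1": "table1_noneco_counts.csv",
        "table2": "table2_ecoli_counts.csv",
    }
    if which not in names:
        raise KeyError(f"unknown counts fixture {which!r}")
    with resources.as_file(_data_path(names[which])) as p:
        return pd.read_csv(p, index_col="host")


def load_lab_fixture() -> tuple[pd.DataFrame, dict[str, int]]:
    """Load the frequent-user plasmid table: (cells, per-lab article counts)."""
    with resources.as_file(_data_path("table4_frequent_users.csv")) as p:
        df = pd.read_csv(p, index_col="lab")
    article_counts = df["n_articles"].to_dict()
    cells = df.drop(columns=["n_articles"])
    return cells, article_counts


def expand_counts_to_entries(
    counts: pd.DataFrame,
    organism_class: str,
    n_unique: int | None = None,
    prefix: str = "S",
) -> list[StructureEntry]:
    """Expand a host x promoter count matrix into synthetic ledger entries.

    Synthetic stand-in: the count matrix is real summary data but the
    underlying entry-level list (accessions, protein identities) is not
    shipped, so entries are materialised with generated identifiers. When
    ``n_unique`` is given, the first ``n_unique`` entries receive distinct
    protein identities and the remainder reuse earlier identities, modelling
    unique structures solved in more than one expression system.
    """
    total = int(counts.to_numpy().sum())
    if n_unique is None:
        n_unique = total
    if not 0 < n_unique <= total:
        raise ValueError("n_unique must be in (0, total]")
    entries: list[StructureEntry] = []
    k = 0
    for host, row in counts.iterrows():
        for promoter, n in row.items():
            for _ in range(int(n)):
                protein = f"{prefix}P{(k % n_unique) + 1:04d}"
                host_label = "" if host == UNSPECIFIED_HOST_LABEL else str(host)
                entries.append(
                    StructureEntry(
                        accession=f"{prefix}{k + 1:04d}",
                        protein_name=protein,
                        organism_class=organism_class,
                        host=host_label,
                        promoter=str(promoter),
                    )
                )
                k += 1
    return entries
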