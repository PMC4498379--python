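"""Loading of a partitioned plain-text article corpus.

Articles live under ``corpus/<group>/<article_id>.txt`` with one
subdirectory per citation group:

* ``g1_c41c43`` — articles citing the C41(DE3)/C43(DE3) mutant hosts,
* ``g2_bl21``   — articles citing the parental BL21(DE3) T7 host,
* ``g3_ara``    — articles citing the arabinose (pBAD) expression system.

Text is lowercased exactly once at ingest and typographic variants of the
degree sign, micro sign, dashes and non-breaking spaces are canonicalised,
so every downstream regex operates on a single spelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from mpmine.rounding import pct

logger = logging.getLogger(__name__)

GROUPS = ("g1_c41c43", "g2_bl21", "g3_ara")

_CHAR_MAP = str.maketrans(
    {
        "℃": "°c",   # ℃
        "º": "°",    # masculine ordinal used as degree sign
        "–": "-",    # en dash
        "—": "-",    # em dash
        "−": "-",    # minus sign
        " ": " ",    # no-break space
        "μ": "µ",  # Greek mu -> micro sign
        "’": "'",
        "“": '"',
        "”": '"',
    }
)


def normalize_text(raw: str) -> str:
    """Lowercase and canonicalise the symbols the extraction regexes rely on."""
    return raw.translate(_CHAR_MAP).lower()


@dataclass(frozen=True)
class ArticleRecord:
    """One corpus document with its citation-group label and normalized text."""

    article_id: str
    group: str
    text: str
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not self.text:
            raise ValueError(f"article {self.article_id!r} has empty text")


def load_corpus(root: str | Path) -> list[ArticleRecord]:
    """Load every readable ``.txt`` file under the per-group layout.

    Files are visited in sorted order per group, so the result is
    deterministic for a given directory. Unreadable or empty files are
    logged and skipped; a duplicate article id anywhere in the corpus is an
    error.
    """
    root = Path(root)
    records: list[ArticleRecord] = []
    seen: set[str] = set()
    skipped = 0
    for group in GROUPS:
        gdir = root / group
        if not gdir.is_dir():
            continue
        for path in sorted(gdir.glob("*.txt")):
            article_id = path.stem
            if article_id in seen:
                raise ValueError(f"duplicate article id {article_id!r} at {path}")
            try:
                raw = path.read_text(encoding="utf-8", errors="strict")
            except (OSError, UnicodeError) as exc:
                logger.warning("skipping unreadable file %s: %s", path, exc)
                skipped += 1
                continue
            if not raw.strip():
                logger.warning("skipping empty file %s", path)
                skipped += 1
                continue
            seen.add(article_id)
            records.append(
                ArticleRecord(
                    article_id=article_id,
                    group=group,
                    text=normalize_text(raw),
                    source_path=str(path),
                )
            )
    if skipped:
        logger.warning("%d corpus files were skipped", skipped)
    return records


def group_counts(records: Iterable[ArticleRecord]) -> dict[str, int]:
    counts = {g: 0 for g in GROUPS}
    for r in records:
        counts[r.group] += 1
    return counts


def keyword_frequency(
    records: Sequence[ArticleRecord], pattern: str
) -> dict[str, int | None]:
    """Per-group percentage of articles containing a literal phrase.

    One positive hit per article is sufficient: match multiplicity within a
    document never changes the count. Empty groups report ``None`` (the rate
    is undefined), never zero.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    needle = normalize_text(pattern)
    sizes = {g: 0 for g in GROUPS}
    hits = {g: 0 for g in GROUPS}
    for r in records:
        sizes[r.group] += 1
        if needle in r.text:
            hits[r.group] += 1
    return {g: (pct(hits[g], sizes[g]) if sizes[g] else None) for g in GROUPS}
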