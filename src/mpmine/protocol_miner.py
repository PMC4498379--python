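"""Regex extraction of expression-protocol parameters from article text.

All functions operate on ingested text (lowercased, symbols canonicalised
by :func:`mpmine.corpus_ingest.normalize_text`). Extraction is deterministic
and position-stable: every hit carries its character offset and containing
line.

Temperatures are found wherever one-to-three digits are preceded by a space
or a minus and followed by an (optional) degree sign and a ``c``; that
global sweep deliberately picks up centrifugation, storage and denaturation
temperatures alongside growth temperatures. A second pass classifies each
value: a trigger expression ("harvested/cultured/grown/cultivated ... at")
immediately before the value marks growth; decoy heuristics mechanise the
manual-annotation step the global search otherwise needs; everything left
is flagged for review rather than silently counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from mpmine.corpus_ingest import ArticleRecord
from mpmine.normalizer import UnitError, classify_plasmid, normalize_concentration

CONTEXT_CLASSES = ("growth", "induction", "other", "unknown")

# one-to-three digits, preceded by whitespace or a minus, followed by an
# optional degree sign and a bare "c" not opening a longer word
_TEMP_RE = re.compile(r"(?<=[\s\-])(\d{1,3})(?:\s?°\s?|\s|°)c(?![a-z0-9])")

# growth trigger: verb then "at" ending just before the value
_TRIGGER_RE = re.compile(
    r"(harvested|cultured|grown|cultivated)\b[^.;!?\n]{0,30}?\bat\s*$"
)
_TRIGGER_WINDOW = 40  # chars before the value the trigger must end within

_DENATURATION_WORDS = ("denatur", "boil", "heat", "sds", "pcr")

_AMOUNT_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(mm|µm|um|m)\b")
_PERCENT_RE = re.compile(r"(\d+(?:\.\d+)?)\s*%")
_UNINDUCED_RE = re.compile(
    r"\b(?:without|no|absence\s+of|lacking)\s+(?:any\s+)?(?:addition\s+of\s+)?iptg\b"
)

_PLASMID_RE = re.compile(
    r"\bp(?:et\d{0,2}[a-z]?|rset|gem|mw7|his|run|dest|ivex|pr-iba|lyss|lyse|laci"
    r"|bad|gex|ask|qe|mal|rare|cdna)[a-z0-9.+\-]*"
)

KEYWORD_PHRASE = "membrane protein"


@dataclass(frozen=True)
class ExtractionHit:
    """One matched span with its context classification."""

    article_id: str
    category: str  # temperature | inducer | plasmid | keyword
    raw_span: str
    line_context: str
    char_offset: int
    context_class: str = "unknown"
    needs_review: bool = False

    def __post_init__(self) -> None:
        if self.context_class not in CONTEXT_CLASSES:
            raise ValueError(f"unknown context class {self.context_class!r}")
        if self.context_class == "unknown" and not self.needs_review:
            object.__setattr__(self, "needs_review", True)


@dataclass(frozen=True)
class TemperatureObservation:
    value_celsius: int
    char_offset: int  # offset of the first digit (sign excluded)
    raw_span: str
    line_context: str
    context_class: str = "unknown"
    trigger: str = ""
    needs_review: bool = False

    def __post_init__(self) -> None:
        if not -99 <= self.value_celsius <= 999:
            raise ValueError("temperature out of the one-to-three-digit range")


@dataclass(frozen=True)
class InducerObservation:
    inducer: str  # iptg | arabinose | other
    amount: float | None
    unit_raw: str
    amount_mM: float | None = None
    percent_wv: float | None = None
    uninduced: bool = False
    char_offset: int = 0
    line_context: str = ""
    needs_review: bool = False

    def __post_init__(self) -> None:
        if not self.uninduced and not self.needs_review:
            if (self.amount_mM is None) == (self.percent_wv is None):
                raise ValueError("exactly one of amount_mM / percent_wv must be set")


@dataclass(frozen=True)
class PlasmidMention:
    name: str
    family: str
    char_offset: int
    line_context: str


def _line_of(text: str, pos: int) -> str:
    start = text.rfind("\n", 0, pos) + 1
    end = text.find("\n", pos)
    if end == -1:
        end = len(text)
    return text[start:end]


# ---------------------------------------------------------------------------
# temperature


def find_temperatures(text: str) -> list[TemperatureObservation]:
    """All matches of the global temperature sweep, context not yet classed.

    A minus directly before the digits makes the value negative. Four-digit
    numbers and digits embedded in words never match (the pattern requires a
    space or minus before and a free-standing ``c`` after).
    """
    out = []
    for m in _TEMP_RE.finditer(text):
        value = int(m.group(1))
        if text[m.start() - 1] == "-":
            value = -value
        out.append(
            TemperatureObservation(
                value_celsius=value,
                char_offset=m.start(),
                raw_span=text[m.start() - 1 : m.end()],
                line_context=_line_of(text, m.start()),
            )
        )
    return out


def classify_growth(
    observations: Sequence[TemperatureObservation], text: str
) -> list[TemperatureObservation]:
    """Assign a context class to each temperature observation.

    Rules, in order: negative values are never growth (storage/freezer
    context); a trigger expression ending within the window before the value
    marks growth; 4 °C on a centrifugation line and values >= 90 °C on a
    denaturation line are decoys; anything left is unknown and flagged for
    review.
    """
    classed = []
    for obs in observations:
        line = obs.line_context
        if obs.value_celsius < 0:
            classed.append(replace(obs, context_class="other"))
            continue
        window = text[max(0, obs.char_offset - _TRIGGER_WINDOW) : obs.char_offset]
        # strip the sign/space that separates trigger from value
        window = window.rstrip("- ")
        trig = _TRIGGER_RE.search(window)
        if trig:
            classed.append(
                replace(obs, context_class="growth", trigger=trig.group(0).strip())
            )
            continue
        if obs.value_celsius == 4 and "centrifug" in line:
            classed.append(replace(obs, context_class="other"))
            continue
        if obs.value_celsius >= 90 and any(w in line for w in _DENATURATION_WORDS):
            classed.append(replace(obs, context_class="other"))
            continue
        classed.append(replace(obs, context_class="unknown", needs_review=True))
    return classed


# ---------------------------------------------------------------------------
# inducer


def find_inducer(text: str) -> tuple[list[InducerObservation], list[str]]:
    """Scan every line naming the inducer for explicit amounts.

    Lines containing ``iptg`` yield molar-unit amounts normalised to mM;
    lines containing ``arabinose`` yield % (w/v) values. "without iptg" and
    variants yield an uninduced observation. Returns ``(observations,
    review_lines)`` where ``review_lines`` are inducer lines in which no
    amount could be parsed. A line with several amounts returns all of
    them, each flagged for review.
    """
    observations: list[InducerObservation] = []
    review_lines: list[str] = []
    offset = 0
    for line in text.split("\n"):
        if "iptg" in line:
            if _UNINDUCED_RE.search(line):
                observations.append(
                    InducerObservation(
                        inducer="iptg", amount=None, unit_raw="", uninduced=True,
                        char_offset=offset, line_context=line,
                    )
                )
            else:
                matches = list(_AMOUNT_RE.finditer(line))
                conflict = len(matches) > 1
                if not matches:
                    review_lines.append(line)
                for m in matches:
                    amount = float(m.group(1))
                    unit = m.group(2)
                    try:
                        mM = normalize_concentration(amount, unit)
                    except (UnitError, ValueError):
                        review_lines.append(line)
                        continue
                    observations.append(
                        InducerObservation(
                            inducer="iptg", amount=amount, unit_raw=unit,
                            amount_mM=mM, char_offset=offset + m.start(),
                            line_context=line, needs_review=conflict,
                        )
                    )
        elif "arabinose" in line:
            for m in _PERCENT_RE.finditer(line):
                observations.append(
                    InducerObservation(
                        inducer="arabinose", amount=float(m.group(1)),
                        unit_raw="%", percent_wv=float(m.group(1)),
                        char_offset=offset + m.start(), line_context=line,
                    )
                )
        offset += len(line) + 1
    return observations, review_lines


# ---------------------------------------------------------------------------
# plasmids


def find_plasmids(text: str) -> list[PlasmidMention]:
    """Lexicon matches of plasmid names, classified into families.

    Every mention is returned; tallying callers deduplicate to at most one
    count per family per article.
    """
    out = []
    for m in _PLASMID_RE.finditer(text):
        name = m.group(0).rstrip(".-+")
        out.append(
            PlasmidMention(
                name=name,
                family=classify_plasmid(name).family,
                char_offset=m.start(),
                line_context=_line_of(text, m.start()),
            )
        )
    return out


def plasmid_families(text: str) -> set[str]:
    """Distinct plasmid families cited in one article (one count each)."""
    return {p.family for p in find_plasmids(text)}


# ---------------------------------------------------------------------------
# corpus-level driver


def mine_corpus(
    records: Iterable[ArticleRecord], keyword: str = KEYWORD_PHRASE
) -> pd.DataFrame:
    """Run every extractor over a corpus and return a flat hit table.

    Columns: article_id, group, category, value, unit, family,
    context_class, needs_review, raw_span, line_context, char_offset.
    Temperature rows carry °C values; inducer rows carry mM (IPTG) or
    % w/v (arabinose) values, with ``unit == 'uninduced'`` marking explicit
    no-inducer protocols; plasmid rows are already one per family per
    article; keyword rows are one per article containing the phrase.
    """
    rows: list[dict] = []
    for rec in records:
        temps = classify_growth(find_temperatures(rec.text), rec.text)
        for t in temps:
            rows.append(
                dict(
                    article_id=rec.article_id, group=rec.group,
                    category="temperature", value=float(t.value_celsius),
                    unit="C", family="", context_class=t.context_class,
                    needs_review=t.needs_review, raw_span=t.raw_span.strip(),
                    line_context=t.line_context, char_offset=t.char_offset,
                )
            )
        obs, review_lines = find_inducer(rec.text)
        for o in obs:
            if o.uninduced:
                value, unit = float("nan"), "uninduced"
            elif o.amount_mM is not None:
                value, unit = o.amount_mM, "mM"
            else:
                value, unit = o.percent_wv, "%w/v"
            rows.append(
                dict(
                    article_id=rec.article_id, group=rec.group,
                    category="inducer", value=value, unit=unit,
                    family=o.inducer, context_class="induction",
                    needs_review=o.needs_review, raw_span=f"{o.amount} {o.unit_raw}".strip(),
                    line_context=o.line_context, char_offset=o.char_offset,
                )
            )
        for line in review_lines:
            rows.append(
                dict(
                    article_id=rec.article_id, group=rec.group,
                    category="inducer", value=float("nan"), unit="",
                    family="iptg", context_class="unknown", needs_review=True,
                    raw_span="", line_context=line, char_offset=-1,
                )
            )
        for fam in sorted(plasmid_families(rec.text)):
            rows.append(
                dict(
                    article_id=rec.article_id, group=rec.group,
                    category="plasmid", value=float("nan"), unit="",
                    family=fam, context_class="other", needs_review=False,
                    raw_span="", line_context="", char_offset=-1,
                )
            )
        if keyword and keyword in rec.text:
            rows.append(
                dict(
                    article_id=rec.article_id, group=rec.group,
                    category="keyword", value=float("nan"), unit="",
                    family="", context_class="other", needs_review=False,
                    raw_span=keyword, line_context="", char_offset=rec.text.find(keyword),
                )
            )
    columns = [
        "article_id", "group", "category", "value", "unit", "family",
        "context_class", "needs_review", "raw_span", "line_context", "char_offset",
    ]
    return pd.DataFrame(rows, columns=columns)
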