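"""Canonicalisation of extracted entities.

Three normalisers:

* plasmid names -> plasmid families with copy-number class and replication
  origin label (the T7 vectors split into medium-copy pET, high-copy
  pMB1-origin vectors, and attenuation companions);
* bacterial strain strings -> canonical host labels via an alias table plus
  a conservative edit-distance-1 fuzzy match in which digits are exempt
  (C41 and C43 differ by one digit and must never be conflated);
* inducer concentrations -> millimolar.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

logger = logging.getLogger(__name__)

PLASMID_FAMILIES = (
    "pET_medium_copy",
    "high_copy_T7",
    "T7_attenuation",
    "pET_delta_lacI_lacO",
    "pBAD",
    "pRARE",
    "other_non_T7",
    "negative_control",
)

COPY_CLASSES = ("medium_20_50", "high_200_600", "companion", "n_a")
ORIGIN_LABELS = ("colE1", "pMB1", "other", "unknown")


@dataclass(frozen=True)
class PlasmidFamily:
    family: str
    copy_class: str
    origin_label: str

    def __post_init__(self) -> None:
        if self.family not in PLASMID_FAMILIES:
            raise ValueError(f"unknown plasmid family {self.family!r}")
        if self.copy_class not in COPY_CLASSES:
            raise ValueError(f"unknown copy class {self.copy_class!r}")
        if self.origin_label not in ORIGIN_LABELS:
            raise ValueError(f"unknown origin label {self.origin_label!r}")


# pET variants carrying neither lacI nor a lacO operator in the promoter
_PET_DELTA_NUMBERS = {3, 9, 14, 17, 20, 23}

# stem -> (family, copy_class, origin_label)
_STEM_TABLE: dict[str, tuple[str, str, str]] = {
    "pmw7": ("high_copy_T7", "high_200_600", "pMB1"),
    "phis": ("high_copy_T7", "high_200_600", "pMB1"),
    "prun": ("high_copy_T7", "high_200_600", "pMB1"),
    "pgem": ("high_copy_T7", "high_200_600", "pMB1"),
    "prset": ("high_copy_T7", "high_200_600", "pMB1"),
    "pdest": ("high_copy_T7", "high_200_600", "pMB1"),
    "pivex": ("high_copy_T7", "high_200_600", "pMB1"),
    "ppr-iba": ("high_copy_T7", "high_200_600", "pMB1"),
    "plyss": ("T7_attenuation", "companion", "other"),
    "plyse": ("T7_attenuation", "companion", "other"),
    "placi": ("T7_attenuation", "companion", "other"),
    "pbad": ("pBAD", "n_a", "other"),
    "prare": ("pRARE", "companion", "other"),
    "pgex": ("other_non_T7", "n_a", "other"),
    "pask": ("other_non_T7", "n_a", "other"),
    "pqe": ("other_non_T7", "n_a", "other"),
    "pmal": ("other_non_T7", "n_a", "other"),
    "pcdna": ("negative_control", "n_a", "other"),
}

_PET_RE = re.compile(r"^pet(\d*)")


def classify_plasmid(name: str) -> PlasmidFamily:
    """Map a raw plasmid mention to its family taxonomy entry.

    pET names with the variant numbers 3/9/14/17/20/23 (no lacI/lacO
    attenuation) form their own class; all other pET vectors are the
    medium-copy colE1 default. Names outside the lexicon fall back to
    ``other_non_T7`` with an unknown origin and are logged.
    """
    key = name.strip().lower().replace("μ", "µ")
    m = _PET_RE.match(key)
    if m:
        digits = m.group(1)
        if digits and int(digits) in _PET_DELTA_NUMBERS:
            return PlasmidFamily("pET_delta_lacI_lacO", "medium_20_50", "colE1")
        return PlasmidFamily("pET_medium_copy", "medium_20_50", "colE1")
    for stem in sorted(_STEM_TABLE, key=len, reverse=True):
        if key.startswith(stem):
            fam, copy_class, origin = _STEM_TABLE[stem]
            return PlasmidFamily(fam, copy_class, origin)
    logger.info("plasmid name %r outside lexicon; classed other_non_T7", name)
    return PlasmidFamily("other_non_T7", "n_a", "unknown")


# ---------------------------------------------------------------------------
# host strain canonicalisation

# alias core (alphanumeric, lowercased, lambda dropped) -> canonical label
HOST_ALIASES: dict[str, str] = {
    "c41de3": "C41(DE3)",
    "c41": "C41(DE3)",
    "c43de3": "C43(DE3)",
    "c43": "C43(DE3)",
    "bl21de3": "BL21(DE3)",
    "bl21de3plyss": "BL21(DE3)pLysS",
    "bl21de3plyse": "BL21(DE3)pLysE",
    "bl21de3codonplus": "BL21(DE3)CodonPlus",
    "bl21starde3": "BL21Star(DE3)",
    "bl21de3star": "BL21Star(DE3)",
    "bl21de3tuner": "BL21(DE3)Tuner",
    "bl21rosetta": "BL21Rosetta",
    "bl21ai": "BL21(AI)",
    "bl21gold": "BL21-Gold",
    "bl21t1r": "BL21-T1R",
    "xl1blue": "XL1-Blue",
    "dh5a": "DH5a",
    "dh5alpha": "DH5a",
    "top10": "TOP10",
    "dh10b": "DH10B/TOP10",
}


def _core(raw: str) -> str:
    """Alphanumeric core: lowercased, lambda and punctuation stripped."""
    s = raw.lower().replace("λ", "").replace("lambda", "")
    return re.sub(r"[^a-z0-9]", "", s)


def _edit1_no_digit(a: str, b: str) -> bool:
    """True when edit distance <= 1 and no edit operation touches a digit."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:  # one substitution
        diffs = [(x, y) for x, y in zip(a, b) if x != y]
        return len(diffs) == 1 and not (diffs[0][0].isdigit() or diffs[0][1].isdigit())
    if la > lb:
        a, b = b, a
        la, lb = lb, la
    # b is one char longer: one insertion
    for i in range(la + 1):
        if a[:i] + b[i] + a[i:] == b:
            return not b[i].isdigit()
    return False


def normalize_host(raw: str, aliases: dict[str, str] | None = None) -> str:
    """Canonicalise a strain string via alias table, then edit-distance 1.

    The fuzzy stage accepts a single non-digit typo against a known alias
    core; digits never take part in an edit so C41/C43 stay distinct.
    Unresolvable strings pass through unchanged (and are logged).
    """
    table = HOST_ALIASES if aliases is None else aliases
    core = _core(raw)
    if core in table:
        return table[core]
    for alias, canonical in table.items():
        if _edit1_no_digit(core, alias):
            return canonical
    logger.info("host %r not in alias table; passing through", raw)
    return raw


# ---------------------------------------------------------------------------
# concentration units


class UnitError(ValueError):
    """Raised for a concentration unit outside the accepted spellings."""


_UNIT_TO_MM = {
    "m": 1000.0,
    "mm": 1.0,
    "µm": 1e-3,
    "μm": 1e-3,
    "um": 1e-3,
}


def normalize_concentration(amount: float, unit_raw: str) -> float:
    """Exact scaling of an inducer amount to millimolar."""
    if amount <= 0:
        raise ValueError("amount must be positive")
    key = unit_raw.strip().lower()
    if key not in _UNIT_TO_MM:
        raise UnitError(f"unknown concentration unit {unit_raw!r}")
    return amount * _UNIT_TO_MM[key]
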