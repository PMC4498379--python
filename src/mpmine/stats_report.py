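"""Distribution summaries, threshold fractions, citation frequencies, ANOVA.

The reporting layer turns the flat hit table produced by
:func:`mpmine.protocol_miner.mine_corpus` into the quantities of interest:
the fraction of protocols inducing at or below a concentration threshold,
the fraction growing at or below a temperature, binned distributions of
both parameters, per-group plasmid-family citation percentages, and a
one-way ANOVA comparing the parameter distributions across citation groups
(significance at alpha = 0.05).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from mpmine.rounding import pct

ALPHA = 0.05

# default bin edges; the upper IPTG edge is open-ended
IPTG_EDGES_MM = (0.0, 0.01, 0.1, 0.5, 1.0, math.inf)
TEMP_EDGES_C = (0.0, 16.0, 20.0, 25.0, 30.0, 37.0, 42.0)


@dataclass(frozen=True)
class DistributionSummary:
    """Binned distribution of an extracted protocol parameter.

    Fractions are over the articles (or values) with an explicit value,
    mirroring how such distributions are conventionally reported: percent of
    the total number of articles where an explicit value was found.
    """

    variable: str  # iptg_mM | growth_temp_C
    bin_edges: tuple[float, ...]
    bin_fractions: tuple[float, ...]
    n_explicit: int
    group: str = "pooled"
    underflow: int = 0
    overflow: int = 0
    bimodal: bool = False

    @property
    def bin_percent(self) -> tuple[int, ...]:
        return tuple(pct(f, 1) for f in self.bin_fractions)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "group": self.group,
            "bin_edges": list(self.bin_edges),
            "bin_fractions": list(self.bin_fractions),
            "bin_percent": list(self.bin_percent),
            "n_explicit": self.n_explicit,
            "underflow": self.underflow,
            "overflow": self.overflow,
            "bimodal": self.bimodal,
        }


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    group_ns: tuple[int, ...]
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.f_statistic < 0:
            raise ValueError("F statistic is non-negative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value must lie in [0, 1]")
        object.__setattr__(self, "significant", bool(self.p_value < ALPHA))

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "group_ns": list(self.group_ns),
            "significant": self.significant,
        }


def fraction_at_or_below(
    values: Sequence[float], threshold: float, strict: bool = False
) -> float:
    """P(value < threshold) when strict, else P(value <= threshold)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("fraction over an empty value list is undefined")
    if strict:
        return float((vals < threshold).mean())
    return float((vals <= threshold).mean())


def histogram(
    values: Sequence[float],
    bin_edges: Sequence[float],
    variable: str = "",
    group: str = "pooled",
) -> DistributionSummary:
    """Bin values into half-open [lo, hi) bins, final bin closed.

    Values outside the edges are tallied in under/overflow counters and
    excluded from the fractions, which are over the in-range values.
    """
    edges = tuple(float(e) for e in bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    vals = np.asarray(list(values), dtype=float)
    under = int((vals < edges[0]).sum())
    over = int((vals > edges[-1]).sum())
    in_range = vals[(vals >= edges[0]) & (vals <= edges[-1])]
    finite_edges = np.asarray(edges)
    # np.histogram implements half-open bins with the final bin closed
    counts, _ = np.histogram(in_range, bins=finite_edges)
    n = int(in_range.size)
    fractions = tuple((counts / n).tolist()) if n else tuple(0.0 for _ in counts)
    order = np.argsort(counts)[::-1]
    bimodal = len(counts) >= 3 and n > 0 and abs(int(order[0]) - int(order[1])) > 1
    return DistributionSummary(
        variable=variable,
        bin_edges=edges,
        bin_fractions=fractions,
        n_explicit=n,
        group=group,
        underflow=under,
        overflow=over,
        bimodal=bimodal,
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA over two or more groups.

    F and p come from the F distribution with (k-1, N-k) degrees of freedom.
    The fully degenerate case — zero variance within every group and equal
    means — is defined as F = 0, p = 1 (no evidence of any difference).
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    means = [a.mean() for a in arrays]
    within_ss = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    if within_ss == 0.0:
        if np.allclose(means, means[0]):
            f, p = 0.0, 1.0
        else:
            f, p = math.inf, 0.0
        return AnovaResult(f, p, tuple(a.size for a in arrays))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.f_oneway(*arrays)
    return AnovaResult(float(res.statistic), float(res.pvalue), tuple(a.size for a in arrays))


def vector_citation_frequencies(
    hits: pd.DataFrame, group_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """Per-group plasmid-family citation percentages.

    ``hits`` is a mined hit table; plasmid rows are already deduplicated to
    one per family per article, so the percentage for a family is the share
    of the group's articles citing it at least once. Groups of size zero
    are reported as missing (NA), never as zero.
    """
    plasmid = hits[hits["category"] == "plasmid"]
    families = sorted(plasmid["family"].unique())
    groups = sorted(group_sizes)
    table = pd.DataFrame(index=families, columns=groups, dtype=float)
    for g in groups:
        n = group_sizes[g]
        sub = plasmid[plasmid["group"] == g]
        for fam in families:
            if n == 0:
                table.loc[fam, g] = float("nan")
            else:
                cited = sub[sub["family"] == fam]["article_id"].nunique()
                table.loc[fam, g] = pct(cited, n)
    return table


# ---------------------------------------------------------------------------
# report assembly


def _explicit_iptg(hits: pd.DataFrame, include_review: bool) -> pd.DataFrame:
    sel = (hits["category"] == "inducer") & (hits["unit"] == "mM")
    if not include_review:
        sel &= ~hits["needs_review"]
    return hits[sel]


def _growth_temps(hits: pd.DataFrame, include_review: bool) -> pd.DataFrame:
    sel = (hits["category"] == "temperature") & (hits["context_class"] == "growth")
    if include_review:
        sel = (hits["category"] == "temperature") & (
            hits["context_class"].isin(["growth", "unknown"])
        )
    return hits[sel]


def _distinct_values(df: pd.DataFrame) -> tuple[list[float], int]:
    """One contribution per distinct value per article; n counts articles."""
    pairs = df[["article_id", "value"]].drop_duplicates()
    return pairs["value"].tolist(), int(df["article_id"].nunique())


def summarize_protocols(
    hits: pd.DataFrame,
    group_sizes: Mapping[str, int],
    iptg_threshold_mM: float = 0.5,
    temp_threshold_C: float = 30.0,
    strict: bool = False,
    include_review: bool = False,
    iptg_edges: Sequence[float] = IPTG_EDGES_MM,
    temp_edges: Sequence[float] = TEMP_EDGES_C,
) -> dict:
    """Assemble the full protocol-mining report from a hit table.

    Returns a dict with pooled and per-group threshold fractions and
    histograms for IPTG (mM) and growth temperature (°C), the ANOVA
    comparing groups, keyword and plasmid-family citation percentages.
    An article with several distinct extracted values contributes each value
    once; review-flagged hits are excluded unless ``include_review``.
    """
    report: dict = {
        "n_articles": dict(group_sizes),
        "include_review": include_review,
        "strict_threshold": strict,
    }

    iptg = _explicit_iptg(hits, include_review)
    temps = _growth_temps(hits, include_review)

    for name, df, thr, edges, var in (
        ("iptg_mM", iptg, iptg_threshold_mM, iptg_edges, "iptg_mM"),
        ("growth_temp_C", temps, temp_threshold_C, temp_edges, "growth_temp_C"),
    ):
        values, n_articles = _distinct_values(df)
        block: dict = {"n_values": len(values), "n_articles_explicit": n_articles}
        if values:
            frac = fraction_at_or_below(values, thr, strict=strict)
            block["threshold"] = thr
            block["fraction_at_or_below"] = frac
            block["percent_at_or_below"] = pct(frac, 1)
            block["histogram"] = histogram(values, edges, variable=var).to_dict()
        else:
            block["fraction_at_or_below"] = None
            block["percent_at_or_below"] = None
            block["histogram"] = None
        per_group = {}
        for g in sorted(group_sizes):
            gvals, gn = _distinct_values(df[df["group"] == g])
            if gvals:
                gfrac = fraction_at_or_below(gvals, thr, strict=strict)
                per_group[g] = {
                    "n_values": len(gvals),
                    "n_articles_explicit": gn,
                    "fraction_at_or_below": gfrac,
                    "percent_at_or_below": pct(gfrac, 1),
                }
            else:
                per_group[g] = {
                    "n_values": 0,
                    "n_articles_explicit": 0,
                    "fraction_at_or_below": None,
                    "percent_at_or_below": None,
                }
        block["per_group"] = per_group
        # ANOVA across groups with at least two values
        anova_groups = [
            df[df["group"] == g]["value"].tolist()
            for g in sorted(group_sizes)
            if len(df[df["group"] == g]) >= 2
        ]
        block["anova"] = (
            one_way_anova(anova_groups).to_dict() if len(anova_groups) >= 2 else None
        )
        report[name] = block

    keyword = hits[hits["category"] == "keyword"]
    report["keyword_percent"] = {
        g: (pct(int(keyword[keyword["group"] == g]["article_id"].nunique()), n) if n else None)
        for g, n in group_sizes.items()
    }
    vec = vector_citation_frequencies(hits, group_sizes)
    report["vector_citation_percent"] = {
        fam: {g: (None if pd.isna(v) else int(v)) for g, v in row.items()}
        for fam, row in vec.iterrows()
    }
    return report
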