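"""Ground-truthed synthetic article corpus generator.

Emulates the statistical structure the protocol-mining pipeline assumes in
a real methods-section corpus: a bimodal growth-temperature mixture peaked
at 37 °C with a ≤30 °C shoulder, a bimodal IPTG mixture peaked at 1 mM with
a sub-0.5 mM half including a sub-10 µM tail, decoy temperatures
(centrifugation at 4 °C, storage at −20/−80 °C, denaturation at 95/100 °C),
per-group plasmid-family citation rates, and group-specific
"membrane protein" keyword rates. Every planted entity is recorded in a
truth table so extraction precision and recall are measurable exactly.

Articles are generated from sentence templates; a configurable fraction of
articles additionally carries a deliberately ambiguous temperature sentence
(no trigger verb, no decoy vocabulary) to exercise the review-flag path.
Ambiguous plants are marked in the truth table and excluded from
precision/recall scoring.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from mpmine.corpus_ingest import GROUPS, ArticleRecord, normalize_text

# default mixtures calibrated so that P(IPTG <= 0.5 mM) = 0.50 and
# P(growth temperature <= 30 °C) = 0.38
DEFAULT_IPTG_MIXTURE: dict[float, float] = {
    1.0: 0.42, 0.7: 0.08, 0.5: 0.15, 0.1: 0.15, 0.05: 0.08, 0.01: 0.06, 0.008: 0.06,
}
DEFAULT_TEMP_MIXTURE: dict[int, float] = {37: 0.62, 30: 0.14, 25: 0.12, 20: 0.07, 18: 0.05}
DEFAULT_ARA_MIXTURE: dict[float, float] = {0.2: 0.5, 0.02: 0.3, 0.002: 0.2}

# per-group plasmid-family citation probabilities (independent per family)
DEFAULT_PLASMID_RATES: dict[str, dict[str, float]] = {
    "g1_c41c43": {
        "pET_medium_copy": 0.40, "pET_delta_lacI_lacO": 0.13, "high_copy_T7": 0.19,
        "T7_attenuation": 0.10, "pRARE": 0.02, "other_non_T7": 0.16, "pBAD": 0.09,
    },
    "g2_bl21": {
        "pET_medium_copy": 0.34, "pET_delta_lacI_lacO": 0.13, "high_copy_T7": 0.13,
        "T7_attenuation": 0.16, "pRARE": 0.004, "other_non_T7": 0.10, "pBAD": 0.03,
    },
    "g3_ara": {
        "pET_medium_copy": 0.19, "pET_delta_lacI_lacO": 0.04, "high_copy_T7": 0.08,
        "T7_attenuation": 0.04, "pRARE": 0.005, "other_non_T7": 0.0, "pBAD": 0.99,
    },
}

DEFAULT_KEYWORD_RATES: dict[str, float] = {
    "g1_c41c43": 0.77, "g2_bl21": 0.25, "g3_ara": 0.45,
}

DEFAULT_DECOY_RATES: dict[str, float] = {
    "centrifugation": 0.5, "storage": 0.4, "denaturation": 0.3,
}

# one concrete plasmid name per family draw
_FAMILY_NAMES: dict[str, tuple[str, ...]] = {
    "pET_medium_copy": ("pET28a", "pET22b", "pET21a"),
    "pET_delta_lacI_lacO": ("pET3a", "pET17", "pET9a"),
    "high_copy_T7": ("pRSET", "pMW7", "pHis", "pGEM", "pIVEX"),
    "T7_attenuation": ("pLysS", "pLysE", "pLacI"),
    "pRARE": ("pRARE",),
    "other_non_T7": ("pGEX", "pASK", "pQE30", "pMAL"),
    "pBAD": ("pBAD24", "pBAD33"),
}

_HOST_BY_GROUP = {"g1_c41c43": "C41(DE3)", "g2_bl21": "BL21(DE3)", "g3_ara": "TOP10"}

_GROWTH_VERBS = ("grown", "cultured", "cultivated")


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Generator parameters and their defaults (the emulated study design).

    Mixture dictionaries map a planted value to its probability and must sum
    to one. ``explicit_value_rate`` is the probability an article states its
    growth temperature / inducer amount at all (half of real methods
    sections do not). ``uninduced_rate`` is the probability that an article
    with explicit induction reports expression without any inducer.
    Identical spec and seed reproduce the corpus byte for byte.
    """

    n_per_group: tuple[int, int, int] = (300, 300, 300)
    iptg_mixture: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_IPTG_MIXTURE)
    )
    temp_mixture: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMP_MIXTURE)
    )
    ara_mixture: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_ARA_MIXTURE)
    )
    decoy_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DECOY_RATES)
    )
    plasmid_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_PLASMID_RATES.items()}
    )
    keyword_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KEYWORD_RATES)
    )
    explicit_value_rate: float = 0.5
    uninduced_rate: float = 0.02
    ambiguous_rate: float = 0.05
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("iptg_mixture", "temp_mixture", "ara_mixture"):
            mix = getattr(self, name)
            total = float(sum(mix.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
            if any(not 0.0 <= p <= 1.0 for p in mix.values()):
                raise ValueError(f"{name} has probabilities outside [0, 1]")
        for rate in (self.explicit_value_rate, self.uninduced_rate, self.ambiguous_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @classmethod
    def calibrated(cls, n_per_group: int = 300, explicit_value_rate: float = 1.0,
                   seed: int = 17) -> "SyntheticCorpusSpec":
        """The default calibrated mixtures with every article explicit."""
        return cls(
            n_per_group=(n_per_group,) * 3,
            explicit_value_rate=explicit_value_rate,
            seed=seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["n_per_group"] = list(self.n_per_group)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticCorpusSpec":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "n_per_group" in d:
            d["n_per_group"] = tuple(d["n_per_group"])
        return cls(**d)


def _draw(rng: np.random.Generator, mixture: Mapping) -> float:
    keys = list(mixture.keys())
    probs = np.asarray([mixture[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _fmt_amount(amount_mM: float) -> tuple[str, str]:
    """Printable (value, unit) for an IPTG amount, µM below 0.1 mM."""
    if amount_mM < 0.1:
        return f"{amount_mM * 1000:g}", "µM"
    return f"{amount_mM:g}", "mM"


def generate_article(
    spec: SyntheticCorpusSpec, group: str, index: int
) -> tuple[ArticleRecord, dict]:
    """Generate one methods-style article and its ground-truth annotations.

    The per-article RNG substream is keyed on (seed, group index, article
    index), so any article is reproducible in isolation.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    gidx = GROUPS.index(group)
    rng = np.random.default_rng([spec.seed, gidx, index])
    article_id = f"{group}_{index:04d}"
    host = _HOST_BY_GROUP[group]

    sentences = [
        "The target gene encoding the protein of interest was amplified by "
        "standard molecular cloning techniques.",
    ]
    truth: dict = {
        "article_id": article_id,
        "group": group,
        "explicit": False,
        "growth_temp_C": None,
        "iptg_mM": None,
        "uninduced": False,
        "ara_percent": None,
        "families": "",
        "keyword": False,
        "ambiguous_temp_C": None,
        "decoys": "",
    }

    # plasmid citations, independent Bernoulli per family
    families = []
    for fam, p in spec.plasmid_rates[group].items():
        if rng.random() < p:
            families.append(fam)
            name = _FAMILY_NAMES[fam][int(rng.integers(len(_FAMILY_NAMES[fam])))]
            sentences.append(
                f"The construct was assembled in the {name} vector and "
                f"transformed into {host} cells."
            )
    truth["families"] = ";".join(sorted(set(families)))

    explicit = rng.random() < spec.explicit_value_rate
    truth["explicit"] = bool(explicit)
    if explicit:
        temp = int(_draw(rng, spec.temp_mixture))
        verb = _GROWTH_VERBS[int(rng.integers(len(_GROWTH_VERBS)))]
        degree = "°C" if rng.random() < 0.7 else "C"
        sentences.append(
            f"Cells were {verb} at {temp} {degree} in LB medium until the "
            "culture reached mid-log phase."
        )
        truth["growth_temp_C"] = temp
        if group == "g3_ara":
            pc = float(_draw(rng, spec.ara_mixture))
            sentences.append(
                f"Expression was induced with {pc:g} % arabinose for 4 h."
            )
            truth["ara_percent"] = pc
        elif rng.random() < spec.uninduced_rate:
            sentences.append(
                "Notably, the recombinant protein accumulated without IPTG "
                "induction owing to leaky expression."
            )
            truth["uninduced"] = True
        else:
            amount = float(_draw(rng, spec.iptg_mixture))
            val, unit = _fmt_amount(amount)
            sentences.append(
                f"Protein production was induced by addition of {val} {unit} "
                "IPTG and continued for 4 h."
            )
            truth["iptg_mM"] = amount

    # decoy temperature sentences (never growth context)
    decoys = []
    if rng.random() < spec.decoy_rates.get("centrifugation", 0.0):
        sentences.append("Cultures were centrifuged at 4 °C for 20 min.")
        decoys.append("centrifugation:4")
    if rng.random() < spec.decoy_rates.get("storage", 0.0):
        t = -80 if rng.random() < 0.5 else -20
        sentences.append(f"Membrane pellets were stored at {t} °C until use.")
        decoys.append(f"storage:{t}")
    if rng.random() < spec.decoy_rates.get("denaturation", 0.0):
        t = 95 if rng.random() < 0.5 else 100
        sentences.append(f"Samples were denatured at {t} °C for 5 min before loading.")
        decoys.append(f"denaturation:{t}")
    truth["decoys"] = ";".join(decoys)

    # deliberately ambiguous temperature (no trigger, no decoy vocabulary)
    if rng.random() < spec.ambiguous_rate:
        t = int(_draw(rng, spec.temp_mixture))
        sentences.append(f"The binding reaction proceeded at {t} °C in buffer A.")
        truth["ambiguous_temp_C"] = t

    if rng.random() < spec.keyword_rates[group]:
        sentences.append(
            "The purified membrane protein was analysed by SDS-PAGE and "
            "size-exclusion chromatography."
        )
        truth["keyword"] = True

    text = "\n".join(sentences) + "\n"
    record = ArticleRecord(
        article_id=article_id, group=group, text=normalize_text(text)
    )
    return record, truth


def generate_records(
    spec: SyntheticCorpusSpec,
) -> tuple[list[ArticleRecord], pd.DataFrame]:
    """Generate the whole corpus in memory with its truth table."""
    records: list[ArticleRecord] = []
    truths: list[dict] = []
    for gidx, group in enumerate(GROUPS):
        for i in range(spec.n_per_group[gidx]):
            rec, truth = generate_article(spec, group, i)
            records.append(rec)
            truths.append(truth)
    return records, pd.DataFrame(truths)


def generate_corpus(
    spec: SyntheticCorpusSpec,
    out_dir: str | Path,
    truth_path: str | Path | None = None,
    force: bool = False,
) -> tuple[list[ArticleRecord], pd.DataFrame]:
    """Write the corpus in the on-disk layout ``<out>/<group>/<id>.txt``.

    Refuses to write into an existing non-empty directory unless ``force``.
    The truth table is written as TSV next to the corpus by default.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(f"output directory {out_dir} is not empty")
        shutil.rmtree(out_dir)
    records, truth = generate_records(spec)
    for rec in records:
        gdir = out_dir / rec.group
        gdir.mkdir(parents=True, exist_ok=True)
        (gdir / f"{rec.article_id}.txt").write_text(rec.text, encoding="utf-8")
    if truth_path is None:
        truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return records, truth


# ---------------------------------------------------------------------------
# extraction scoring against planted truth


def score_extraction(truth: pd.DataFrame, hits: pd.DataFrame) -> dict:
    """Precision/recall of growth-temperature and IPTG-amount extraction.

    Scoring is restricted to unambiguous plants: the planted growth
    temperature and IPTG amount of each article. Review-flagged hits are
    excluded on the extraction side (the pipeline's default tally), and
    ambiguous planted sentences do not count against precision. Also
    reports the number of decoy temperatures that leaked into the growth
    class (should be zero).
    """
    temps = hits[
        (hits["category"] == "temperature")
        & (hits["context_class"] == "growth")
        & (~hits["needs_review"])
    ]
    iptg = hits[
        (hits["category"] == "inducer")
        & (hits["unit"] == "mM")
        & (~hits["needs_review"])
    ]

    truth_temp = {
        row["article_id"]: row["growth_temp_C"]
        for _, row in truth.iterrows()
        if row["growth_temp_C"] is not None and not pd.isna(row["growth_temp_C"])
    }
    truth_iptg = {
        row["article_id"]: row["iptg_mM"]
        for _, row in truth.iterrows()
        if row["iptg_mM"] is not None and not pd.isna(row["iptg_mM"])
    }
    decoy_values = {
        row["article_id"]: {
            int(d.split(":")[1]) for d in str(row["decoys"]).split(";") if d and d != "nan"
        }
        for _, row in truth.iterrows()
    }

    def _pr(extracted: pd.DataFrame, planted: dict, tol: float) -> tuple[float, float, int, int]:
        tp = fp = 0
        recovered: set[str] = set()
        for _, h in extracted.iterrows():
            aid, val = h["article_id"], h["value"]
            if aid in planted and abs(val - planted[aid]) <= tol:
                tp += 1
                recovered.add(aid)
            else:
                fp += 1
        fn = len(set(planted) - recovered)
        precision = tp / (tp + fp) if (tp + fp) else 1.0
        recall = tp / (tp + fn) if (tp + fn) else 1.0
        return precision, recall, tp, fp

    t_prec, t_rec, t_tp, t_fp = _pr(temps, truth_temp, tol=0.0)
    i_prec, i_rec, i_tp, i_fp = _pr(iptg, truth_iptg, tol=1e-9)

    decoys_as_growth = 0
    for _, h in temps.iterrows():
        if h["value"] in decoy_values.get(h["article_id"], set()) and (
            h["article_id"] not in truth_temp
            or h["value"] != truth_temp[h["article_id"]]
        ):
            decoys_as_growth += 1

    return {
        "growth_temp": {"precision": t_prec, "recall": t_rec, "tp": t_tp, "fp": t_fp},
        "iptg": {"precision": i_prec, "recall": i_rec, "tp": i_tp, "fp": i_fp},
        "decoys_classified_growth": decoys_as_growth,
    }
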