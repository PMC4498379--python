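"""Regex extraction: temperatures, inducer amounts, plasmids."""

import re

import pytest

from mpmine.corpus_ingest import ArticleRecord, normalize_text
from mpmine.protocol_miner import (
    classify_growth,
    find_inducer,
    find_plasmids,
    find_temperatures,
    mine_corpus,
    plasmid_families,
)


def _temps(text):
    return [t.value_celsius for t in find_temperatures(normalize_text(text))]


# ---------------------------------------------------------------------------
# temperature pattern


@pytest.mark.parametrize(
    "text,expected",
    [
        ("cells grown at 37 °c overnight", [37]),
        ("lysate stored at -80 °c", [-80]),
        ("heated to 95 c for 5 min", [95]),
        ("incubated at 37°c.", [37]),
        ("kept at 4 ° c in the cold room", [4]),
        ("induced with 2mm iptg", []),  # digits embedded in a quantity
        ("the year 1234 c was not a temperature", []),  # four digits
        ("od600 reached 0.6 at 37 °c", [37]),  # decimals never match
        ("buffer c was used", []),
        ("at 37 celsius", []),  # 'c' opening a longer word
        ("no temperatures here", []),
    ],
)
def test_temperature_pattern(text, expected):
    assert _temps(text) == expected


def test_extraction_is_deterministic_and_position_stable():
    text = normalize_text("Grown at 30 °C. Stored at -20 °C. Heated to 95 C.")
    first = find_temperatures(text)
    second = find_temperatures(text)
    assert first == second
    for obs in first:
        assert text[obs.char_offset] == str(abs(obs.value_celsius))[0]
        assert obs.raw_span.strip().lstrip("-").startswith(str(abs(obs.value_celsius)))


def test_temperature_hits_match_bruteforce_character_walk(calibrated_corpus):
    """On short documents the regex equals a character-walk of the same rule."""

    def walk(text):
        out = []
        i = 0
        n = len(text)
        while i < n:
            if text[i].isdigit() and i > 0 and text[i - 1] in " \t\n-":
                j = i
                while j < n and text[j].isdigit():
                    j += 1
                ndigits = j - i
                if 1 <= ndigits <= 3:
                    k = j
                    # optional single space, optional degree, optional space
                    if k < n and text[k] == " ":
                        k += 1
                    if k < n and text[k] == "°":
                        k += 1
                        if k < n and text[k] == " ":
                            k += 1
                    elif k == j:  # neither space nor degree separated
                        i = j
                        continue
                    if k < n and text[k] == "c" and (
                        k + 1 >= n or not text[k + 1].isalnum()
                    ):
                        val = int(text[i:j])
                        if text[i - 1] == "-":
                            val = -val
                        out.append(val)
                i = j
            else:
                i += 1
        return out

    _, records, _, _ = calibrated_corpus
    for rec in records[:40]:
        assert len(rec.text) <= 2048
        assert [t.value_celsius for t in find_temperatures(rec.text)] == walk(rec.text)


# ---------------------------------------------------------------------------
# growth-context classification


def _classified(text):
    norm = normalize_text(text)
    return classify_growth(find_temperatures(norm), norm)


@pytest.mark.parametrize(
    "text,expected_class",
    [
        ("cells were cultivated at 25 °c", "growth"),
        ("cultures were grown at 37 °c", "growth"),
        ("cultured overnight at 30 °c", "growth"),
        ("harvested at 37 °c by gentle shaking", "growth"),
        ("aliquots stored at -20 °c", "other"),
        ("pellets frozen at -80 °c", "other"),
        ("centrifuged at 4 °c for 20 min", "other"),
        ("samples were denatured at 95 °c", "other"),
        ("boiled at 100 °c in sds buffer", "other"),
        ("the reaction proceeded at 22 °c", "unknown"),
    ],
)
def test_growth_classification_rules(text, expected_class):
    (obs,) = _classified(text)
    assert obs.context_class == expected_class
    if expected_class == "growth":
        assert obs.trigger
    if expected_class == "unknown":
        assert obs.needs_review


def test_trigger_must_end_within_window_before_value():
    far = "cells were grown in a fermenter and much later the probe sat at 30 °c"
    (obs,) = _classified(far)
    assert obs.context_class == "unknown"


# ---------------------------------------------------------------------------
# inducer amounts


def test_iptg_amounts_parse_and_normalise_to_mm():
    obs, review = find_inducer(normalize_text("induced with 0.5 mM IPTG at once"))
    assert review == []
    (o,) = obs
    assert o.inducer == "iptg" and o.amount_mM == pytest.approx(0.5)


def test_micromolar_iptg_normalises_to_submillimolar():
    obs, _ = find_inducer(normalize_text("an improved protocol used 8 μM IPTG"))
    (o,) = obs
    assert o.amount_mM == pytest.approx(0.008)


def test_expression_without_iptg_is_uninduced():
    obs, _ = find_inducer(normalize_text("expression proceeded without IPTG"))
    (o,) = obs
    assert o.uninduced and o.amount_mM is None


def test_iptg_line_without_amount_is_flagged_for_review():
    obs, review = find_inducer(normalize_text("IPTG was added as appropriate"))
    assert obs == []
    assert len(review) == 1 and "iptg" in review[0]


def test_multiple_amounts_on_one_line_all_returned_flagged():
    obs, _ = find_inducer(normalize_text("with 0.1 mM or 1 mM IPTG"))
    assert sorted(o.amount_mM for o in obs) == [pytest.approx(0.1), pytest.approx(1.0)]
    assert all(o.needs_review for o in obs)


def test_arabinose_percent_parsed():
    obs, _ = find_inducer(normalize_text("induced with 0.2 % arabinose"))
    (o,) = obs
    assert o.inducer == "arabinose" and o.percent_wv == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# plasmids


def test_pet_mention_hits_pet_family():
    mentions = find_plasmids(normalize_text("cloned into pET28a for expression"))
    assert [m.family for m in mentions] == ["pET_medium_copy"]


def test_pcdna_is_the_negative_control_family():
    mentions = find_plasmids(normalize_text("transfected with pcDNA3.1"))
    assert [m.family for m in mentions] == ["negative_control"]


def test_family_counted_once_per_article():
    text = normalize_text("pRSET was used. pRSET again. pRSET, pRSET and pRSET.")
    assert len(find_plasmids(text)) == 5
    assert plasmid_families(text) == {"high_copy_T7"}


def test_mine_corpus_hit_table_shape_and_dedup():
    rec = ArticleRecord(
        "a1",
        "g1_c41c43",
        normalize_text(
            "Cells were grown at 37 °C.\n"
            "Induced with 1 mM IPTG.\n"
            "Cloned into pET28a and pET22b.\n"
            "The membrane protein was pure. membrane protein again.\n"
        ),
    )
    hits = mine_corpus([rec])
    temp = hits[hits.category == "temperature"]
    assert list(temp.value) == [37.0] and list(temp.context_class) == ["growth"]
    ind = hits[hits.category == "inducer"]
    assert list(ind.value) == [1.0] and list(ind.unit) == ["mM"]
    plas = hits[hits.category == "plasmid"]
    assert list(plas.family) == ["pET_medium_copy"]  # two pETs, one family row
    kw = hits[hits.category == "keyword"]
    assert len(kw) == 1  # once per article
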