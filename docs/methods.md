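# Methods

## Structure-provenance curation

A ledger row records one expression-vector/bacterial-host combination
behind a deposited membrane-protein structure. Secondary accessions — the
same protein in the same expression system re-deposited with a ligand, a
point mutation or different crystallisation conditions — are merged onto
their primary entry; a secondary accession whose primary cannot be resolved
is a hard curation error. A protein solved after production in two
*different* systems keeps both rows (two ledger records, one unique
structure), so unique-structure accounting deduplicates on protein
identity while cross-tabulations count host–vector combinations. The
shipped fixtures are the published host × promoter count matrices for
heterologous (grand total 163 combinations, 141 unique structures) and
homologous (103 combinations as tabulated; 111 stated unique expression
systems is used as the contribution denominator on that side, 72 unique
structures) membrane proteins, plus the frequent-user plasmid table (124
citing articles). Entry-level ledgers are expanded from the count matrices
with synthetic protein identities, since the underlying per-accession lists
are not shipped; the expansion function documents this.

**Percentage rounding.** Scalar percentages round half away from zero.
Percentage *rows* additionally repair any over- or undershoot of 100 on the
rightmost rounded-up (or rounded-down) cells; this composite rule is the
one that reproduces both published percentage rows exactly, where plain
per-cell rounding sums to 101 on the heterologous table. Every reported
percentage is accompanied by its raw numerator and denominator in the JSON
reports so rounding is auditable.

## Protocol mining

All matching operates on ingested text: lowercased exactly once, with the
degree sign, Greek mu, typographic dashes and non-breaking spaces
canonicalised, so one spelling covers the unicode variants.

**Temperature.** The global sweep matches one-to-three ASCII digits
preceded by whitespace or a minus and followed by an optional degree sign
and a free-standing `c` (so `2mm`, four-digit numbers and decimals never
match). A second pass classifies context: negative values are never
growth; a trigger expression — one of *harvested, cultured, grown,
cultivated* followed by *at* within 30 characters, ending within 40
characters before the value — marks growth; 4 °C on a line mentioning
centrifugation and ≥ 90 °C on a line with denaturation vocabulary
(denatur/boil/heat/SDS/PCR) are decoys; everything else is `unknown` and
flagged `needs_review`. The review flag mechanises the manual-annotation
step a global temperature search otherwise requires; flagged hits are
excluded from tallies by default and can be included for sensitivity
analysis. Room-temperature phrases without a numeral are ignored.

**Inducer.** Every line containing `iptg` is scanned for
`number + unit (M, mM, µM)`; amounts normalise exactly to mM (M → ×1000,
µM → ×0.001). "without/no/absence of IPTG" yields an explicit uninduced
observation; an IPTG line with no parsable amount becomes a review hit with
no observation; several amounts on one line are all returned, each flagged.
Lines containing `arabinose` are scanned for `% (w/v)` values.

**Plasmids.** A lexicon regex (pET with variant numbers, pRSET, pGEM,
pMW7, pHis, pRun, pDEST, pIVEX, pPR-IBA, pLysS/E, pLacI, pBAD, pGEX, pASK,
pQE, pMAL, pRARE, pcDNA) finds mentions; family tallies count at most one
hit per family per article. The taxonomy maps pET → medium-copy colE1;
pET3/9/14/17/20/23 → the ΔlacI/lacO pET class; pMW7/pHis/pRun/pGEM/pRSET/
pDEST/pIVEX/pPR-IBA → high-copy (pMB1 origin) T7 vectors; pLysS/pLysE/
pLacI → T7 attenuation companions; pBAD, pRARE and the non-T7 vectors
separately; pcDNA is a eukaryotic-plasmid negative control for the regex
search. Unknown names fall back to `other_non_T7` with unknown origin and
are logged. The lexicon is deliberately naive (no word-sense
disambiguation): a token like "petri" would match the pET stem; the
synthetic templates avoid such collisions, real corpora would need the
review output inspected.

**Hosts.** Strain strings canonicalise through an alias table on their
alphanumeric core (λ and punctuation stripped), then a conservative fuzzy
match at edit distance ≤ 1 in which digits are exempt from editing —
C41/C43 differ by one digit and must never be conflated. Unresolved
strings pass through unchanged.

## Statistics

Threshold fractions are empirical CDF values; "at or below" (≤) is the
default reading of the headline fractions, with the strict (<) variant
exposed for sensitivity. Histograms use half-open bins `[lo, hi)` with the
final bin closed; out-of-range values are counted in explicit
under/overflow buckets, never silently dropped. Default edges are
(0, 0.01, 0.1, 0.5, 1, ∞) mM for IPTG and (0, 16, 20, 25, 30, 37, 42) °C
for temperature; both are configurable since no canonical binning exists.
Bimodality is reported descriptively as the two largest bins being
non-adjacent. An article contributing several distinct extracted values
contributes each value once (the alternative — one value per article —
would need an article-level aggregation rule the data do not dictate);
`n_explicit` counts articles. Group comparisons use the classical one-way
ANOVA (scipy) at α = 0.05; the fully degenerate case (zero within-group
variance everywhere, equal means) is defined as F = 0, p = 1, and zero
within-group variance with unequal means as F = ∞, p = 0. No post-hoc
tests or multiple-testing corrections are applied.

## Synthetic corpus

The generator emulates the statistical structure of a methods-section
corpus partitioned into three citation groups (C41/C43 users, BL21(DE3)
users, arabinose-system users). Defaults are the calibrated study
conditions:

* growth-temperature mixture {37: 0.62, 30: 0.14, 25: 0.12, 20: 0.07,
  18: 0.05} °C, giving P(T ≤ 30) = 0.38;
* IPTG mixture {1.0: 0.42, 0.7: 0.08, 0.5: 0.15, 0.1: 0.15, 0.05: 0.08,
  0.01: 0.06, 0.008: 0.06} mM, giving P(≤ 0.5 mM) = 0.50 with a sub-10 µM
  tail; amounts below 0.1 mM are printed in µM spellings;
* explicit-value rate 0.5 (half of methods sections state neither
  parameter), uninduced rate 0.02 (leaky-expression protocols are rare but
  real); groups 1–2 induce with IPTG, group 3 with arabinose
  (% w/v mixture {0.2, 0.02, 0.002} at {0.5, 0.3, 0.2});
* per-group keyword rates for the phrase "membrane protein"
  (0.77, 0.25, 0.45) and per-family plasmid citation rates taken from the
  published frequency table, including pBAD at 0.99 in group 3;
* decoy rates per article — centrifugation at 4 °C 0.5, storage at
  −20/−80 °C 0.4, denaturation at 95/100 °C 0.3 — chosen once as realistic
  frequencies for protein-purification methods sections (no published
  values exist for these);
* an ambiguous-sentence rate of 0.05: a temperature with neither trigger
  nor decoy vocabulary, exercising the review-flag path; ambiguous plants
  are marked in the truth table and excluded from precision/recall scoring.

A single root seed drives per-article RNG substreams keyed on
(seed, group index, article index), so an identical spec and seed
reproduce the corpus byte for byte and any single article can be
regenerated in isolation.

What the generator does **not** emulate: real scientific prose variety,
OCR/conversion noise, cross-sentence references ("the same temperature as
above"), plasmid nomenclature drift, and multi-protocol papers. Perfect
extraction scores on the synthetic corpus therefore demonstrate that the
patterns implement their stated rules exactly, not that they would achieve
perfect recall on real articles — on real text the review-flag stream and
the lexicon-coverage report are the honesty mechanisms.

## Problem sizes

The analysis scripts and the acceptance computation use 300
explicit-value articles per group (900 articles), which puts three
binomial standard errors at about ±6 percentage points on the pooled IPTG
fraction and ±5 on the temperature fraction — tight enough to separate the
planted bimodal structure from noise while keeping the full pipeline
run under a second. The curation stage is exact and deterministic at any
size.

## Known limitations

* The temperature pattern cannot see decimal temperatures (37.5 °C) — a
  faithful consequence of the digit-class rule it implements.
* Trigger classification is window-based, not sentence-parsed; a growth
  verb more than 40 characters before its value is missed (flagged for
  review rather than lost).
* The homologous-side contribution denominator (111 stated systems) and
  the tabulated grand total (103) disagree in the source material; both
  numbers are carried as-is and documented at the call site.
* Plasmid counting reports citation of a family, not actual use; explicit
  pET citation is known to undercount because vector names drift.
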