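# mpmine

Meta-analysis toolkit for bacterial membrane-protein (MP) expression
systems. It answers two questions that structural biologists planning an
*E. coli* expression campaign keep asking:

1. **Which host/promoter combinations actually produced the deposited MP
   structures?** Starting from curated structure-provenance records (one
   row per expression-vector/host combination behind a PDB structure), the
   package builds host × promoter cross-tabulations with integer percentage
   rows, computes the contribution of host groups such as the Walker
   mutants C41(DE3)/C43(DE3), tallies structures by topology class
   (monotopic, bitopic, α-helical integral, β-barrel), and summarises the
   plasmid usage of the most frequent user labs.
2. **What induction conditions do published protocols really use?** A
   regex miner extracts growth temperatures, IPTG/arabinose inducer
   amounts, plasmid-family citations and keyword rates from plain-text
   methods sections, classifies each temperature by context (growth vs.
   centrifugation/storage/denaturation decoys, with ambiguous hits flagged
   for review), normalises units to mM, and reports threshold fractions,
   binned distributions and a one-way ANOVA across citation groups.

Because the original downloaded literature corpus is external, the package
includes a first-class synthetic-corpus generator that plants methods-style
sentences from known bimodal mixtures — growth temperature peaked at 37 °C
with a ≤30 °C shoulder (P(T ≤ 30 °C) = 0.38), IPTG peaked at 1 mM with half
the mass at ≤0.5 mM including a sub-10 µM tail — plus decoy temperatures,
group-specific plasmid and keyword rates, and a ground-truth table, so
every extraction and statistics stage is testable end to end.

## Core quantities

For a host × promoter count matrix `N` with column totals `n_j` and grand
total `n`, the percentage row is `round(100 n_j / n)` (half away from zero)
with any over/undershoot of 100 repaired on the rightmost rounded cells;
the contribution of a host set `H` over a denominator `d` is
`round(100 Σ_{i∈H} Σ_j N_ij / d)`. Threshold fractions are empirical CDF
values `P(X ≤ x)` (a strict variant is exposed); group comparisons use the
classical one-way ANOVA `F = MS_between / MS_within` with `(k−1, N−k)`
degrees of freedom, significant at p < 0.05. The temperature pattern
matches one-to-three digits preceded by a space or minus and followed by an
optional degree sign and a free-standing `c`; growth context requires a
trigger expression (`harvested|cultured|grown|cultivated … at`) ending
within 40 characters before the value.

## Worked example

```
$ python analysis/01_curate_structures.py
heterologous ledger: 163 host-vector records, column totals [102, 28, 11, 8, 14] ([63, 17, 7, 5, 8] %)
  C41(DE3)+C43(DE3) contribution: 28 %
homologous ledger: 103 records as tabulated; C41+C43 contribution over the 111 stated systems: 19 %
unique structures: 141 heterologous + 72 homologous = 213
frequent users: 124 citations; C41+high-copy 53 %, C43 13 %
```

Reading: of the 163 expression-vector/host combinations behind the 141
unique heterologous MP structures, the T7 system dominates (102
combinations, 63 %), and the C41(DE3)/C43(DE3) mutant hosts account for
28 % — 19 % on the homologous (E. coli MP) side. Among the eight most
frequent C41/C43 user labs (124 citing articles), 53 % of studies combined
C41(DE3) with a high-copy-number vector while C43(DE3) usage was 13 %.

```
$ python analysis/02_simulate_corpus.py && python analysis/03_mine_protocols.py && python analysis/04_report_stats.py
...
growth-temperature extraction: precision 1.000, recall 1.000
IPTG-amount extraction: precision 1.000, recall 1.000
decoy temperatures classified as growth: 0
IPTG: 589 explicit values; 51 % at or below 0.5 mM
growth temperature: 900 explicit values; 36 % at or below 30.0 °C
temperature ANOVA across groups: F = 0.078, p = 0.925 (not significant)
keyword rates (%): {'g1_c41c43': 75, 'g2_bl21': 26, 'g3_ara': 45}
pBAD citation (%): {'g1_c41c43': 9, 'g2_bl21': 3, 'g3_ara': 99}
```

Reading: on a 900-article calibrated synthetic corpus the miner recovers
every planted unambiguous value, no decoy temperature leaks into the
growth class, and the mined fractions (51 % IPTG ≤ 0.5 mM, 36 % growth
T ≤ 30 °C) sit within binomial sampling error of the planted 50 %/38 %.

The same stages are available as a CLI (`mpmine curate|ingest|mine|stats|
simulate|report`) for use on any corpus laid out as
`corpus/<group>/<article>.txt`.

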