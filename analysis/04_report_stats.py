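"""Summarise the mined hits: distributions, thresholds, ANOVA, frequencies.

Reads scratch/hits.tsv and scratch/corpus/ (run 02 and 03 first) and writes
results/protocol_report.json with the pooled and per-group IPTG and
growth-temperature summaries, the across-group ANOVA, and the keyword and
plasmid-family citation percentages.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from mpmine.corpus_ingest import group_counts, load_corpus
from mpmine.stats_report import summarize_protocols

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    hits_path = ROOT / "scratch" / "hits.tsv"
    corpus_dir = ROOT / "scratch" / "corpus"
    if not hits_path.exists() or not corpus_dir.is_dir():
        sys.exit("run analysis/02_simulate_corpus.py and 03_mine_protocols.py first")
    hits = pd.read_csv(hits_path, sep="\t")
    sizes = group_counts(load_corpus(corpus_dir))

    report = summarize_protocols(hits, sizes)
    out = ROOT / "results" / "protocol_report.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    iptg = report["iptg_mM"]
    temp = report["growth_temp_C"]
    print(f"IPTG: {iptg['n_values']} explicit values; "
          f"{iptg['percent_at_or_below']} % at or below {iptg['threshold']} mM")
    print(f"growth temperature: {temp['n_values']} explicit values; "
          f"{temp['percent_at_or_below']} % at or below {temp['threshold']} °C")
    anova = temp["anova"]
    if anova:
        print(f"temperature ANOVA across groups: F = {anova['f_statistic']:.3f}, "
              f"p = {anova['p_value']:.3f} "
              f"({'significant' if anova['significant'] else 'not significant'})")
    print(f"keyword rates (%): {report['keyword_percent']}")
    print(f"pBAD citation (%): {report['vector_citation_percent'].get('pBAD')}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
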