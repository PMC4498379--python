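"""Mine the synthetic corpus and score extraction against the planted truth.

Reads scratch/corpus/ (run 02_simulate_corpus.py first), writes the flat
hit table to scratch/hits.tsv and the precision/recall scores to
results/extraction_scores.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from mpmine.corpus_ingest import load_corpus
from mpmine.protocol_miner import mine_corpus
from mpmine.synthetic_corpus import score_extraction

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    corpus_dir = ROOT / "scratch" / "corpus"
    if not corpus_dir.is_dir():
        sys.exit("scratch/corpus missing - run analysis/02_simulate_corpus.py first")
    records = load_corpus(corpus_dir)
    truth = pd.read_csv(corpus_dir / "truth.tsv", sep="\t")

    hits = mine_corpus(records)
    hits_path = ROOT / "scratch" / "hits.tsv"
    hits.to_csv(hits_path, sep="\t", index=False)

    score = score_extraction(truth, hits)
    out = ROOT / "results" / "extraction_scores.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(score, indent=2, sort_keys=True) + "\n")

    print(f"mined {len(hits)} hits from {len(records)} articles -> {hits_path}")
    print(f"growth-temperature extraction: precision "
          f"{score['growth_temp']['precision']:.3f}, recall "
          f"{score['growth_temp']['recall']:.3f}")
    print(f"IPTG-amount extraction: precision {score['iptg']['precision']:.3f}, "
          f"recall {score['iptg']['recall']:.3f}")
    print(f"decoy temperatures classified as growth: "
          f"{score['decoys_classified_growth']}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
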