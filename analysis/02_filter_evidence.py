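#!/usr/bin/env python
"""Reduce the raw interaction table to strong-evidence validated targets.

Reads results/bundle/interactions.tsv, keeps records backed by reporter
gene assays, immunoblot/Western blot or RT-qPCR evidence, deduplicates the
(miRNA, gene) pairs and writes results/pairs.tsv.
"""

from pathlib import Path

from mirnet.evidence_filter import filter_interactions, write_interaction_set
from mirnet.tables_io import read_interactions

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_interactions(ROOT / "bundle" / "interactions.tsv")
    interactions = filter_interactions(records)
    write_interaction_set(interactions, ROOT / "pairs.tsv")
    kept = 100.0 * len(interactions) / max(len(records), 1)
    print(f"{len(records)} records -> {len(interactions)} strong-evidence pairs ({kept:.1f}%)")
    print(f"  distinct miRNAs: {len(interactions.mirnas())}")
    print(f"  distinct genes : {len(interactions.genes())}")
    print(f"  wrote {ROOT / 'pairs.tsv'}")


if __name__ == "__main__":
    main()
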