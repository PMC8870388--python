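#!/usr/bin/env python
"""Assemble the per-cluster multi-layer miRNA-gene-SNP-drug networks.

For each term cluster the gene set is the union of enrichment hit genes of
its member terms; the network layers in the miRNAs regulating those genes,
the drugs targeting them and the SNPs located in them. Writes one GraphML
file and one degree-summary table per cluster, plus top-k rankings of
miRNAs (by target count) and genes (by drug count).
"""

from pathlib import Path

import pandas as pd

from mirnet.evidence_filter import interaction_set_from_pairs
from mirnet.network_assembly import (
    build_cluster_network,
    degree_summary,
    export_network,
    rank_genes_by_drug_count,
    rank_mirnas,
    write_degree_summary,
)
from mirnet.tables_io import read_disease_associations, read_drug_targets, read_snps

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pairs = pd.read_csv(ROOT / "pairs.tsv", sep="\t")
    interactions = interaction_set_from_pairs(
        (str(m), str(g)) for m, g in zip(pairs["mirna"], pairs["gene"])
    )
    drugs = read_drug_targets(ROOT / "bundle" / "drugs.tsv")
    snps = read_snps(ROOT / "bundle" / "snps.tsv")
    associations = read_disease_associations(ROOT / "bundle" / "disease_associations.tsv")
    enrichment = pd.read_csv(ROOT / "enrichment.tsv", sep="\t")
    hits = {
        str(r.term_id): set(str(r.hits).split("//")) for r in enrichment.itertuples(index=False)
    }

    clusters = pd.read_csv(ROOT / "clusters.tsv", sep="\t")
    for row in clusters.itertuples(index=False):
        members = str(row.members).split("//")
        genes = set().union(*(hits.get(t, set()) for t in members))
        network = build_cluster_network(genes, interactions, drugs, snps)
        export_network(network, "graphml", ROOT / f"cluster_{row.cluster}.graphml")
        summary = degree_summary(network)
        write_degree_summary(summary, ROOT / f"cluster_{row.cluster}_degrees.tsv")
        print(
            f"cluster {row.cluster}: {summary.n_genes} genes, {summary.n_mirnas} miRNAs, "
            f"{summary.n_edges} miRNA-gene edges, mean degree {summary.mean_degree}, "
            f"{summary.pct_lt5}% of genes with <5 and {summary.pct_gt10}% with >10 partners"
        )

    mirna_ranking = rank_mirnas(interactions, snps, drugs, associations, k=10)
    mirna_ranking.to_csv(ROOT / "mirna_ranking.tsv", sep="\t", index=False)
    gene_ranking = rank_genes_by_drug_count(drugs, interactions, k=10)
    gene_ranking.to_csv(ROOT / "gene_drug_ranking.tsv", sep="\t", index=False)
    top = mirna_ranking.iloc[0]
    print(f"top miRNA: {top['mirna']} with {top['targeted_genes']} validated targets")
    print(f"wrote rankings and per-cluster networks to {ROOT}")


if __name__ == "__main__":
    main()
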