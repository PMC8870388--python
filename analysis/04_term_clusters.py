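#!/usr/bin/env python
"""Cluster the significant disease terms by Wang semantic similarity.

Computes the pairwise Wang similarity matrix over the significant terms,
clusters them agglomeratively (average linkage, cut at distance 0.7) and
reports clusters of two or more terms, mirroring how related disease terms
(e.g. an atherosclerosis group, a cardiomyopathy group) co-cluster in
enrichment heat maps.
"""

from pathlib import Path

import pandas as pd

from mirnet.tables_io import read_ontology
from mirnet.term_similarity import (
    cluster_terms,
    report_clusters,
    similarity_matrix,
    write_similarity_matrix,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    enrichment = pd.read_csv(ROOT / "enrichment.tsv", sep="\t")
    terms = sorted(enrichment.loc[enrichment["p_adj"] < 0.05, "term_id"])
    dag = read_ontology(
        ROOT / "bundle" / "ontology_edges.tsv",
        dialect="edgelist",
        annotations=ROOT / "bundle" / "annotations.tsv",
    )
    matrix = similarity_matrix(terms, dag)
    write_similarity_matrix(matrix, ROOT / "similarity.tsv")
    assignment = cluster_terms(matrix, linkage="average", cut_height=0.7)
    table, singletons = report_clusters(assignment, min_size=2)
    table.to_csv(ROOT / "clusters.tsv", sep="\t", index=False)

    print(f"{len(terms)} significant terms clustered")
    for row in table.itertuples(index=False):
        print(f"  cluster {row.cluster} (n={row.size}): {row.members}")
    print(f"  singletons: {len(singletons)}")
    print(f"wrote {ROOT / 'similarity.tsv'} and {ROOT / 'clusters.tsv'}")


if __name__ == "__main__":
    main()
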