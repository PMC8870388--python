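"""Multi-layer gene/miRNA/SNP/drug network assembly, degree statistics,
top-k rankings, and Cytoscape-compatible export (GraphML, SIF).

Node types map to the conventional Cytoscape shapes: gene=circle,
miRNA=diamond, SNP=square, drug=triangle. Degree statistics are computed
over miRNA-gene edges only: the question they answer is how many miRNAs
regulate each validated target gene; drug and SNP links are annotation
layers, not regulatory connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from mirnet.errors import UndefinedSummaryError
from mirnet.evidence_filter import InteractionSet
from mirnet.tables_io import DiseaseAssociationRecord, DrugTargetRecord, SnpRecord

NODE_TYPES = ("gene", "mirna", "snp", "drug")
NODE_SHAPES = {"gene": "circle", "mirna": "diamond", "snp": "square", "drug": "triangle"}

#: edge_type -> (source node type, target node type)
EDGE_ENDPOINTS = {
    "mirna_gene": ("mirna", "gene"),
    "drug_gene": ("drug", "gene"),
    "snp_gene": ("snp", "gene"),
}


def _round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero (so 10.625 -> 10.63, not 10.62)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MultiLayerNetwork:
    """Typed nodes and typed edges of one cluster's multi-layer network.

    nodes: id -> node type; edges: (source, target, edge_type) with the
    source carrying the non-gene layer (miRNA/drug/SNP) and the target the
    gene; isolated: cluster genes retained despite having no incident edge.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    isolated: set[str] = field(default_factory=set)

    def add_node(self, node_id: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        existing = self.nodes.get(node_id)
        if existing is not None and existing != node_type:
            raise ValueError(
                f"node {node_id!r} already present with type {existing!r}"
            )
        self.nodes[node_id] = node_type

    def add_edge(self, source: str, target: str, edge_type: str) -> None:
        if edge_type not in EDGE_ENDPOINTS:
            raise ValueError(f"unknown edge type {edge_type!r}")
        if source == target:
            raise ValueError(f"self-loop on {source!r}")
        src_type, tgt_type = EDGE_ENDPOINTS[edge_type]
        self.add_node(source, src_type)
        self.add_node(target, tgt_type)
        self.edges.add((source, target, edge_type))

    def nodes_of_type(self, node_type: str) -> set[str]:
        return {n for n, t in self.nodes.items() if t == node_type}

    def edges_of_type(self, edge_type: str) -> set[tuple[str, str, str]]:
        return {e for e in self.edges if e[2] == edge_type}

    def validate(self) -> None:
        for source, target, edge_type in self.edges:
            src_type, tgt_type = EDGE_ENDPOINTS[edge_type]
            if self.nodes.get(source) != src_type or self.nodes.get(target) != tgt_type:
                raise ValueError(
                    f"edge ({source}, {target}, {edge_type}) endpoint types do not "
                    f"match ({self.nodes.get(source)}, {self.nodes.get(target)})"
                )


@dataclass(frozen=True)
class DegreeSummary:
    """Gene-side degree statistics over miRNA-gene edges.

    mean_degree is the mean number of miRNA partners per gene rounded (half
    away from zero) to 1 decimal; the percentage fields to 2 decimals. The
    below-5 / above-10 buckets are strict (< 5, > 10): genes with 5-10
    partners fall in neither.
    """

    n_genes: int
    n_mirnas: int
    n_edges: int
    mean_degree: float
    n_lt5: int
    pct_lt5: float
    n_gt10: int
    pct_gt10: float


def build_cluster_network(
    cluster_genes: Iterable[str],
    interactions: InteractionSet,
    drugs: Sequence[DrugTargetRecord] = (),
    snps: Sequence[SnpRecord] = (),
) -> MultiLayerNetwork:
    """Assemble the multi-layer network restricted to one cluster's genes.

    Gene nodes are the cluster genes; miRNA, drug and SNP nodes appear only
    if linked to a cluster gene. Cluster genes with no edge of any type are
    retained but flagged as isolated, keeping node counts auditable against
    the enrichment hits that defined the cluster.
    """
    genes = {g.upper() for g in cluster_genes}
    net = MultiLayerNetwork()
    for gene in genes:
        net.add_node(gene, "gene")
    for mirna, gene in interactions.pairs:
        if gene in genes:
            net.add_edge(mirna, gene, "mirna_gene")
    for record in drugs:
        if record.gene in genes:
            net.add_edge(record.drug, record.gene, "drug_gene")
    for record in snps:
        if record.gene in genes:
            net.add_edge(record.rsid, record.gene, "snp_gene")
    touched = {e[1] for e in net.edges}
    net.isolated = genes - touched
    return net


def degree_summary(network: MultiLayerNetwork) -> DegreeSummary:
    """Summarize how many miRNAs regulate each gene node."""
    genes = sorted(network.nodes_of_type("gene"))
    if not genes:
        raise UndefinedSummaryError("degree summary undefined: network has no gene nodes")
    mg_edges = network.edges_of_type("mirna_gene")
    degree = {g: 0 for g in genes}
    for _mirna, gene, _ in mg_edges:
        degree[gene] += 1
    n_genes = len(genes)
    n_edges = len(mg_edges)
    n_lt5 = sum(1 for d in degree.values() if d < 5)
    n_gt10 = sum(1 for d in degree.values() if d > 10)
    return DegreeSummary(
        n_genes=n_genes,
        n_mirnas=len(network.nodes_of_type("mirna")),
        n_edges=n_edges,
        mean_degree=_round_half_up(n_edges / n_genes, 1),
        n_lt5=n_lt5,
        pct_lt5=_round_half_up(100.0 * n_lt5 / n_genes, 2),
        n_gt10=n_gt10,
        pct_gt10=_round_half_up(100.0 * n_gt10 / n_genes, 2),
    )


def rank_mirnas(
    interactions: InteractionSet,
    snps: Sequence[SnpRecord] = (),
    drugs: Sequence[DrugTargetRecord] = (),
    disease_map: Sequence[DiseaseAssociationRecord] = (),
    k: int = 10,
) -> pd.DataFrame:
    """Top-k miRNAs by distinct validated target gene count.

    For each miRNA the table also counts distinct SNPs located in and drugs
    hitting its target genes, and joins its associated disease labels. Ties
    in target count are broken lexicographically by miRNA name.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    targets: dict[str, set[str]] = {}
    for mirna, gene in interactions.pairs:
        targets.setdefault(mirna, set()).add(gene)

    snps_by_gene: dict[str, set[str]] = {}
    for s in snps:
        snps_by_gene.setdefault(s.gene, set()).add(s.rsid)
    drugs_by_gene: dict[str, set[str]] = {}
    for d in drugs:
        drugs_by_gene.setdefault(d.gene, set()).add(d.drug)
    diseases: dict[str, list[str]] = {}
    for rec in disease_map:
        slot = diseases.setdefault(rec.mirna, [])
        if rec.term_name not in slot:
            slot.append(rec.term_name)

    ranked = sorted(targets.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:k]
    rows = []
    for rank, (mirna, genes) in enumerate(ranked, start=1):
        n_snps = len(set().union(*(snps_by_gene.get(g, set()) for g in genes)) if genes else set())
        n_drugs = len(set().union(*(drugs_by_gene.get(g, set()) for g in genes)) if genes else set())
        rows.append(
            {
                "rank": rank,
                "mirna": mirna,
                "targeted_genes": len(genes),
                "n_snps": n_snps,
                "n_drugs": n_drugs,
                "diseases": "; ".join(diseases.get(mirna, [])),
            }
        )
    return pd.DataFrame(
        rows, columns=["rank", "mirna", "targeted_genes", "n_snps", "n_drugs", "diseases"]
    )


def rank_genes_by_drug_count(
    drugs: Sequence[DrugTargetRecord],
    interactions: InteractionSet,
    k: int = 10,
) -> pd.DataFrame:
    """Top-k miRNA target genes by distinct-drug count.

    Only genes that appear as miRNA targets qualify; ties are broken
    lexicographically by gene symbol.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mirna_targets = interactions.genes()
    drugs_by_gene: dict[str, set[str]] = {}
    for d in drugs:
        if d.gene in mirna_targets:
            drugs_by_gene.setdefault(d.gene, set()).add(d.drug)
    ranked = sorted(drugs_by_gene.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:k]
    rows = [
        {"rank": i + 1, "gene": gene, "n_drugs": len(ds)}
        for i, (gene, ds) in enumerate(ranked)
    ]
    return pd.DataFrame(rows, columns=["rank", "gene", "n_drugs"])


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def _sorted_nodes(network: MultiLayerNetwork) -> list[str]:
    return sorted(network.nodes, key=lambda n: (network.nodes[n], n))


def export_network(network: MultiLayerNetwork, fmt: str, path: str | Path) -> None:
    """Write the network as GraphML or SIF (Cytoscape-readable).

    GraphML carries node_type / shape / isolated node attributes and the
    edge_type edge attribute. SIF uses edge_type as the relation token and
    writes isolated nodes as bare single-column lines. Node order is
    deterministic (type, then id).
    """
    network.validate()
    path = Path(path)
    if fmt == "graphml":
        g = nx.DiGraph()
        for node in _sorted_nodes(network):
            node_type = network.nodes[node]
            g.add_node(
                node,
                node_type=node_type,
                shape=NODE_SHAPES[node_type],
                isolated=node in network.isolated,
            )
        for source, target, edge_type in sorted(network.edges):
            g.add_edge(source, target, edge_type=edge_type)
        nx.write_graphml(g, path)
    elif fmt == "sif":
        lines = [
            f"{source}\t{edge_type}\t{target}"
            for source, target, edge_type in sorted(network.edges)
        ]
        connected = {e[0] for e in network.edges} | {e[1] for e in network.edges}
        lines.extend(n for n in _sorted_nodes(network) if n not in connected)
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network(fmt: str, path: str | Path) -> MultiLayerNetwork:
    """Read back a network written by :func:`export_network`.

    For SIF, bare (isolated) nodes are typed as genes: in this pipeline the
    only nodes retained without edges are cluster genes.
    """
    path = Path(path)
    net = MultiLayerNetwork()
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for node, data in g.nodes(data=True):
            net.add_node(node, data["node_type"])
            if data.get("isolated"):
                net.isolated.add(node)
        for source, target, data in g.edges(data=True):
            net.add_edge(source, target, data["edge_type"])
    elif fmt == "sif":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                net.add_node(parts[0], "gene")
                net.isolated.add(parts[0])
            else:
                source, edge_type, target = parts[0], parts[1], parts[2]
                net.add_edge(source, target, edge_type)
    else:
        raise ValueError(f"unknown import format {fmt!r}")
    return net


def write_degree_summary(summary: DegreeSummary, path: str | Path) -> None:
    pd.DataFrame([summary.__dict__]).to_csv(path, sep="\t", index=False)
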