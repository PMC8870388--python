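"""End-to-end orchestration: filter -> enrich -> cluster terms -> networks.

Each stage writes its output table before the next stage reads anything, so
every intermediate is independently inspectable and re-runnable; the run
returns a manifest of produced files plus a per-stage summary record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from mirnet.enrichment import dotplot_table, run_ora, write_enrichment
from mirnet.errors import MirnetError
from mirnet.evidence_filter import (
    EvidenceKeywordSet,
    filter_interactions,
    write_interaction_set,
)
from mirnet.network_assembly import (
    build_cluster_network,
    degree_summary,
    export_network,
    rank_genes_by_drug_count,
    rank_mirnas,
    write_degree_summary,
)
from mirnet.tables_io import (
    read_disease_associations,
    read_drug_targets,
    read_interactions,
    read_ontology,
    read_snps,
)
from mirnet.term_similarity import (
    cluster_terms,
    report_clusters,
    similarity_matrix,
    write_similarity_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One configuration record for the whole pipeline."""

    interactions: str
    ontology: str
    annotations: str | None = None
    disease_associations: str | None = None
    drugs: str | None = None
    snps: str | None = None
    ontology_dialect: str = "edgelist"
    keywords: tuple[str, ...] | None = None
    evidence_mode: str = "any"
    alpha: float = 0.05
    min_term_size: int = 5
    max_term_size: int = 500
    propagate: bool = True
    linkage: str = "average"
    cut_height: float = 0.7
    min_cluster_size: int = 2
    top_k: int = 10
    network_format: str = "graphml"
    outdir: str = "pipeline_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "keywords" in raw and raw["keywords"] is not None:
            raw["keywords"] = tuple(raw["keywords"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Manifest of produced files and per-stage counts."""

    manifest: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute filter -> enrich -> simcluster -> network on the configured inputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict = {}

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    # ---- filter ----------------------------------------------------------
    _stage("filter")
    records = read_interactions(config.interactions)
    keyword_set = (
        EvidenceKeywordSet(keywords=config.keywords, mode=config.evidence_mode)
        if config.keywords
        else EvidenceKeywordSet(mode=config.evidence_mode)
    )
    interactions = filter_interactions(records, keyword_set)
    pairs_path = outdir / "pairs.tsv"
    write_interaction_set(interactions, pairs_path)
    manifest["pairs"] = str(pairs_path)
    summary["n_records"] = len(records)
    summary["n_pairs"] = len(interactions)
    logger.info("filter: %d records -> %d pairs", len(records), len(interactions))

    # ---- enrich ----------------------------------------------------------
    _stage("enrich")
    dag = read_ontology(
        config.ontology, dialect=config.ontology_dialect, annotations=config.annotations
    )
    results = run_ora(
        interactions.genes(),
        dag,
        min_term_size=config.min_term_size,
        max_term_size=config.max_term_size,
        propagate=config.propagate,
    )
    enrichment_path = outdir / "enrichment.tsv"
    write_enrichment(results, enrichment_path)
    manifest["enrichment"] = str(enrichment_path)
    dot = dotplot_table(results, alpha=config.alpha)
    dot_path = outdir / "dotplot.tsv"
    dot.to_csv(dot_path, sep="\t", index=False)
    manifest["dotplot"] = str(dot_path)
    significant = [r for r in results if r.p_adj < config.alpha]
    summary["n_terms_tested"] = len(results)
    summary["n_terms_significant"] = len(significant)
    logger.info("enrich: %d tested, %d significant", len(results), len(significant))

    # ---- simcluster ------------------------------------------------------
    _stage("simcluster")
    sig_terms = sorted(r.term_id for r in significant)
    clusters_path = outdir / "clusters.tsv"
    cluster_gene_sets: dict[int, set[str]] = {}
    if sig_terms:
        matrix = similarity_matrix(sig_terms, dag)
        sim_path = outdir / "similarity.tsv"
        write_similarity_matrix(matrix, sim_path)
        manifest["similarity"] = str(sim_path)
        assignment = cluster_terms(
            matrix, linkage=config.linkage, cut_height=config.cut_height
        )
        table, singletons = report_clusters(assignment, min_size=config.min_cluster_size)
        table.to_csv(clusters_path, sep="\t", index=False)
        manifest["clusters"] = str(clusters_path)
        summary["n_clusters_reported"] = len(table)
        summary["n_singletons"] = len(singletons)
        hits_by_term = {r.term_id: r.hits for r in significant}
        for label, members in assignment.clusters().items():
            if len(members) >= config.min_cluster_size:
                cluster_gene_sets[label] = set().union(
                    *(hits_by_term[t] for t in members)
                )
    else:
        summary["n_clusters_reported"] = 0
        summary["n_singletons"] = 0

    # ---- network ---------------------------------------------------------
    _stage("network")
    drug_records = read_drug_targets(config.drugs) if config.drugs else []
    snp_records = read_snps(config.snps) if config.snps else []
    disease_records = (
        read_disease_associations(config.disease_associations)
        if config.disease_associations
        else []
    )
    summary["clusters"] = {}
    for label in sorted(cluster_gene_sets):
        genes = cluster_gene_sets[label]
        network = build_cluster_network(genes, interactions, drug_records, snp_records)
        ext = "graphml" if config.network_format == "graphml" else "sif"
        net_path = outdir / f"cluster_{label}.{ext}"
        export_network(network, config.network_format, net_path)
        manifest[f"network_cluster_{label}"] = str(net_path)
        ds = degree_summary(network)
        ds_path = outdir / f"cluster_{label}_degrees.tsv"
        write_degree_summary(ds, ds_path)
        manifest[f"degrees_cluster_{label}"] = str(ds_path)
        summary["clusters"][label] = {
            "n_genes": ds.n_genes,
            "n_mirnas": ds.n_mirnas,
            "n_edges": ds.n_edges,
            "mean_degree": ds.mean_degree,
        }

    ranking = rank_mirnas(
        interactions, snp_records, drug_records, disease_records, k=config.top_k
    )
    ranking_path = outdir / "mirna_ranking.tsv"
    ranking.to_csv(ranking_path, sep="\t", index=False)
    manifest["mirna_ranking"] = str(ranking_path)
    if drug_records:
        gene_ranking = rank_genes_by_drug_count(drug_records, interactions, k=config.top_k)
        gene_ranking_path = outdir / "gene_drug_ranking.tsv"
        gene_ranking.to_csv(gene_ranking_path, sep="\t", index=False)
        manifest["gene_drug_ranking"] = str(gene_ranking_path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps({"files": manifest, "summary": summary}, indent=2, sort_keys=True) + "\n"
    )
    manifest["manifest"] = str(manifest_path)
    return PipelineResult(manifest=manifest, summary=summary)
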