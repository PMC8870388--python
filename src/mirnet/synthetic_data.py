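"""Database-shaped synthetic inputs with planted ground truth.

The generator emits the five table shapes the pipeline ingests (miRNA-target
interactions with evidence strings, miRNA-disease associations, drug targets,
SNP annotations) plus a rooted ontology DAG with term -> gene annotations.
Ground truth is planted so every stage is testable: chosen leaf terms are
"enriched" by giving a hub miRNA most of their annotated genes as targets,
hub target counts follow a truncated power law (mimicking the heavy skew of
real miRNA target databases), and a companion generator builds ontologies
whose leaves form blocks of high within-block Wang similarity.

One integer seed drives a single NumPy generator threaded through all
tables, so an identical configuration reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from mirnet.tables_io import (
    DiseaseAssociationRecord,
    DrugTargetRecord,
    InteractionRecord,
    OntologyDag,
    SnpRecord,
    write_annotations,
    write_disease_associations,
    write_drug_targets,
    write_interactions,
    write_ontology_edgelist,
    write_snps,
)

#: Evidence vocabulary: first group passes the default strong-assay filter,
#: second does not.
PASSING_EVIDENCE = (
    "Luciferase reporter assay",
    "Western blot",
    "qRT-PCR",
    "Real-time PCR; Immunoblot",
)
FAILING_EVIDENCE = ("Microarray", "pSILAC", "CLIP-Seq", "Sequencing")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults define the study conditions used in tests."""

    seed: int = 0
    n_genes: int = 500
    n_mirnas: int = 12
    depth: int = 3
    branching: int = 3
    n_planted_terms: int = 2
    planted_effect: float = 0.8
    background_edge_prob: float = 0.01
    hub_degree: int = 30
    max_hub_degree: int = 60
    hub_degree_exponent: float = 2.5
    evidence_pass_prob: float = 0.9
    n_drugs: int = 30
    n_snps: int = 20
    cross_link_prob: float = 0.05

    def __post_init__(self) -> None:
        for name in ("planted_effect", "background_edge_prob", "evidence_pass_prob",
                     "cross_link_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.depth < 2:
            raise ValueError(f"ontology depth must be >= 2, got {self.depth}")
        if self.branching ** self.depth < self.n_planted_terms:
            raise ValueError(
                f"infeasible shape: {self.branching}^{self.depth} leaves < "
                f"{self.n_planted_terms} planted terms"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticTruth:
    """Planted ground truth, verifiable by recounting the emitted tables."""

    seed: int
    planted_terms: list[str]
    hubs: dict[str, int]  # hub miRNA name -> intended distinct target count
    row_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def simulate_ontology(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> OntologyDag:
    """Rooted b-ary tree of the configured depth, plus sparse cross-links.

    Terms are numbered level by level; genes are annotated uniformly to the
    leaf terms (one leaf per gene). Cross-links are extra part_of edges from
    a node to a strictly shallower non-parent node, so acyclicity holds by
    construction.
    """
    rng = config.rng() if rng is None else rng
    levels: list[list[str]] = [["T0000"]]
    counter = 1
    for _depth in range(config.depth):
        level = []
        for _parent in levels[-1]:
            for _ in range(config.branching):
                level.append(f"T{counter:04d}")
                counter += 1
        levels.append(level)

    terms = {t: f"synthetic term {t[1:].lstrip('0') or '0'}" for lvl in levels for t in lvl}
    edges: list[tuple[str, str, str]] = []
    for depth_i in range(1, len(levels)):
        parents = levels[depth_i - 1]
        for j, child in enumerate(levels[depth_i]):
            edges.append((child, parents[j // config.branching], "is_a"))

    # sparse cross-links to strictly shallower levels (keeps the DAG acyclic)
    for depth_i in range(2, len(levels)):
        for j, child in enumerate(levels[depth_i]):
            if rng.random() < config.cross_link_prob:
                shallow = int(rng.integers(0, depth_i - 1))
                target = levels[shallow][int(rng.integers(0, len(levels[shallow])))]
                parent = levels[depth_i - 1][j // config.branching]
                if target != parent:
                    edges.append((child, target, "part_of"))

    # balanced random deal: a random permutation of the genes distributed
    # round-robin over the leaves, so every leaf term gets an (almost)
    # equal-sized annotation set with random membership
    leaves = levels[-1]
    genes = [f"SG{i + 1:04d}" for i in range(config.n_genes)]
    annotations: dict[str, set[str]] = {}
    for i, gene_idx in enumerate(rng.permutation(config.n_genes)):
        annotations.setdefault(leaves[i % len(leaves)], set()).add(genes[int(gene_idx)])

    return OntologyDag(terms, edges, annotations=annotations)


def ontology_leaves(dag: OntologyDag) -> list[str]:
    """Terms with no children, in sorted order."""
    return sorted(t for t in dag.terms if not dag.children(t))


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def _evidence_for_row(rng: np.random.Generator, pass_prob: float) -> tuple[str, ...]:
    if rng.random() < pass_prob:
        strings = [PASSING_EVIDENCE[int(rng.integers(0, len(PASSING_EVIDENCE)))]]
        if rng.random() < 0.3:  # realistic: strong assays often co-reported with arrays
            strings.append(FAILING_EVIDENCE[int(rng.integers(0, len(FAILING_EVIDENCE)))])
    else:
        strings = [FAILING_EVIDENCE[int(rng.integers(0, len(FAILING_EVIDENCE)))]]
    return tuple(strings)


def simulate_interactions(
    config: SyntheticConfig,
    dag: OntologyDag,
    rng: np.random.Generator | None = None,
) -> tuple[list[InteractionRecord], SyntheticTruth]:
    """Interaction table with hub miRNAs planted on chosen leaf terms.

    Each planted leaf term gets a dedicated hub miRNA whose target set
    includes ``planted_effect`` of the term's annotated genes, topped up
    with uniform background genes to a truncated-power-law target count.
    The remaining miRNAs draw targets per-gene at ``background_edge_prob``.
    Every row carries evidence strings that pass the default strong-assay
    keyword filter with probability ``evidence_pass_prob``.
    """
    rng = config.rng() if rng is None else rng
    genes = sorted({g for gs in dag.annotations.values() for g in gs})
    leaves = [t for t in ontology_leaves(dag) if dag.annotations.get(t)]
    if len(leaves) < config.n_planted_terms:
        raise ValueError("not enough annotated leaf terms to plant")
    planted_idx = rng.choice(len(leaves), size=config.n_planted_terms, replace=False)
    planted_terms = [leaves[int(i)] for i in sorted(planted_idx)]

    records: list[InteractionRecord] = []
    hubs: dict[str, int] = {}
    for i, term in enumerate(planted_terms):
        hub = f"miR-hub-{i + 1}"
        term_genes = sorted(dag.annotations[term])
        n_planted = int(round(config.planted_effect * len(term_genes)))
        chosen = rng.choice(len(term_genes), size=n_planted, replace=False)
        targets = {term_genes[int(j)] for j in chosen}
        # truncated power-law total target count
        total = int(config.hub_degree * (1.0 + rng.pareto(config.hub_degree_exponent)))
        total = min(max(total, n_planted), config.max_hub_degree, len(genes))
        others = [g for g in genes if g not in targets]
        if total > len(targets):
            extra = rng.choice(len(others), size=total - len(targets), replace=False)
            targets |= {others[int(j)] for j in extra}
        hubs[hub] = len(targets)
        for gene in sorted(targets):
            records.append(
                InteractionRecord(
                    mirna=hub,
                    gene=gene,
                    evidence=_evidence_for_row(rng, config.evidence_pass_prob),
                    source="synthetic",
                )
            )

    n_background = config.n_mirnas - len(hubs)
    for i in range(max(n_background, 0)):
        mirna = f"miR-sim-{i + 1:03d}"
        mask = rng.random(len(genes)) < config.background_edge_prob
        for gene in (g for g, hit in zip(genes, mask) if hit):
            records.append(
                InteractionRecord(
                    mirna=mirna,
                    gene=gene,
                    evidence=_evidence_for_row(rng, config.evidence_pass_prob),
                    source="synthetic",
                )
            )

    truth = SyntheticTruth(
        seed=config.seed,
        planted_terms=planted_terms,
        hubs=hubs,
        row_counts={"interactions": len(records)},
    )
    return records, truth


# ---------------------------------------------------------------------------
# drugs, SNPs, disease associations
# ---------------------------------------------------------------------------

def simulate_drugs_snps(
    config: SyntheticConfig,
    genes: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[list[DrugTargetRecord], list[SnpRecord]]:
    """Drug-target and SNP tables over the given genes.

    Drug targets are drawn from a Zipf-weighted gene distribution so a few
    genes accumulate many compounds; SNPs get fresh rs-numbers and 1-based
    synthetic coordinates.
    """
    rng = config.rng() if rng is None else rng
    genes = sorted(genes)
    weights = 1.0 / np.arange(1, len(genes) + 1)
    weights /= weights.sum()

    drug_records: list[DrugTargetRecord] = []
    seen: set[tuple[str, str]] = set()
    for i in range(config.n_drugs):
        drug = f"drug-{i + 1:03d}"
        n_targets = 1 + int(rng.integers(0, 2))
        for idx in rng.choice(len(genes), size=n_targets, replace=False, p=weights):
            pair = (drug, genes[int(idx)])
            if pair not in seen:
                seen.add(pair)
                drug_records.append(DrugTargetRecord(drug=pair[0], gene=pair[1]))

    snp_records: list[SnpRecord] = []
    used_rsids: set[int] = set()
    for _ in range(config.n_snps):
        while True:
            number = int(rng.integers(10_000, 100_000_000))
            if number not in used_rsids:
                used_rsids.add(number)
                break
        snp_records.append(
            SnpRecord(
                rsid=f"rs{number}",
                gene=genes[int(rng.integers(0, len(genes)))],
                chromosome=str(int(rng.integers(1, 23))),
                position=int(rng.integers(1, 250_000_000)),
            )
        )
    return drug_records, snp_records


def simulate_disease_associations(
    config: SyntheticConfig,
    dag: OntologyDag,
    mirnas: list[str],
    rng: np.random.Generator | None = None,
) -> list[DiseaseAssociationRecord]:
    """Associate each miRNA with one or two random ontology terms."""
    rng = config.rng() if rng is None else rng
    terms = sorted(dag.terms)
    records = []
    for mirna in sorted(mirnas):
        for idx in rng.choice(len(terms), size=1 + int(rng.integers(0, 2)), replace=False):
            term = terms[int(idx)]
            records.append(
                DiseaseAssociationRecord(
                    mirna=mirna, term_id=term, term_name=dag.terms[term]
                )
            )
    return records


# ---------------------------------------------------------------------------
# similarity blocks
# ---------------------------------------------------------------------------

@dataclass
class SimilarityBlocks:
    """A block-structured ontology fixture for term-clustering tests."""

    dag: OntologyDag
    terms: list[str]          # the leaf terms to cluster, all blocks together
    blocks: dict[str, int]    # leaf term -> block index


def simulate_similarity_blocks(
    n_blocks: int,
    terms_per_block: int,
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SimilarityBlocks:
    """Ontology whose leaves form blocks of high within-block similarity.

    Each block hangs its leaves under a private chain of 2-3 ancestors below
    the shared root, so leaves of one block share deep ancestry (Wang
    similarity ~0.66-0.70) while leaves of different blocks share only the
    root (~0.12-0.17).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    config = config or SyntheticConfig()
    rng = config.rng() if rng is None else rng

    terms: dict[str, str] = {"ROOT": "synthetic root"}
    edges: list[tuple[str, str, str]] = []
    leaf_terms: list[str] = []
    blocks: dict[str, int] = {}
    for b in range(n_blocks):
        chain_depth = int(rng.integers(2, 4))
        parent = "ROOT"
        for level in range(chain_depth):
            anc = f"B{b + 1}-anc{level + 1}"
            terms[anc] = f"block {b + 1} ancestor {level + 1}"
            edges.append((anc, parent, "is_a"))
            parent = anc
        for j in range(terms_per_block):
            leaf = f"B{b + 1}-T{j + 1}"
            terms[leaf] = f"block {b + 1} term {j + 1}"
            edges.append((leaf, parent, "is_a"))
            leaf_terms.append(leaf)
            blocks[leaf] = b + 1
    dag = OntologyDag(terms, edges)
    return SimilarityBlocks(dag=dag, terms=leaf_terms, blocks=blocks)


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """All generated tables plus the planted truth."""

    config: SyntheticConfig
    dag: OntologyDag
    interactions: list[InteractionRecord]
    disease_associations: list[DiseaseAssociationRecord]
    drugs: list[DrugTargetRecord]
    snps: list[SnpRecord]
    truth: SyntheticTruth


def simulate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the five tables and the ontology with one threaded generator."""
    rng = config.rng()
    dag = simulate_ontology(config, rng)
    interactions, truth = simulate_interactions(config, dag, rng)
    genes = sorted({g for gs in dag.annotations.values() for g in gs})
    drugs, snps = simulate_drugs_snps(config, genes, rng)
    mirnas = sorted({r.mirna for r in interactions})
    associations = simulate_disease_associations(config, dag, mirnas, rng)
    truth.row_counts.update(
        {
            "drugs": len(drugs),
            "snps": len(snps),
            "disease_associations": len(associations),
            "ontology_terms": len(dag),
        }
    )
    return SyntheticBundle(
        config=config,
        dag=dag,
        interactions=interactions,
        disease_associations=associations,
        drugs=drugs,
        snps=snps,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write all bundle tables into ``outdir``; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": outdir / "interactions.tsv",
        "disease_associations": outdir / "disease_associations.tsv",
        "drugs": outdir / "drugs.tsv",
        "snps": outdir / "snps.tsv",
        "ontology": outdir / "ontology_edges.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.json",
    }
    write_interactions(bundle.interactions, paths["interactions"])
    write_disease_associations(bundle.disease_associations, paths["disease_associations"])
    write_drug_targets(bundle.drugs, paths["drugs"])
    write_snps(bundle.snps, paths["snps"])
    write_ontology_edgelist(bundle.dag, paths["ontology"])
    write_annotations(bundle.dag.annotations, paths["annotations"])
    bundle.truth.to_json(paths["truth"])
    return paths
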