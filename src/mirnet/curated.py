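"""Curated reference inputs from the cardiovascular miRNA literature.

Small, hand-checked fixtures used by the worked examples, the test suite and
the acceptance script: reporter-assay-validated target gene lists for three
well-studied miRNAs (miR-146a-5p in atherosclerosis, miR-21-5p in
cardiomyopathy, miR-138-5p in lipid metabolism disorder), the AGTR1
pharmacogenomic neighbourhood (miRNAs, sartan drugs, the rs5186 variant),
a four-SNP coronary-artery-disease pharmacogenomic panel, and gene-degree
profiles summarizing the reported atherosclerosis and cardiomyopathy
miRNA-target networks.
"""

from __future__ import annotations

from mirnet.evidence_filter import InteractionSet, interaction_set_from_pairs
from mirnet.network_assembly import MultiLayerNetwork
from mirnet.tables_io import DrugTargetRecord, SnpRecord

#: Atherosclerosis-associated genes validated as miR-146a-5p targets.
MIR146A_ATHEROSCLEROSIS_TARGETS: tuple[str, ...] = (
    "CCL5", "CD40LG", "CFH", "CXCL12", "ELAVL1", "ICAM1", "IL6", "MIF",
    "NFKB1", "PLAUR", "PTGS2", "RHOA", "ROCK1", "S100A12", "SPP1", "TGFB1",
    "TLR2", "TLR4",
)

#: Cardiomyopathy-associated genes validated as miR-21-5p targets.
MIR21_CARDIOMYOPATHY_TARGETS: tuple[str, ...] = (
    "ERBB2", "IGF1R", "IL1B", "MMP2", "MMP9", "PTX3", "SMARCA4", "TGFB1",
    "TLR3", "TPM1",
)

#: Lipid-metabolism-disorder genes validated as miR-138-5p targets.
MIR138_LIPID_TARGETS: tuple[str, ...] = (
    "CEBPA", "FABP4", "LPL", "MMP3", "NFKB1", "SERPINE1", "PPARG", "TERT",
)

#: Variants carried in pharmacogenomic panels for coronary artery disease,
#: each in the 3'UTR / coding region of a drug-targeted, miRNA-regulated gene.
PANEL_SNPS: tuple[SnpRecord, ...] = (
    SnpRecord(rsid="rs5186", gene="AGTR1", chromosome="3", position=148742201),
    SnpRecord(rsid="rs17244841", gene="HMGCR", chromosome="5", position=75347030),
    SnpRecord(rsid="rs5918", gene="ITGB3", chromosome="17", position=47283364),
    SnpRecord(rsid="rs3856806", gene="PPARG", chromosome="3", position=12434058),
)

#: Angiotensin II receptor blockers targeting AGTR1.
AGTR1_DRUGS: tuple[DrugTargetRecord, ...] = (
    DrugTargetRecord(drug="candesartan", gene="AGTR1"),
    DrugTargetRecord(drug="eprosartan", gene="AGTR1"),
    DrugTargetRecord(drug="olmesartan", gene="AGTR1"),
)

#: miRNAs with reporter-assay / immunoblot support for AGTR1 repression.
AGTR1_MIRNAS: tuple[str, ...] = ("miR-155-5p", "miR-34a-5p")


def curated_interaction_set() -> InteractionSet:
    """The three curated miRNA target lists as one deduplicated pair set."""
    pairs = (
        [("miR-146a-5p", g) for g in MIR146A_ATHEROSCLEROSIS_TARGETS]
        + [("miR-21-5p", g) for g in MIR21_CARDIOMYOPATHY_TARGETS]
        + [("miR-138-5p", g) for g in MIR138_LIPID_TARGETS]
    )
    return interaction_set_from_pairs(pairs)


def degree_sequence_from_profile(
    n_genes: int, n_edges: int, n_lt5: int, n_gt10: int,
    lt5_degree: int = 2, mid_degree: int = 6,
) -> list[int]:
    """Build an integer gene-degree sequence matching a bucketed profile.

    ``n_lt5`` genes get a degree below 5, ``n_gt10`` genes above 10, the rest
    a degree in [5, 10], and the total equals ``n_edges``. The remainder
    after the low and middle buckets is spread evenly over the high bucket.
    """
    n_mid = n_genes - n_lt5 - n_gt10
    if n_mid < 0:
        raise ValueError("bucket counts exceed the number of genes")
    if not 1 <= lt5_degree < 5 or not 5 <= mid_degree <= 10:
        raise ValueError("bucket degrees outside their bucket ranges")
    remainder = n_edges - n_lt5 * lt5_degree - n_mid * mid_degree
    degrees = [lt5_degree] * n_lt5 + [mid_degree] * n_mid
    if n_gt10:
        base, extra = divmod(remainder, n_gt10)
        if base < 11:
            raise ValueError("profile infeasible: high-bucket degrees would be <= 10")
        degrees += [base + 1] * extra + [base] * (n_gt10 - extra)
    elif remainder:
        raise ValueError("profile infeasible: leftover edges with no high bucket")
    assert sum(degrees) == n_edges and len(degrees) == n_genes
    return degrees


def network_from_degree_sequence(degrees: list[int]) -> MultiLayerNetwork:
    """Deterministic bipartite miRNA-gene network with the given gene degrees.

    Gene i is wired to the first ``degrees[i]`` of a shared miRNA pool, so
    the realized degree sequence is exact and no duplicate edges can occur.
    """
    net = MultiLayerNetwork()
    width = len(str(max(len(degrees), max(degrees, default=1))))
    for i, d in enumerate(degrees):
        gene = f"G{i + 1:0{width}d}"
        net.add_node(gene, "gene")
        for j in range(d):
            net.add_edge(f"miR-x{j + 1}", gene, "mirna_gene")
    net.isolated = {n for n, t in net.nodes.items() if t == "gene"} - {
        e[1] for e in net.edges
    }
    return net


def atherosclerosis_degree_profile() -> list[int]:
    """Degree profile of the reported atherosclerosis miRNA-target network:
    160 genes, 724 miRNA-gene connections, 114 genes with < 5 and 17 genes
    with > 10 miRNA partners."""
    return degree_sequence_from_profile(n_genes=160, n_edges=724, n_lt5=114, n_gt10=17)


def cardiomyopathy_degree_profile() -> list[int]:
    """Degree profile of the reported cardiomyopathy miRNA-target network:
    67 genes, 340 connections, 47 genes with < 5 and 10 with > 10 partners."""
    return degree_sequence_from_profile(n_genes=67, n_edges=340, n_lt5=47, n_gt10=10)
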