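"""Multi-layer network assembly, degree statistics, rankings, export."""

import pytest

from mirnet.curated import (
    AGTR1_DRUGS,
    AGTR1_MIRNAS,
    MIR138_LIPID_TARGETS,
    MIR146A_ATHEROSCLEROSIS_TARGETS,
    MIR21_CARDIOMYOPATHY_TARGETS,
    PANEL_SNPS,
    atherosclerosis_degree_profile,
    cardiomyopathy_degree_profile,
    curated_interaction_set,
    network_from_degree_sequence,
)
from mirnet.errors import UndefinedSummaryError
from mirnet.evidence_filter import interaction_set_from_pairs
from mirnet.network_assembly import (
    MultiLayerNetwork,
    build_cluster_network,
    degree_summary,
    export_network,
    import_network,
    rank_genes_by_drug_count,
    rank_mirnas,
)
from mirnet.tables_io import DrugTargetRecord, SnpRecord


@pytest.fixture
def agtr1_network():
    """The angiotensin receptor neighbourhood: 2 miRNAs, 1 drug, 1 SNP."""
    interactions = interaction_set_from_pairs((m, "AGTR1") for m in AGTR1_MIRNAS)
    return build_cluster_network(
        {"AGTR1"},
        interactions,
        drugs=[AGTR1_DRUGS[0]],
        snps=[PANEL_SNPS[0]],
    )


class TestBuildClusterNetwork:
    def test_agtr1_neighbourhood_counts(self, agtr1_network):
        assert len(agtr1_network.nodes) == 5
        assert len(agtr1_network.edges) == 4
        assert agtr1_network.nodes["AGTR1"] == "gene"
        assert agtr1_network.nodes["rs5186"] == "snp"
        assert agtr1_network.nodes["candesartan"] == "drug"
        assert not agtr1_network.isolated

    def test_without_drug_and_snp_layers(self):
        interactions = interaction_set_from_pairs([("miR-1", "G1")])
        net = build_cluster_network({"G1"}, interactions)
        assert set(net.nodes.values()) == {"gene", "mirna"}

    def test_interactions_outside_cluster_are_excluded(self):
        interactions = interaction_set_from_pairs([("miR-1", "G1"), ("miR-1", "G2")])
        net = build_cluster_network({"G1"}, interactions)
        assert "G2" not in net.nodes
        assert net.edges == {("miR-1", "G1", "mirna_gene")}

    def test_isolated_cluster_genes_are_kept_and_flagged(self):
        interactions = interaction_set_from_pairs([("miR-1", "G1")])
        net = build_cluster_network({"G1", "LONELY"}, interactions)
        assert net.isolated == {"LONELY"}
        assert net.nodes["LONELY"] == "gene"

    def test_typed_edge_contracts(self):
        net = MultiLayerNetwork()
        with pytest.raises(ValueError):
            net.add_edge("A", "A", "mirna_gene")
        with pytest.raises(ValueError):
            net.add_edge("miR-1", "G1", "regulates")
        net.add_edge("miR-1", "G1", "mirna_gene")
        with pytest.raises(ValueError):  # same id cannot switch type
            net.add_node("miR-1", "gene")


class TestDegreeSummary:
    def test_atherosclerosis_profile_statistics(self):
        net = network_from_degree_sequence(atherosclerosis_degree_profile())
        ds = degree_summary(net)
        assert (ds.n_genes, ds.n_edges) == (160, 724)
        assert ds.mean_degree == 4.5
        assert (ds.n_lt5, ds.pct_lt5) == (114, 71.25)
        assert (ds.n_gt10, ds.pct_gt10) == (17, 10.63)

    def test_cardiomyopathy_profile_statistics(self):
        net = network_from_degree_sequence(cardiomyopathy_degree_profile())
        ds = degree_summary(net)
        assert (ds.n_genes, ds.n_edges) == (67, 340)
        assert ds.mean_degree == 5.1
        assert (ds.n_lt5, ds.pct_lt5) == (47, 70.15)
        assert (ds.n_gt10, ds.pct_gt10) == (10, 14.93)

    def test_bucketed_fixture_with_strict_thresholds(self):
        # 17 genes of degree 11, 114 of degree 1, 29 of degree 5:
        # degree-5 genes land in neither bucket
        degrees = [11] * 17 + [1] * 114 + [5] * 29
        ds = degree_summary(network_from_degree_sequence(degrees))
        assert (ds.n_gt10, ds.pct_gt10) == (17, 10.63)
        assert (ds.n_lt5, ds.pct_lt5) == (114, 71.25)

    def test_no_mirna_edges(self):
        net = MultiLayerNetwork()
        net.add_node("G1", "gene")
        net.add_edge("drug-1", "G1", "drug_gene")
        ds = degree_summary(net)
        assert ds.mean_degree == 0.0
        assert ds.pct_lt5 == 100.00

    def test_no_gene_nodes_is_an_error(self):
        net = MultiLayerNetwork()
        net.add_node("miR-1", "mirna")
        with pytest.raises(UndefinedSummaryError):
            degree_summary(net)

    def test_invariant_to_construction_order(self):
        degrees = [3, 7, 12, 1]
        forward = network_from_degree_sequence(degrees)
        backward = MultiLayerNetwork()
        for source, target, edge_type in sorted(forward.edges, reverse=True):
            backward.add_edge(source, target, edge_type)
        assert degree_summary(forward) == degree_summary(backward)

    def test_handshake_on_synthetic_networks(self, default_bundle):
        from mirnet.evidence_filter import filter_interactions

        interactions = filter_interactions(default_bundle.interactions)
        net = build_cluster_network(
            interactions.genes(), interactions, default_bundle.drugs, default_bundle.snps
        )
        mg = net.edges_of_type("mirna_gene")
        gene_degrees = sum(1 for e in mg)
        mirna_degrees = {}
        for mirna, _gene, _ in mg:
            mirna_degrees[mirna] = mirna_degrees.get(mirna, 0) + 1
        assert gene_degrees == sum(mirna_degrees.values()) == len(mg)


class TestRankings:
    def test_curated_target_counts(self):
        ranking = rank_mirnas(curated_interaction_set(), k=10)
        counts = dict(zip(ranking["mirna"], ranking["targeted_genes"]))
        assert counts["miR-146a-5p"] == len(MIR146A_ATHEROSCLEROSIS_TARGETS) == 18
        assert counts["miR-21-5p"] == len(MIR21_CARDIOMYOPATHY_TARGETS) == 10
        assert counts["miR-138-5p"] == len(MIR138_LIPID_TARGETS) == 8
        assert list(ranking["rank"]) == [1, 2, 3]

    def test_ties_break_lexicographically(self):
        interactions = interaction_set_from_pairs(
            [("miR-b", "G1"), ("miR-b", "G2"), ("miR-a", "G3"), ("miR-a", "G4")]
        )
        ranking = rank_mirnas(interactions, k=2)
        assert list(ranking["mirna"]) == ["miR-a", "miR-b"]

    def test_counts_match_brute_force_recount(self, default_bundle):
        from mirnet.evidence_filter import filter_interactions

        interactions = filter_interactions(default_bundle.interactions)
        ranking = rank_mirnas(
            interactions, default_bundle.snps, default_bundle.drugs, k=5
        )
        for row in ranking.itertuples(index=False):
            recount = len({g for m, g in interactions.pairs if m == row.mirna})
            assert row.targeted_genes == recount

    def test_snp_and_drug_counts_cover_target_genes(self):
        interactions = interaction_set_from_pairs([("miR-155-5p", "AGTR1")])
        ranking = rank_mirnas(
            interactions, snps=[PANEL_SNPS[0]], drugs=list(AGTR1_DRUGS), k=1
        )
        assert ranking.loc[0, "n_snps"] == 1
        assert ranking.loc[0, "n_drugs"] == 3

    def test_most_drugged_gene_ranks_first(self):
        interactions = interaction_set_from_pairs(
            [("miR-1", "CACNA1C"), ("miR-2", "OTHER")]
        )
        drugs = [DrugTargetRecord(drug=f"ccb-{i}", gene="CACNA1C") for i in range(13)]
        drugs += [DrugTargetRecord(drug="x", gene="OTHER")]
        ranking = rank_genes_by_drug_count(drugs, interactions, k=2)
        assert (ranking.loc[0, "gene"], ranking.loc[0, "n_drugs"]) == ("CACNA1C", 13)

    def test_gene_without_mirna_edge_is_excluded(self):
        interactions = interaction_set_from_pairs([("miR-1", "G1")])
        drugs = [DrugTargetRecord(drug="d", gene="NOTTARGET")]
        assert rank_genes_by_drug_count(drugs, interactions, k=5).empty

    def test_empty_drug_table(self):
        interactions = interaction_set_from_pairs([("miR-1", "G1")])
        assert rank_genes_by_drug_count([], interactions, k=5).empty


class TestExportImport:
    def test_sif_has_one_line_per_edge(self, agtr1_network, tmp_path):
        path = tmp_path / "net.sif"
        export_network(agtr1_network, "sif", path)
        lines = [l for l in path.read_text().splitlines() if l]
        assert len(lines) == 4

    def test_empty_network_graphml_is_valid(self, tmp_path):
        path = tmp_path / "empty.graphml"
        export_network(MultiLayerNetwork(), "graphml", path)
        assert import_network("graphml", path).nodes == {}

    @pytest.mark.parametrize("fmt", ["graphml", "sif"])
    def test_round_trip_preserves_network(self, fmt, tmp_path, default_bundle):
        from mirnet.evidence_filter import filter_interactions

        interactions = filter_interactions(default_bundle.interactions)
        genes = sorted(interactions.genes())[:40] + ["ORPHANGENE"]
        net = build_cluster_network(
            genes, interactions, default_bundle.drugs, default_bundle.snps
        )
        path = tmp_path / f"net.{fmt}"
        export_network(net, fmt, path)
        back = import_network(fmt, path)
        assert back.nodes == net.nodes
        assert back.edges == net.edges
        assert back.isolated == net.isolated

    def test_graphml_carries_shape_attributes(self, agtr1_network, tmp_path):
        import networkx as nx

        path = tmp_path / "net.graphml"
        export_network(agtr1_network, "graphml", path)
        g = nx.read_graphml(path)
        assert g.nodes["AGTR1"]["shape"] == "circle"
        assert g.nodes["rs5186"]["shape"] == "square"
        assert g.nodes["candesartan"]["shape"] == "triangle"
        assert g.nodes[AGTR1_MIRNAS[0]]["shape"] == "diamond"
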