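"""Wang S-values/similarity, similarity matrices and term clustering."""

import numpy as np
import pytest

import mirnet.term_similarity as ts
from mirnet.synthetic_data import SyntheticConfig, simulate_similarity_blocks
from mirnet.tables_io import OntologyDag
from mirnet.term_similarity import (
    ClusterAssignment,
    TermSimilarityMatrix,
    cluster_terms,
    report_clusters,
    s_values,
    similarity_matrix,
    wang_similarity,
)


def random_dag(seed: int, n_terms: int = 12) -> OntologyDag:
    """Random rooted DAG: each non-root term gets 1-2 parents earlier in order."""
    rng = np.random.default_rng(seed)
    names = [f"T{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.integers(0, 2)) if i > 1 else 1
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            relation = "is_a" if rng.random() < 0.7 else "part_of"
            edges.append((names[i], names[int(p)], relation))
    return OntologyDag({n: n for n in names}, edges)


class TestSValues:
    def test_chain_values(self, chain_dag):
        assert s_values("D", chain_dag) == pytest.approx({"D": 1.0, "A": 0.8, "C": 0.64})

    def test_root_has_trivial_map(self, chain_dag):
        assert s_values("C", chain_dag) == {"C": 1.0}

    def test_diamond_takes_best_path(self, diamond_dag):
        values = s_values("A", diamond_dag)
        assert values["R"] == pytest.approx(0.64)
        assert set(values) == {"A", "B", "C", "R"}

    def test_unknown_term_raises_key_error(self, chain_dag):
        with pytest.raises(KeyError):
            s_values("NOPE", chain_dag)

    def test_s_values_decay_strictly_along_chain(self):
        names = [f"L{i}" for i in range(6)]
        edges = [(names[i], names[i + 1], "is_a") for i in range(5)]
        dag = OntologyDag({n: n for n in names}, edges)
        values = s_values("L0", dag)
        chain = [values[n] for n in names]
        assert all(a > b for a, b in zip(chain, chain[1:]))


class TestWangSimilarity:
    def test_siblings_under_root(self, sibling_dag):
        assert wang_similarity("A", "B", sibling_dag) == pytest.approx(1.6 / 3.6)

    def test_self_similarity_is_one(self, sibling_dag):
        assert wang_similarity("A", "A", sibling_dag) == pytest.approx(1.0)

    def test_parent_child_on_chain(self, chain_dag):
        assert wang_similarity("D", "A", chain_dag) == pytest.approx(3.24 / 4.24)

    def test_unknown_term_raises(self, sibling_dag):
        with pytest.raises(KeyError):
            wang_similarity("A", "ZZ", sibling_dag)

    @pytest.mark.parametrize("seed", range(25))
    def test_symmetry_and_bounds_on_random_dags(self, seed):
        dag = random_dag(seed)
        terms = sorted(dag.terms)
        rng = np.random.default_rng(seed + 1000)
        for _ in range(8):
            a, b = (terms[int(i)] for i in rng.integers(0, len(terms), size=2))
            sab = wang_similarity(a, b, dag)
            assert sab == wang_similarity(b, a, dag)
            assert 0.0 <= sab <= 1.0 + 1e-12

    def test_similarity_decreases_with_ancestor_distance_on_chain(self):
        names = [f"L{i}" for i in range(6)]
        edges = [(names[i], names[i + 1], "is_a") for i in range(5)]
        dag = OntologyDag({n: n for n in names}, edges)
        sims = [wang_similarity("L0", n, dag) for n in names[1:]]
        assert all(a > b for a, b in zip(sims, sims[1:]))


class TestSimilarityMatrix:
    def test_single_term(self, sibling_dag):
        m = similarity_matrix(["A"], sibling_dag)
        assert m.values.shape == (1, 1) and m.values[0, 0] == 1.0

    def test_sibling_off_diagonal(self, sibling_dag):
        m = similarity_matrix(["A", "B"], sibling_dag)
        assert m.values[0, 1] == pytest.approx(4 / 9)

    def test_matrix_is_exactly_symmetric_with_unit_diagonal(self):
        dag = random_dag(7, n_terms=15)
        m = similarity_matrix(sorted(dag.terms), dag)
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 1.0)

    def test_duplicate_terms_rejected(self, sibling_dag):
        with pytest.raises(ValueError):
            similarity_matrix(["A", "A"], sibling_dag)

    def test_s_values_computed_once_per_term(self, sibling_dag, monkeypatch):
        calls = []
        original = ts.s_values

        def counting(term, dag):
            calls.append(term)
            return original(term, dag)

        monkeypatch.setattr(ts, "s_values", counting)
        similarity_matrix(["A", "B", "C"], sibling_dag)
        assert sorted(calls) == ["A", "B", "C"]


def _matrix(terms, sims):
    n = len(terms)
    values = np.eye(n)
    for (i, j), s in sims.items():
        values[i, j] = values[j, i] = s
    return TermSimilarityMatrix(terms=tuple(terms), values=values)


class TestClusterTerms:
    def test_hand_computed_average_linkage_merges(self):
        # d(A,B)=0.1, d(A,C)=0.9, d(B,C)=0.8 -> merge A,B at 0.1,
        # then {A,B},C at (0.9+0.8)/2 = 0.85
        m = _matrix(["A", "B", "C"], {(0, 1): 0.9, (0, 2): 0.1, (1, 2): 0.2})
        assignment = cluster_terms(m, linkage="average", cut_height=0.5)
        heights = assignment.merges[:, 2]
        assert heights == pytest.approx([0.1, 0.85])
        assert assignment.clusters() == {1: ["A", "B"], 2: ["C"]}

    def test_identical_terms_form_one_cluster_at_any_positive_cut(self):
        m = _matrix(["A", "B", "C"], {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0})
        assignment = cluster_terms(m, cut_height=0.01)
        assert len(set(assignment.labels.values())) == 1

    def test_zero_cut_makes_singletons_of_distinct_terms(self):
        m = _matrix(["A", "B"], {(0, 1): 0.5})
        assignment = cluster_terms(m, cut_height=0.0)
        assert len(set(assignment.labels.values())) == 2

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_cut_height_bounds(self, bad):
        m = _matrix(["A", "B"], {(0, 1): 0.5})
        with pytest.raises(ValueError):
            cluster_terms(m, cut_height=bad)

    def test_merge_heights_non_decreasing_on_random_input(self):
        dag = random_dag(3, n_terms=14)
        m = similarity_matrix(sorted(dag.terms), dag)
        assignment = cluster_terms(m)
        heights = assignment.merges[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_labels_invariant_under_term_permutation(self):
        blocks = simulate_similarity_blocks(2, 3, SyntheticConfig(seed=5))
        m1 = similarity_matrix(blocks.terms, blocks.dag)
        m2 = similarity_matrix(list(reversed(blocks.terms)), blocks.dag)
        c1 = cluster_terms(m1)
        c2 = cluster_terms(m2)
        assert c1.labels == c2.labels  # deterministic relabeling rule


class TestReportClusters:
    def test_min_size_filtering(self):
        assignment = ClusterAssignment(
            labels={"A": 1, "B": 1, "C": 2}, merges=np.empty((0, 4)), cut_height=0.7
        )
        table, singletons = report_clusters(assignment, min_size=2)
        assert list(table["members"]) == ["A//B"]
        assert singletons == ["C"]

    def test_all_singletons_give_empty_report(self):
        assignment = ClusterAssignment(
            labels={"A": 1, "B": 2}, merges=np.empty((0, 4)), cut_height=0.7
        )
        table, singletons = report_clusters(assignment, min_size=2)
        assert table.empty and singletons == ["A", "B"]

    @pytest.mark.parametrize("seed", range(10))
    def test_three_planted_blocks_are_recovered(self, seed):
        blocks = simulate_similarity_blocks(3, 4, SyntheticConfig(seed=seed))
        m = similarity_matrix(blocks.terms, blocks.dag)
        table, singletons = report_clusters(cluster_terms(m), min_size=2)
        assert len(table) == 3 and not singletons
        recovered = {frozenset(members.split("//")) for members in table["members"]}
        expected = {
            frozenset(t for t, b in blocks.blocks.items() if b == block)
            for block in (1, 2, 3)
        }
        assert recovered == expected
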