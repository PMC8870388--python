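"""Wang graph-based semantic similarity between ontology terms, and
hierarchical clustering of terms by similarity.

The Wang measure scores two terms by how much of their ancestry they share.
For an anchor term A, every term t in DAG_A (A plus its ancestors) gets an
S-value: S_A(A) = 1 and, walking upward,

    S_A(t) = max { w_e * S_A(t') : t' a child of t within DAG_A },

where w_e is the semantic contribution factor of the child->parent relation
(is_a 0.8, part_of 0.6 by convention). The similarity of A and B is

    sim(A, B) = sum_{t in DAG_A ∩ DAG_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B)),

with SV(X) the sum of all S-values of X. Terms are then clustered
agglomeratively on distance 1 - sim, and clusters of two or more terms are
reported, mirroring how enriched disease terms are grouped in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from mirnet.tables_io import OntologyDag


@dataclass(frozen=True)
class TermSimilarityMatrix:
    """Square, symmetric Wang similarity matrix over an ordered term list."""

    terms: tuple[str, ...]
    values: np.ndarray

    def sim(self, a: str, b: str) -> float:
        i, j = self.terms.index(a), self.terms.index(b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class ClusterAssignment:
    """Term -> cluster label mapping plus the agglomerative merge history."""

    labels: dict[str, int]
    merges: np.ndarray  # scipy linkage matrix (may be empty for 1 term)
    cut_height: float

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for term, label in self.labels.items():
            out.setdefault(label, []).append(term)
        return {label: sorted(members) for label, members in out.items()}


def s_values(term: str, dag: OntologyDag) -> dict[str, float]:
    """S-value map of ``term``: contribution of each of its ancestors.

    Covers exactly the term and its ancestors; S(term) = 1 and values decay
    multiplicatively along the child->parent edges, taking the best
    (maximum) path where several exist.
    """
    if term not in dag:
        raise KeyError(term)
    support = {term} | dag.ancestors(term)
    s: dict[str, float] = {term: 1.0}
    # Relax upward until stable; DAG_A is small, and each pass propagates
    # values one level further, so this terminates in <= depth passes.
    pending = True
    while pending:
        pending = False
        for t in support:
            if t == term:
                continue
            best = 0.0
            for child, _relation in dag.children(t):
                if child in s:
                    cand = dag.edge_weight(child, t) * s[child]
                    if cand > best:
                        best = cand
            if best > 0.0 and (t not in s or best > s[t] + 1e-15):
                s[t] = best
                pending = True
    return s


def semantic_value(s_map: dict[str, float]) -> float:
    """SV(X): the sum of a term's S-values."""
    return float(sum(s_map.values()))


def wang_similarity(a: str, b: str, dag: OntologyDag) -> float:
    """Wang semantic similarity of two terms, in [0, 1]."""
    sa = s_values(a, dag)
    sb = s_values(b, dag)
    return _similarity_from_s(sa, sb)


def _similarity_from_s(sa: dict[str, float], sb: dict[str, float]) -> float:
    shared = sorted(set(sa) & set(sb))
    if not shared:
        return 0.0
    numerator = sum(sa[t] + sb[t] for t in shared)
    return numerator / (semantic_value(sa) + semantic_value(sb))


def similarity_matrix(terms, dag: OntologyDag) -> TermSimilarityMatrix:
    """Pairwise Wang similarity; S-value maps computed once per term."""
    terms = tuple(terms)
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate term ids in similarity_matrix input")
    maps = {t: s_values(t, dag) for t in terms}
    n = len(terms)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = _similarity_from_s(maps[terms[i]], maps[terms[j]])
    return TermSimilarityMatrix(terms=terms, values=values)


def cluster_terms(
    matrix: TermSimilarityMatrix,
    linkage: str = "average",
    cut_height: float = 0.7,
) -> ClusterAssignment:
    """Agglomerative clustering of terms on distance 1 - sim.

    Merges whose height exceeds ``cut_height`` are cut, and the resulting
    groups become clusters. Labels are assigned 1..K ordered by cluster size
    descending, ties by the smallest member term id.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if not 0.0 <= cut_height <= 1.0:
        raise ValueError(f"cut_height must be in [0, 1], got {cut_height}")

    terms = matrix.terms
    n = len(terms)
    if n == 0:
        return ClusterAssignment(labels={}, merges=np.empty((0, 4)), cut_height=cut_height)
    if n == 1:
        return ClusterAssignment(
            labels={terms[0]: 1}, merges=np.empty((0, 4)), cut_height=cut_height
        )

    distance = 1.0 - matrix.values
    np.fill_diagonal(distance, 0.0)
    distance = np.clip((distance + distance.T) / 2.0, 0.0, None)
    condensed = squareform(distance, checks=False)
    merges = scipy_linkage(condensed, method=linkage)
    raw = fcluster(merges, t=cut_height, criterion="distance")

    # deterministic relabeling: by size desc, then smallest member term id
    groups: dict[int, list[str]] = {}
    for term, label in zip(terms, raw):
        groups.setdefault(int(label), []).append(term)
    ordered = sorted(groups.values(), key=lambda members: (-len(members), min(members)))
    labels = {term: i + 1 for i, members in enumerate(ordered) for term in members}
    return ClusterAssignment(labels=labels, merges=merges, cut_height=cut_height)


def report_clusters(assignment: ClusterAssignment, min_size: int = 2):
    """Tabulate clusters of at least ``min_size`` terms; singletons apart.

    Returns ``(clusters_df, singletons)`` where the DataFrame has columns
    cluster / size / members ("//"-joined) and ``singletons`` lists terms in
    clusters smaller than ``min_size``.
    """
    import pandas as pd

    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    rows = []
    singletons: list[str] = []
    for label, members in sorted(assignment.clusters().items()):
        if len(members) >= min_size:
            rows.append(
                {"cluster": label, "size": len(members), "members": "//".join(members)}
            )
        else:
            singletons.extend(members)
    df = pd.DataFrame(rows, columns=["cluster", "size", "members"])
    return df, sorted(singletons)


def write_similarity_matrix(matrix: TermSimilarityMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(matrix.values, index=matrix.terms, columns=matrix.terms).to_csv(
        path, sep="\t", index_label="term_id"
    )
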