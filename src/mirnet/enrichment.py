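"""Over-representation analysis of a gene set against ontology annotations.

For a universe of N genes, a term annotated to M of them, and a query of n
genes, the probability of observing an overlap of at least k by chance is the
hypergeometric upper tail P(X >= k). One test is performed per ontology term
that has any overlap with the query (and whose annotation size lies within
the configured bounds); p-values are Bonferroni-adjusted over the number of
tests actually performed. The same machinery serves both hierarchical
disease-ontology annotations (with upward propagation) and flat pathway
collections (a single-root DAG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

from mirnet.errors import NoTestableGenesError
from mirnet.tables_io import OntologyDag

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term ORA outcome.

    N: universe size; M: annotated genes within the universe; n: query genes
    within the universe; k: overlap; gene_ratio = k/n; bg_ratio = M/N;
    p: hypergeometric upper-tail probability; p_adj: Bonferroni-adjusted p.
    """

    term_id: str
    term_name: str
    N: int
    M: int
    n: int
    k: int
    p: float
    p_adj: float
    hits: frozenset[str]

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n

    @property
    def bg_ratio(self) -> float:
        return self.M / self.N


def hypergeom_upper_tail(k: int, N: int, M: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, M, n).

    N: population size, M: marked items, n: draws, k: observed marked draws.
    """
    if not (0 <= M <= N):
        raise ValueError(f"require 0 <= M <= N, got M={M}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(M, n)):
        raise ValueError(f"require 0 <= k <= min(M, n), got k={k}, M={M}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, M, n))


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """Multiply each p by the number of tests, capping at 1; order preserved."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value must be in (0, 1], got {p}")
        out.append(min(1.0, p * m))
    return out


def run_ora(
    query: Iterable[str],
    dag: OntologyDag,
    min_term_size: int = 5,
    max_term_size: int = 500,
    universe: Iterable[str] | None = None,
    propagate: bool = True,
    adjust_over_all_terms: bool = False,
) -> list[EnrichmentResult]:
    """Test every overlapping ontology term for over-representation.

    Parameters
    ----------
    query
        Gene symbols of interest (e.g. the validated target genes).
    dag
        Ontology with term -> gene annotations.
    min_term_size, max_term_size
        Only terms whose within-universe annotation count M lies in
        [min_term_size, max_term_size] are tested. Pass 0 / a large number
        to disable.
    universe
        Background gene set. Default: every gene annotated to at least one
        term (after propagation, if enabled). Query genes outside the
        universe are dropped (count logged).
    propagate
        Propagate annotations up the DAG before testing (default on).
    adjust_over_all_terms
        Bonferroni multiplier = all terms passing the size bounds, rather
        than only the tested (k >= 1) terms.

    Returns results sorted by p ascending, ties broken by term_id. Raises
    :class:`NoTestableGenesError` if nothing in the query is in the universe.
    """
    annotations = dag.propagated_annotations() if propagate else dict(dag.annotations)

    if universe is None:
        universe_set = set().union(*annotations.values()) if annotations else set()
    else:
        universe_set = {g.upper() for g in universe}

    query_set = {g.upper() for g in query}
    dropped = len(query_set - universe_set)
    if dropped:
        logger.info("run_ora: dropped %d query gene(s) outside the universe", dropped)
    effective_query = query_set & universe_set
    if not effective_query:
        raise NoTestableGenesError(
            "no testable genes: query does not intersect the annotation universe"
        )

    N = len(universe_set)
    n = len(effective_query)

    sized_terms = []  # terms within size bounds
    tested = []       # (term, M, k, hits) with k >= 1
    for term, genes in annotations.items():
        in_universe = genes & universe_set
        M = len(in_universe)
        if not (min_term_size <= M <= max_term_size):
            continue
        sized_terms.append(term)
        hits = in_universe & effective_query
        if hits:
            tested.append((term, M, len(hits), frozenset(hits)))

    multiplier = len(sized_terms) if adjust_over_all_terms else len(tested)
    results = []
    for term, M, k, hits in tested:
        p = hypergeom_upper_tail(k, N, M, n)
        p_adj = min(1.0, p * multiplier)
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=dag.terms.get(term, term),
                N=N,
                M=M,
                n=n,
                k=k,
                p=p,
                p_adj=p_adj,
                hits=hits,
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def dotplot_table(results: Sequence[EnrichmentResult], alpha: float = 0.05) -> pd.DataFrame:
    """Plot-data table behind the enrichment dot plot.

    Rows: significant terms (p_adj < alpha) with term_name, gene_ratio, k and
    p_adj, sorted by gene ratio descending.
    """
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "gene_ratio": r.gene_ratio,
            "k": r.k,
            "p_adj": r.p_adj,
        }
        for r in results
        if r.p_adj < alpha
    ]
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "gene_ratio", "k", "p_adj"])
    if not df.empty:
        df = df.sort_values(
            ["gene_ratio", "p_adj", "term_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df


def write_enrichment(results: Sequence[EnrichmentResult], path) -> None:
    """Write full ORA results as TSV."""
    rows = [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k,
            "n": r.n,
            "M": r.M,
            "N": r.N,
            "gene_ratio": r.gene_ratio,
            "bg_ratio": r.bg_ratio,
            "p": r.p,
            "p_adj": r.p_adj,
            "hits": "//".join(sorted(r.hits)),
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k", "n", "M", "N",
            "gene_ratio", "bg_ratio", "p", "p_adj", "hits",
        ],
    ).to_csv(path, sep="\t", index=False)
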