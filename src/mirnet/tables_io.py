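"""Readers, writers and domain records for the five input table shapes.

All tables are tab-separated UTF-8 with a header row; list-valued cells
(evidence strings, hit genes) use ``//`` as the within-cell separator,
mirroring common miRNA-target database exports. Gene symbols are upper-cased
and miRNA names canonicalized at read time so that all downstream comparisons
are plain case-sensitive string equality.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from mirnet.errors import OntologyStructureError, TableFormatError

LIST_SEP = "//"

#: Semantic contribution factor of an edge whose relation label has no
#: configured weight. Sits between the conventional is_a (0.8) and
#: part_of (0.6) factors.
DEFAULT_RELATION_WEIGHT = 0.7

DEFAULT_RELATION_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}

_RSID_RE = re.compile(r"^rs\d+$")


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionRecord:
    """One miRNA -> gene link with its evidence strings and provenance."""

    mirna: str
    gene: str
    evidence: tuple[str, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        if not self.mirna:
            raise ValueError("InteractionRecord.mirna must be non-empty")
        if not self.gene:
            raise ValueError("InteractionRecord.gene must be non-empty")


@dataclass(frozen=True)
class DiseaseAssociationRecord:
    """A miRNA associated with a disease-ontology term."""

    mirna: str
    term_id: str
    term_name: str


@dataclass(frozen=True)
class DrugTargetRecord:
    """A compound known to target or affect a gene."""

    drug: str
    gene: str


@dataclass(frozen=True)
class SnpRecord:
    """A dbSNP variant annotated to its host gene (1-based coordinate)."""

    rsid: str
    gene: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if not _RSID_RE.match(self.rsid):
            raise ValueError(f"not an rs-number identifier: {self.rsid!r}")
        if self.position <= 0:
            raise ValueError(f"SNP position must be positive, got {self.position}")


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

class OntologyDag:
    """Rooted DAG of ontology terms with weighted relations and annotations.

    Edges point child -> parent and each carries a relation label whose
    semantic contribution factor (used by the Wang similarity recursion)
    comes from ``relation_weights``, falling back to ``default_weight``
    for labels not in the map.

    Parameters
    ----------
    terms
        Mapping term id -> human-readable name.
    edges
        Iterable of (child_id, parent_id, relation) triples.
    annotations
        Mapping term id -> set of gene symbols directly annotated to it.
    relation_weights
        Mapping relation label -> factor in (0, 1).
    default_weight
        Factor for relation labels absent from ``relation_weights``.
    """

    def __init__(
        self,
        terms: Mapping[str, str],
        edges: Iterable[tuple[str, str, str]] = (),
        annotations: Mapping[str, Iterable[str]] | None = None,
        relation_weights: Mapping[str, float] | None = None,
        default_weight: float = DEFAULT_RELATION_WEIGHT,
    ) -> None:
        self.terms: dict[str, str] = dict(terms)
        self.relation_weights: dict[str, float] = dict(
            DEFAULT_RELATION_WEIGHTS if relation_weights is None else relation_weights
        )
        self.default_weight = float(default_weight)
        for label, w in self.relation_weights.items():
            if not 0.0 < w < 1.0:
                raise ValueError(f"relation weight for {label!r} must be in (0,1), got {w}")
        if not 0.0 < self.default_weight < 1.0:
            raise ValueError(f"default relation weight must be in (0,1), got {default_weight}")

        # child -> parent graph
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.terms)
        for child, parent, relation in edges:
            if parent not in self.terms:
                raise OntologyStructureError(
                    f"dangling parent {parent!r} (edge {child!r} -> {parent!r})"
                )
            if child not in self.terms:
                raise OntologyStructureError(
                    f"dangling child {child!r} (edge {child!r} -> {parent!r})"
                )
            self._graph.add_edge(child, parent, relation=relation)

        try:
            cycle = nx.find_cycle(self._graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyStructureError(f"ontology contains a cycle: {path}")

        self.annotations: dict[str, frozenset[str]] = {}
        if annotations:
            for term, genes in annotations.items():
                if term not in self.terms:
                    raise OntologyStructureError(
                        f"annotation references unknown term {term!r}"
                    )
                self.annotations[term] = frozenset(g.upper() for g in genes)

    # -- structure ---------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def roots(self) -> frozenset[str]:
        """Terms with no parent."""
        return frozenset(t for t in self.terms if self._graph.out_degree(t) == 0)

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs of ``term``."""
        return [(p, self._graph.edges[term, p]["relation"]) for p in self._graph.successors(term)]

    def children(self, term: str) -> list[tuple[str, str]]:
        """(child, relation) pairs of ``term``."""
        return [(c, self._graph.edges[c, term]["relation"]) for c in self._graph.predecessors(term)]

    def ancestors(self, term: str) -> set[str]:
        if term not in self.terms:
            raise KeyError(term)
        return set(nx.descendants(self._graph, term))  # child->parent direction

    def edge_weight(self, child: str, parent: str) -> float:
        relation = self._graph.edges[child, parent]["relation"]
        return self.relation_weights.get(relation, self.default_weight)

    def edge_list(self) -> list[tuple[str, str, str]]:
        return sorted(
            (c, p, d["relation"]) for c, p, d in self._graph.edges(data=True)
        )

    # -- annotations -------------------------------------------------------

    def propagated_annotations(self) -> dict[str, frozenset[str]]:
        """Annotations propagated up the DAG.

        A gene annotated to a term also counts for every ancestor of that
        term (the usual ontology-aware ORA convention).
        """
        acc: dict[str, set[str]] = {t: set(g) for t, g in self.annotations.items()}
        for term in nx.topological_sort(self._graph):  # children before parents
            genes = acc.get(term)
            if not genes:
                continue
            for parent in self._graph.successors(term):
                acc.setdefault(parent, set()).update(genes)
        return {t: frozenset(g) for t, g in acc.items()}


# ---------------------------------------------------------------------------
# identifier normalization
# ---------------------------------------------------------------------------

def normalize_mirna_name(raw: str) -> str:
    """Canonicalize a mature miRNA name.

    Strips the human species prefix ``hsa-``, canonicalizes the family token
    to ``miR-`` or ``let-`` and lower-cases the remainder (arm suffixes such
    as ``-5p`` included), so that e.g. ``HSA-LET-7A-5P`` -> ``let-7a-5p`` and
    ``hsa-miR-138-5p`` -> ``miR-138-5p``.
    """
    if not raw:
        raise ValueError("empty miRNA name")
    name = raw.strip()
    if name.lower().startswith("hsa-"):
        name = name[4:]
    lowered = name.lower()
    if lowered.startswith("mir-"):
        return "miR-" + lowered[4:]
    if lowered.startswith("mir"):  # e.g. "miR138-5p" without the dash
        return "miR-" + lowered[3:].lstrip("-")
    if lowered.startswith("let-"):
        return "let-" + lowered[4:]
    if lowered.startswith("let"):
        return "let-" + lowered[3:].lstrip("-")
    return name


# ---------------------------------------------------------------------------
# table readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path.name}: missing mandatory column(s) {', '.join(missing)}"
        )
    return df


def read_interactions(path: str | Path, source: str = "") -> list[InteractionRecord]:
    """Read a miRNA-target interaction table.

    Expects columns ``mirna``, ``gene``, ``evidence`` (``//``-joined list;
    may be empty). Extra columns are ignored. Records are returned in file
    order, non-deduplicated: collapsing duplicates is the filter stage's job.
    """
    df = _read_tsv(path, ("mirna", "gene", "evidence"))
    records: list[InteractionRecord] = []
    for row in df.itertuples(index=False):
        evidence = tuple(e.strip() for e in row.evidence.split(LIST_SEP) if e.strip())
        records.append(
            InteractionRecord(
                mirna=normalize_mirna_name(row.mirna),
                gene=row.gene.strip().upper(),
                evidence=evidence,
                source=source or getattr(row, "source", ""),
            )
        )
    return records


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    rows = [
        {
            "mirna": r.mirna,
            "gene": r.gene,
            "evidence": LIST_SEP.join(r.evidence),
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["mirna", "gene", "evidence", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_disease_associations(path: str | Path) -> list[DiseaseAssociationRecord]:
    """Read miRNA-disease associations (columns mirna, term_id, term_name)."""
    df = _read_tsv(path, ("mirna", "term_id", "term_name"))
    return [
        DiseaseAssociationRecord(
            mirna=normalize_mirna_name(row.mirna),
            term_id=row.term_id.strip(),
            term_name=row.term_name.strip(),
        )
        for row in df.itertuples(index=False)
    ]


def write_disease_associations(
    records: Iterable[DiseaseAssociationRecord], path: str | Path
) -> None:
    rows = [
        {"mirna": r.mirna, "term_id": r.term_id, "term_name": r.term_name}
        for r in records
    ]
    pd.DataFrame(rows, columns=["mirna", "term_id", "term_name"]).to_csv(
        path, sep="\t", index=False
    )


def read_drug_targets(path: str | Path) -> list[DrugTargetRecord]:
    """Read drug-target records (columns drug, gene); deduplicated on load."""
    df = _read_tsv(path, ("drug", "gene"))
    seen: set[tuple[str, str]] = set()
    records: list[DrugTargetRecord] = []
    for row in df.itertuples(index=False):
        pair = (row.drug.strip(), row.gene.strip().upper())
        if pair in seen:
            continue
        seen.add(pair)
        records.append(DrugTargetRecord(drug=pair[0], gene=pair[1]))
    return records


def write_drug_targets(records: Iterable[DrugTargetRecord], path: str | Path) -> None:
    rows = [{"drug": r.drug, "gene": r.gene} for r in records]
    pd.DataFrame(rows, columns=["drug", "gene"]).to_csv(path, sep="\t", index=False)


def read_snps(path: str | Path) -> list[SnpRecord]:
    """Read SNP annotations (columns rsid, gene, chromosome, position)."""
    df = _read_tsv(path, ("rsid", "gene", "chromosome", "position"))
    records: list[SnpRecord] = []
    for row in df.itertuples(index=False):
        try:
            position = int(row.position)
        except ValueError as exc:
            raise TableFormatError(
                f"non-integer SNP position {row.position!r} for {row.rsid}"
            ) from exc
        records.append(
            SnpRecord(
                rsid=row.rsid.strip(),
                gene=row.gene.strip().upper(),
                chromosome=str(row.chromosome).strip(),
                position=position,
            )
        )
    return records


def write_snps(records: Iterable[SnpRecord], path: str | Path) -> None:
    rows = [
        {"rsid": r.rsid, "gene": r.gene, "chromosome": r.chromosome, "position": r.position}
        for r in records
    ]
    pd.DataFrame(rows, columns=["rsid", "gene", "chromosome", "position"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# ontology readers/writers
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a term -> gene annotation table (columns term_id, gene)."""
    df = _read_tsv(path, ("term_id", "gene"))
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.term_id.strip(), set()).add(row.gene.strip().upper())
    return out


def write_annotations(annotations: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"term_id": term, "gene": gene}
        for term in sorted(annotations)
        for gene in sorted(annotations[term])
    ]
    pd.DataFrame(rows, columns=["term_id", "gene"]).to_csv(path, sep="\t", index=False)


def _read_obo(path: Path) -> tuple[dict[str, str], list[tuple[str, str, str]]]:
    import obonet

    graph = obonet.read_obo(path)
    terms = {n: str(d.get("name", n)) for n, d in graph.nodes(data=True)}
    edges = [(child, parent, key) for child, parent, key in graph.edges(keys=True)]
    return terms, edges


def _read_edgelist(path: Path) -> tuple[dict[str, str], list[tuple[str, str, str]]]:
    df = _read_tsv(path, ("child_id", "parent_id"))
    relation_col = "relation" if "relation" in df.columns else None
    name_col = "child_name" if "child_name" in df.columns else None
    terms: dict[str, str] = {}
    edges: list[tuple[str, str, str]] = []
    for row in df.itertuples(index=False):
        child = row.child_id.strip()
        parent = row.parent_id.strip()
        relation = getattr(row, relation_col).strip() if relation_col else "is_a"
        terms.setdefault(child, getattr(row, name_col) if name_col else child)
        terms.setdefault(parent, parent)
        edges.append((child, parent, relation))
    return terms, edges


def read_ontology(
    path: str | Path,
    dialect: str = "edgelist",
    annotations: str | Path | Mapping[str, Iterable[str]] | None = None,
    relation_weights: Mapping[str, float] | None = None,
    default_weight: float = DEFAULT_RELATION_WEIGHT,
) -> OntologyDag:
    """Load an ontology DAG from an OBO file or a child/parent edge list.

    ``dialect`` is ``"obo"`` or ``"edgelist"``. ``annotations`` may be a path
    to a term/gene TSV or an in-memory mapping. Acyclicity is verified; a
    detected cycle raises :class:`OntologyStructureError` naming one cycle.
    """
    path = Path(path)
    if dialect == "obo":
        terms, edges = _read_obo(path)
    elif dialect == "edgelist":
        terms, edges = _read_edgelist(path)
    else:
        raise ValueError(f"unknown ontology dialect {dialect!r}")

    ann: Mapping[str, Iterable[str]] | None
    if annotations is None or isinstance(annotations, Mapping):
        ann = annotations
    else:
        ann = read_annotations(annotations)
    return OntologyDag(
        terms,
        edges,
        annotations=ann,
        relation_weights=relation_weights,
        default_weight=default_weight,
    )


def write_ontology_edgelist(dag: OntologyDag, path: str | Path) -> None:
    rows = [
        {
            "child_id": child,
            "parent_id": parent,
            "relation": relation,
            "child_name": dag.terms[child],
        }
        for child, parent, relation in dag.edge_list()
    ]
    pd.DataFrame(rows, columns=["child_id", "parent_id", "relation", "child_name"]).to_csv(
        path, sep="\t", index=False
    )
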