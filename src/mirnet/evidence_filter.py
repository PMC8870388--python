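"""Strong-evidence filtering of miRNA-target interactions.

Database exports mix support types from direct functional assays (reporter
gene / luciferase assays, immunoblot / Western blot, RT-qPCR) with weaker
high-throughput evidence (microarray, CLIP-seq, pSILAC). Downstream analyses
use only interactions backed by at least one strong assay; matching is
case-insensitive substring search against a configurable keyword set, with
non-alphanumeric characters stripped first so that spelling variants such as
"RT-qPCR" / "qRT-PCR" / "real-time PCR" are all caught.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from mirnet.tables_io import InteractionRecord

#: Assay-family keywords counted as strong experimental validation.
DEFAULT_EVIDENCE_KEYWORDS: tuple[str, ...] = (
    "luciferase",
    "reporter",
    "western",
    "immunoblot",
    "qpcr",
    "qrt-pcr",
    "real-time",
)

_STRIP_RE = re.compile(r"[^a-z0-9]+")


def _canon(text: str) -> str:
    return _STRIP_RE.sub("", text.lower())


@dataclass(frozen=True)
class EvidenceKeywordSet:
    """Keywords defining strong evidence, with the match mode.

    mode="any": a record passes if any evidence string contains any keyword.
    mode="all": every keyword must be found in at least one evidence string.
    """

    keywords: tuple[str, ...] = DEFAULT_EVIDENCE_KEYWORDS
    mode: str = "any"

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keyword list must be non-empty")
        if self.mode not in ("any", "all"):
            raise ValueError(f"mode must be 'any' or 'all', got {self.mode!r}")


@dataclass(frozen=True)
class PairSummary:
    """Evidence bookkeeping for one surviving (miRNA, gene) pair."""

    n_records: int
    evidence: tuple[str, ...]
    sources: tuple[str, ...]


@dataclass(frozen=True)
class InteractionSet:
    """Deduplicated strong-evidence (miRNA, gene) pairs.

    ``pairs`` is sorted lexicographically by (mirna, gene); every pair is
    traceable to at least one passing input record via ``summaries``.
    """

    pairs: tuple[tuple[str, str], ...]
    summaries: dict[tuple[str, str], PairSummary] = field(default_factory=dict)
    counts_by_source: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> set[str]:
        return {gene for _, gene in self.pairs}

    def mirnas(self) -> set[str]:
        return {mirna for mirna, _ in self.pairs}

    def targets_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.pairs if m == mirna}


def classify_evidence(
    evidence: Sequence[str],
    keywords: EvidenceKeywordSet | None = None,
) -> bool:
    """Return True if the evidence strings satisfy the keyword set.

    Empty evidence never passes. Matching strips non-alphanumerics from both
    sides and does case-insensitive substring search.
    """
    kw = keywords or EvidenceKeywordSet()
    canon_evidence = [_canon(e) for e in evidence if e]
    canon_keywords = [_canon(k) for k in kw.keywords]
    if not canon_evidence:
        return False
    if kw.mode == "any":
        return any(k in e for e in canon_evidence for k in canon_keywords)
    return all(any(k in e for e in canon_evidence) for k in canon_keywords)


def filter_interactions(
    records: Iterable[InteractionRecord],
    keywords: EvidenceKeywordSet | None = None,
) -> InteractionSet:
    """Keep strong-evidence records and deduplicate (miRNA, gene) pairs."""
    kw = keywords or EvidenceKeywordSet()
    by_pair: dict[tuple[str, str], dict] = {}
    counts_by_source: dict[str, int] = {}
    for record in records:
        if not classify_evidence(record.evidence, kw):
            continue
        pair = (record.mirna, record.gene)
        slot = by_pair.setdefault(
            pair, {"n": 0, "evidence": [], "sources": []}
        )
        slot["n"] += 1
        for e in record.evidence:
            if e not in slot["evidence"]:
                slot["evidence"].append(e)
        if record.source and record.source not in slot["sources"]:
            slot["sources"].append(record.source)
        counts_by_source[record.source] = counts_by_source.get(record.source, 0) + 1

    pairs = tuple(sorted(by_pair))
    summaries = {
        pair: PairSummary(
            n_records=slot["n"],
            evidence=tuple(slot["evidence"]),
            sources=tuple(slot["sources"]),
        )
        for pair, slot in by_pair.items()
    }
    return InteractionSet(pairs=pairs, summaries=summaries, counts_by_source=counts_by_source)


def write_interaction_set(interactions: InteractionSet, path) -> None:
    """Write surviving pairs as TSV (mirna, gene, n_evidence, sources)."""
    import pandas as pd

    rows = [
        {
            "mirna": mirna,
            "gene": gene,
            "n_evidence": len(interactions.summaries[(mirna, gene)].evidence),
            "sources": "//".join(interactions.summaries[(mirna, gene)].sources),
        }
        for mirna, gene in interactions.pairs
    ]
    pd.DataFrame(rows, columns=["mirna", "gene", "n_evidence", "sources"]).to_csv(
        path, sep="\t", index=False
    )


def interaction_set_from_pairs(pairs: Iterable[tuple[str, str]]) -> InteractionSet:
    """Build an InteractionSet directly from known-good (miRNA, gene) pairs.

    Convenience for curated lists that carry no evidence strings; each pair
    gets a one-record summary.
    """
    unique = sorted(set(pairs))
    summaries = {
        pair: PairSummary(n_records=1, evidence=(), sources=()) for pair in unique
    }
    return InteractionSet(pairs=tuple(unique), summaries=summaries, counts_by_source={})
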