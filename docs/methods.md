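# Methods

## Pipeline model

The package treats a pharmacogenomic miRNA-network study as four
deterministic transformations over five tabular inputs (miRNA–target
interactions with free-text evidence, miRNA–disease associations,
drug–target pairs, SNP–gene annotations, and a disease-ontology DAG with
term→gene annotations):

raw interactions → strong-evidence pair set → enriched ontology terms →
term clusters → per-cluster multi-layer networks.

Every stage writes a plain table before the next stage reads anything, so
each intermediate is independently inspectable and each stage can be rerun
from the command line.

## Evidence filtering

An interaction record passes if at least one of its evidence strings
contains at least one keyword of the configured set (default:
`luciferase, reporter, western, immunoblot, qpcr, qrt-pcr, real-time`),
after lower-casing and stripping non-alphanumeric characters from both
sides. Stripping makes spelling variants ("RT-qPCR", "qRT PCR",
"real-time PCR") converge onto the same token stream. The default `any`
mode reflects how curated databases record support: the assay families are
alternative acceptable validations, not a required conjunction; an `all`
mode exists for stricter protocols. Surviving records are deduplicated to
(miRNA, gene) pairs, sorted lexicographically, with per-pair evidence and
provenance retained. Filtering is monotone in the keyword set (under
`any`) and idempotent.

Gene symbols are upper-cased and miRNA names canonicalized (species
prefix stripped, `miR-`/`let-` capitalization fixed, arm suffix kept) once
at read time; all later comparisons are exact string equality.

## Over-representation analysis

The test is the standard one-sided hypergeometric ORA. The universe
defaults to all genes annotated to at least one term — the most common
convention when no explicit background is given — and is configurable.
Annotations propagate up the DAG by default (a gene annotated to a child
counts for its ancestors), the usual ontology-aware convention; a flat
single-root collection (e.g. pathway gene sets) is the same computation
with propagation having nothing to do. Terms are tested when their
within-universe annotation count M lies within size bounds (default
[5, 500], avoiding degenerate one-gene terms) and they overlap the query
(k ≥ 1). The Bonferroni multiplier counts the tests actually performed;
a flag switches to all size-eligible terms. Tail probabilities come from
`scipy.stats.hypergeom.sf`; the test suite checks them against an exact
rational-arithmetic tail sum for every parameter combination with N ≤ 12
at 1e-12.

## Wang similarity and term clustering

S-values are computed by upward relaxation from the anchor over
`DAG_A`; the max rule selects the best-contributing path through multiple
parents. Semantic contribution factors are the conventional is_a = 0.8 and
part_of = 0.6, with 0.7 for unknown relation labels (between the two
conventions); all are configurable per ontology. Distances are `1 − sim`
(the simplest monotone transform), linkage defaults to average (UPGMA),
and the tree is cut at height 0.7: merges above the cut are broken and the
remaining groups become clusters, labelled 1..K by size descending then
smallest member id (a pure determinism device). The 0.7 default separates
groups that share only a root (sim ≈ 0.12–0.17, distance ≈ 0.83+) from
groups sharing a deep ancestor chain (sim ≈ 0.66–0.70); it is a
configuration knob, not a scientific claim.

## Network assembly and degree statistics

Cluster gene sets are the union of enrichment hit genes over the
cluster's member terms (a per-term network can be built by passing a
single term's hits). Gene nodes are the cluster genes; miRNA, drug and SNP
nodes enter only through an edge to a cluster gene; cluster genes with no
edge at all are retained but flagged isolated so node counts remain
auditable against the enrichment output. SNPs are distinct square nodes
with `snp_gene` edges, not gene attributes, matching how such maps are
drawn in Cytoscape.

Degree statistics are computed over miRNA–gene edges only — the question
is how many miRNAs regulate each gene; drug and SNP links are annotation
layers. The buckets are strict (`< 5`, `> 10`; degrees 5–10 fall in
neither). Means are rounded to 1 decimal and percentages to 2, using
half-away-from-zero rounding (17/160 = 10.625% → 10.63, which
bankers' rounding would report as 10.62). Rankings break count ties
lexicographically. GraphML carries node_type/shape/isolated and edge_type
attributes; SIF uses the edge type as relation token and writes isolated
nodes as bare lines (on import such nodes are typed as genes — the only
node type this pipeline retains without edges).

## Synthetic data generator

The generator emulates the *shapes* and the *statistical structure* of the
real database exports, not their content: evidence strings are drawn from
a fixed vocabulary with both passing and failing assay names; the ontology
is a rooted b-ary tree (depth 3, branching 3 → 40 terms) with sparse
part_of cross-links; 500 genes are dealt to the 27 leaves by a balanced
random deal (random permutation, round-robin), so each leaf term holds
18–19 genes with random membership; hub miRNA target counts follow a
truncated power law (scale 30, cap 60, exponent 2.5) to mimic the
heavy-tailed skew of real target databases.

Planting: each of 2 planted leaf terms gets a hub miRNA whose targets
include 80% of the term's annotated genes (`planted_effect = 0.8`), topped
up with uniform background genes; the remaining miRNAs (panel size 12,
the scale of a curated CVD biomarker panel) target each gene independently
with probability 0.01; each record's evidence passes the default filter
with probability 0.9. A single seeded NumPy generator is threaded through
all tables, so a configuration reproduces byte-identical files.

These defaults were set by a power analysis of the planted-recovery
design: with query size ≈ 100–130 of a 500-gene universe and ≈ 40 tested
terms, a planted term (M ≈ 18, k ≈ 12–14) sits several standard deviations
above its null mean, leaving the recovery property (all planted terms at
`p_adj < 0.05`) holding in ≈ 98% of runs with no decoy leaf term
significant — margins verified over six disjoint 50-seed windows. The
companion block generator builds, per block, a private 2–3-term ancestor
chain under a shared root, which guarantees within-block similarity above
and between-block similarity below the default cut.

What the generator does **not** emulate: real database accession
semantics, PubMed-linked evidence provenance, genome-accurate SNP
coordinates, correlated miRNA families, or annotation sizes spanning
orders of magnitude as in the real disease ontology. Passing recovery
tests therefore demonstrates correctness of the machinery under the
planted model, not performance on real database snapshots.

## Numerical and degenerate-input choices

- Hypergeometric tails delegate to scipy; `k = 0` short-circuits to 1.
- Bonferroni rejects p-values outside (0, 1] rather than silently
  clamping.
- An empty effective query (no gene in the universe) is an explicit
  `NoTestableGenesError`; the pipeline aborts naming the stage.
- A similarity matrix over one term skips linkage entirely; cutting at
  height 0 separates all distinct terms; distance-0 duplicates always
  co-cluster.
- A network with no gene nodes has no defined degree summary (error); a
  network with genes but no miRNA edges reports mean 0.0 and 100% in the
  `< 5` bucket.
- Ontology loading verifies acyclicity and rejects dangling parents,
  reporting one offending cycle.

## Problem sizes

Default test and analysis runs use the generator defaults above
(500 genes, 12 miRNAs, 40 terms); the recovery sweeps use 50 seeds and the
block-recovery sweeps 20 seeds. These sizes keep every stage's behaviour
statistically visible while the full suite runs in seconds.

## Known limitations

- The similarity measure is Wang's graph-based method only; information-
  content measures (Resnik/Lin) are out of scope.
- Multiple-testing control is Bonferroni only, as the analysis this
  package operationalizes specifies; no FDR procedures.
- SIF round-trips rely on the pipeline's invariant that only gene nodes
  can be isolated; foreign SIF files with isolated non-gene nodes would
  import those nodes as genes.
- Disease-term selection (which ontology terms define "CVD-associated")
  is a user-supplied list, not a packaged constant.
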