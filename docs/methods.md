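# Methods

This note records the modeling decisions behind `kgpathrank`: what each
stage assumes, which parameters matter, and what the synthetic fixtures do
and do not emulate.

## Graph model

The knowledge graph is an undirected multigraph of typed entities. The
entity-type vocabulary is closed (18 types: compound, phenotype, gene,
biological_process, enzyme_class, go, pathway, organism, tissue, disease,
chemical, species, protein_mutation, snp, dna_mutation, cell_line, genus,
strain); unknown labels are rejected at load time unless lenient parsing is
requested. The relation vocabulary is the 27 curated chemogenomic labels
plus the literature label `co_occur` (28 total). Labels are normalized to
lowercase because source files print both cases.

Design choices:

* **Edges are a multiset.** Parallel edges with different labels encode
  genuinely different evidence (a curated `gene_gene` assertion and a
  literature co-mention), and duplicate rows in source tables are preserved
  rather than silently collapsed — dedup is the merge step's job, where it
  is explicit and counted.
* **Self-loops are rejected.** Path semantics assume distinct endpoints,
  and none of the supported sources emit them; loops produced by entity
  merging are dropped and counted.
* **Degree = number of distinct neighbors**, not edge multiplicity. This is
  the quantity node size conventionally encodes in rendered subgraphs, and
  it is invariant to how many parallel edges support a link.
* **Stored orientation is metadata.** Curated tables declare a head and a
  tail; the orientation is preserved on write, but degree, ego networks and
  path enumeration all treat edges as undirected, because the relations of
  interest (co-mention, interaction, association) are symmetric in use:
  ranked paths traverse `gene_disease` edges in both directions.
* **Ego networks are induced subgraphs** on all nodes within radius r
  (default 1, as a neighborhood inspection tool); hop counting ignores
  labels and weights, and every parent edge between retained nodes is
  retained, so triangles survive. Each retained node is annotated with its
  ego-subgraph degree for rendering.

Entities are keyed as `type::normalized-name`, so a gene and a disease
sharing a surface name are distinct nodes.

## Name normalization

`normalize_name` lowercases, maps underscores to spaces, collapses internal
whitespace and strips. Underscores are treated as spaces because printed
path records join multi-word names either way ("il-6_receptor" and
"il-6 receptor" denote the same entity). Normalization is idempotent.

## Co-occurrence extraction

Counting is per-document binary: a pair of distinct (name, type) entities
mentioned in the same title/abstract gains +1 per document, however many
times either is repeated inside it. Edge weight is therefore the number of
supporting documents. Mention character offsets are parsed and validated
but do not affect counting; no sentence windows and no association
weighting (PMI etc.) are applied — weights are raw document counts. The
minimum-weight threshold defaults to 1 (all observed pairs kept). Mentions
without a database identifier are kept: the pipeline operates on surface
names, and discarding unidentified mentions would bias literature coverage.

## Disambiguation and merging

Each (name, type) is compared against every same-type lexicon entry; an
entry's score is the maximum similarity between the name and any of the
entry's surface forms (canonical or synonym). Links require score ≥ τ;
ties break on higher score, then lexicographically smaller canonical —
reproducibility over cleverness. Unlinked entities stay self-canonical.

* **Similarity**: normalized Levenshtein `1 − dist/max(|a|,|b|)` (edlib
  under the hood; two empty strings are defined as identical). The metric
  is pluggable through `MergeConfig`.
* **Threshold τ = 0.95 by default.** The right value is a property of the
  lexicon and corpus at hand and must be re-calibrated per deployment, so τ
  is a first-class parameter rather than a constant.
* **Type constraint is hard.** "Similar types" is implemented
  conservatively as identical type. Optional equivalence pairs
  (chemical≡compound, species≡organism) exist behind a switch that is off
  by default, because merged-graph statistics conventionally keep those
  types separate.
* **Merge semantics.** Entities resolving to the same (canonical, type)
  become one node with the union of synonyms and sources, displayed under
  the lexicon canonical. `co_occur` edges between the same canonical pair
  combine by summing weights (document counts add); curated parallel edges
  are all retained. Edges collapsing to self-loops are dropped with a
  counter. A conflict is raised only when *lexicon-justified* links of
  different types target the same canonical term; self-canonical entities
  group by (name, own type) and never conflict, which is what lets a gene
  and a disease share a surface name after merging.
* The merge returns optional bookkeeping (`MergeReport`): entities in/out/
  absorbed, edges in/out, co-occurrence pairs combined, self-loops dropped.
  These satisfy exact conservation identities that the test suite checks on
  random graph pairs.

## Path ranking

* **Exact depth, not shortest path.** Queries enumerate all node-simple
  paths with exactly d edges (depth = edge count; a depth-2 path has three
  nodes), separately per depth. Exact-depth semantics are what makes
  per-depth path counts and per-depth score distributions well-defined.
* **Multigraph traversal.** Distinct parallel edge instances give distinct
  paths. Enumeration is delegated to `networkx.all_simple_edge_paths`
  (filtered to exact length) and verified in tests against an exhaustive
  depth-limited DFS oracle on random multigraphs.
* **Entity vectors.** The embedding store lowercases tokens at load and at
  lookup. A multi-word entity name is first tried under phrase conventions
  (as-is, underscore-joined, hyphen-joined, concatenated); failing that,
  the mean of its in-vocabulary whitespace tokens is used; if no token is
  known the entity is unembeddable. Paths containing an unembeddable node
  are **dropped and counted**, not zero-scored: zeros would silently favor
  longer out-of-vocabulary-laden paths.
* **Score** S = Σ cos(v(nᵢ₋₁), v(nᵢ)), bounded by ±d, invariant under path
  reversal and under any orthogonal transform of the embedding space.
  Cosine of a zero vector is an error, not 0.
* **Selection** keeps scores strictly greater than the nearest-rank q-th
  percentile (the ⌈(q/100)·n⌉-th smallest score), q = 95 by default. With
  n distinct scores this retains ⌊n·(1−q/100)⌋ paths (202 → 10); with heavy
  ties it can retain many more or none (all-tied → none) — the convention
  chosen precisely because it reproduces both regimes observed in practice.
* **Distinct-relationship counting** has two conventions, both exposed:
  typed (undirected node–label–node triples) and untyped (unordered node
  pairs). Published summaries use each in different places, so no single
  intent is guessed; `run_path_query` reports both.
* Ties in the ranking break on node then label sequence; report
  serialization rounds scores to 6 decimals (the precision path tables are
  printed at); score assertions in tests use absolute tolerance 1e−9.

## Synthetic fixtures

A `FixturePlan` fixes a seed, per-type entity counts, per-label Bernoulli
edge densities, planted paths with target per-step cosines, a pairwise
co-mention plan, and a lexicon plan. All randomness flows from the plan's
seed through a local `numpy` generator — no global state — so identical
plans give identical fixtures, byte-for-byte after serialization.

* **Embedding planting** assembles a Gram matrix over the constrained
  entities: specified entries from the planted cosines, unspecified entries
  completed with the product of constraints along a BFS spanning-tree path
  of the constraint graph (exact and positive semidefinite for acyclic
  constraint sets, which planted simple paths are), zeros across
  components. The matrix is factorized by eigendecomposition (eigenvalues
  below −1e−9 ⇒ infeasible plan), rows normalized to unit vectors, and
  every planted cosine verified to 1e−6 — exactness and determinism over
  iterative optimization. The dimension must be at least the number of
  constrained entities. Unconstrained entities get seeded random unit
  vectors.
* **Document generation** emits, per planned pair, exactly that many
  two-mention documents, so co-occurrence extraction recovers the plan
  exactly (generator/extractor duality, tested).
* **Lexicon generation** mutates canonicals with ≤ max_edits random edits
  and verifies the bound with the real distance function.

What the fixtures deliberately do **not** emulate: realistic degree
distributions (edges are i.i.d. Bernoulli, not scale-free), realistic
document text (titles are templates around the mentions), embedding
geometry of real language models (unconstrained vectors are isotropic
random), or lexicon noise beyond character edits. Passing tests therefore
demonstrate algorithmic correctness — enumeration, counting, scoring,
selection, conservation — not robustness to the messiness of real curated
tables or NER output.

## Bundled reference records

Two published case-study tables of top-ranked paths (IL-6 receptor →
hydroxychloroquine; STAT1 → chloroquine) ship as plain-text TSVs of
`declared_depth, path_record, score`. They are inputs for the parser and
for relationship counting; the package does not re-derive their scores,
which depend on an external biomedical word2vec model and its phrase
vocabulary. One printed row declares depth 3 but carries four edges; it is
preserved verbatim, and counting code filters on actual edge count.

## Problem sizes

Tests and the acceptance script run entirely on synthetic inputs at small
scale, chosen so the whole suite completes in seconds while still
exercising every code path: random multigraphs of ≤ 12 nodes with ≤ 3
parallel edges per pair (200 graphs for the enumeration oracle), 100
random planted-path plans, 50 random co-mention plans and merge pairs, and
a 202-point score distribution for the percentile convention. Full-scale
runs on deposited curated tables (hundreds of thousands of edges) use the
same code paths via the CLI but require downloading those inputs.

## Known limitations

* Exact-depth enumeration is exponential in depth on dense graphs; depths
  beyond 4 on large merged graphs can be expensive. No pruning heuristics
  are applied (they would change the score distribution the percentile is
  taken over).
* Disambiguation considers every same-type lexicon entry per entity
  (O(entities × lexicon) similarity calls); at large scale a blocking index
  would be needed.
* The untyped/typed relationship-count duality means summary counts are
  only comparable when the convention is stated.
* Binary word2vec files are not read; convert to text format first.
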