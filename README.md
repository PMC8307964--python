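# kgpathrank

Typed biomedical knowledge-graph fusion and embedding-scored path ranking.

## The problem

Drug-repurposing and mechanism-hunting questions ("how is this gene
connected to this compound?") are increasingly asked of heterogeneous
knowledge graphs that fuse two very different evidence sources:

* **curated relation tables** from chemogenomic databases — typed edges
  such as `gene_disease`, `compound_gene`, `gene_gene` between genes,
  diseases, compounds, pathways, phenotypes (27 relation labels);
* **literature co-mentions** — two entities annotated in the same
  publication's title or abstract receive a `co_occur` edge whose weight is
  the number of supporting documents.

The two sources name entities inconsistently (`msg1` vs `cited1`,
`breast carcinoma` vs `breast cancer`), so fusing them needs entity
disambiguation against a synonym lexicon under a string-similarity
threshold, restricted to same-type candidates. Once merged, the graph is
interrogated with ego networks (a node's ≤ r-hop neighborhood) and a
path-ranking framework for hypothesis generation.

`kgpathrank` is a library (plus a thin CLI) for every step of that
pipeline, with a synthetic-fixture generator so the whole thing builds and
tests offline.

## The method

For a source s and target t, all **node-simple paths with exactly d
edges** (d ∈ {2, 3, 4} by convention; a depth-2 path has three nodes) are
enumerated under undirected traversal of the multigraph. Parallel edges
give distinct paths, so the same node sequence can appear once per label
combination. Each path n₀ — n₁ — … — n_d is scored with word-embedding
vectors v(·):

    S = Σᵢ₌₁..d cos(v(nᵢ₋₁), v(nᵢ)),        −d ≤ S ≤ d

Per depth, paths are sorted by S and the **top-ranked** set is every path
whose score strictly exceeds the nearest-rank 95th percentile of the score
multiset (the ⌈0.95·n⌉-th smallest score). The top set is summarized by
its distinct (node, relationship, node) triples, counted either typed
(label-sensitive) or as unordered node pairs.

Entity linking uses normalized Levenshtein similarity
`1 − dist(a,b)/max(|a|,|b|)` with threshold τ (default 0.95) and a hard
same-type constraint; entities that land on the same canonical term are
merged, `co_occur` weights summing and curated parallel edges all kept.

## Worked example

```python
from kgpathrank import (FixturePlan, PathQuery, PlantedPath,
                        make_synthetic_embeddings, make_synthetic_kg,
                        render_path_record, run_path_query)

plan = FixturePlan(
    seed=5,
    entity_counts={"gene": 10, "chemical": 4},
    edge_density={"co_occur": 0.25, "gene_gene": 0.1},
    planted_paths=(PlantedPath(
        nodes=(("stat1", "gene"), ("eif2ak2", "gene"),
               ("chloroquine", "chemical")),
        labels=("gene_gene", "co_occur"),
        step_cosines=(0.95, 0.92)),),
)
graph = make_synthetic_kg(plan)
store = make_synthetic_embeddings(sorted(e.name for e in graph.entities()),
                                  dim=24, plan=plan)
report = run_path_query(graph, store,
                        PathQuery(source="stat1", target="chloroquine",
                                  depths=(2, 3)))
best = report.depths[0].scored[0]
print(render_path_record(best.path), round(best.score, 6))
```

prints

```
stat1--gene_gene--eif2ak2--co_occur--chloroquine 1.87
```

the planted route: its score is the sum of the planted per-step cosines
0.95 + 0.92 = 1.87, the maximum over all depth-2 paths, so it ranks first.
The full report also carries per-depth path counts, the top-percentile
subset, distinct-relationship counts, and how many paths were dropped for
missing embeddings. See `examples/` for merging, ego networks, and the
bundled published case-study records (IL-6 receptor → hydroxychloroquine,
STAT1 → chloroquine).

## Command line

```bash
kgpathrank cooccur  --pubtator corpus.txt --out lit_edges.csv
kgpathrank merge    --ag ag_edges.csv --lit lit_edges.csv \
                    --lexicon lexicon.tsv --threshold 0.95 \
                    --out merged.csv --report merge_report.json
kgpathrank paths    --graph merged.csv --embeddings vectors.txt \
                    --source "il-6 receptor" --target hydroxychloroquine \
                    --depths 2,3,4 --percentile 95 --out report.json
kgpathrank ego      --graph merged.csv --center ace --radius 1 --out ego.graphml
kgpathrank fixtures --plan plan.yaml --out-dir fixtures/
kgpathrank convert  --edges merged.csv --out graph.graphml
```

## Layout

* `src/kgpathrank/model.py` — typed multigraph, degree, ego networks
* `src/kgpathrank/io.py` — edge tables, PubTator, word2vec text, GraphML,
  path records, lexicon files
* `src/kgpathrank/cooccur.py` — document-level co-occurrence extraction
* `src/kgpathrank/merge.py` — disambiguation and graph merging
* `src/kgpathrank/pathrank.py` — enumeration, scoring, percentile selection
* `src/kgpathrank/fixtures.py` — deterministic synthetic data generators
* `src/kgpathrank/datasets.py` — bundled published case-study records
* `src/kgpathrank/cli.py` — the `kgpathrank` command
* `docs/methods.md` — modeling choices, parameters, limitations
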