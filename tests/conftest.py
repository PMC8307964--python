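"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from kgpathrank import Edge, Entity, KnowledgeGraph, entity_key


def make_entity(name: str, etype: str = "gene") -> Entity:
    return Entity(entity_id=entity_key(name, etype), name=name, etype=etype)


def build_graph(entities, edges) -> KnowledgeGraph:
    """Graph from (name, etype) entities and (name_a, name_b, label) edges.

    Edge endpoints are given by name; the entity list must make them
    unambiguous.
    """
    g = KnowledgeGraph()
    by_name = {}
    for name, etype in entities:
        e = make_entity(name, etype)
        g.add_entity(e)
        by_name[name] = e.entity_id
    for a, b, label in edges:
        g.add_edge(Edge(head=by_name[a], tail=by_name[b], label=label))
    return g


def random_multigraph(rng: np.random.Generator, n_nodes: int,
                      n_edges: int, max_parallel: int = 3) -> KnowledgeGraph:
    """Random typed multigraph with up to ``max_parallel`` parallel edges."""
    labels = ["co_occur", "gene_gene", "gene_disease", "compound_gene"]
    g = KnowledgeGraph()
    names = [f"n{i}" for i in range(n_nodes)]
    for name in names:
        g.add_entity(make_entity(name))
    ids = [entity_key(name, "gene") for name in names]
    added = 0
    guard = 0
    while added < n_edges and guard < 50 * n_edges:
        guard += 1
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        a, b = ids[i], ids[j]
        if len(g.edges_between(a, b)) >= max_parallel:
            continue
        label = labels[int(rng.integers(0, len(labels)))]
        g.add_edge(Edge(head=a, tail=b, label=label))
        added += 1
    return g


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def bfs_hops(graph: KnowledgeGraph, start: str) -> dict[str, int]:
    """Shortest hop counts by hand-rolled BFS over distinct neighbors."""
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
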