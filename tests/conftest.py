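"""Shared fixtures: hand-built micro-graphs and random-graph generators."""

from __future__ import annotations

import numpy as np
import pytest

from microkg.model import Entity, HierarchyEdge, KnowledgeGraph, RelationEdge


def make_edge(m: str, d: str, w: float, n_papers: int = 1) -> RelationEdge:
    direction = "positive" if w > 0 else "negative" if w < 0 else "contested"
    return RelationEdge(
        microbe_id=m, disease_id=d, strength=w, n_papers=n_papers,
        direction=direction, evidence=(("P0", f"{m}-{d}", "positive"),),
    )


def make_graph(
    microbes: list[str],
    diseases: list[str],
    rel: list[tuple[str, str, float]] = (),
    hier: list[tuple[str, str, str]] = (),
) -> KnowledgeGraph:
    """Convenience constructor from terse edge tuples."""
    g = KnowledgeGraph()
    for m in microbes:
        g.add_entity(Entity(m, m, "microbe"))
    for d in diseases:
        g.add_entity(Entity(d, d, "disease"))
    for m, d, w in rel:
        g.add_relation_edge(make_edge(m, d, w))
    for p, c, kind in hier:
        g.add_hierarchy_edge(HierarchyEdge(p, c, kind))
    return g


def random_small_graph(rng: np.random.Generator, max_nodes: int = 10) -> KnowledgeGraph:
    """Random mixed graph (relation + hierarchy edges) for path oracles."""
    n_m = int(rng.integers(1, max_nodes // 2 + 1))
    n_d = int(rng.integers(1, max_nodes - n_m + 1))
    microbes = [f"m{i}" for i in range(n_m)]
    diseases = [f"d{i}" for i in range(n_d)]
    rel = [
        (m, d, float(rng.uniform(-3, 3)))
        for m in microbes for d in diseases
        if rng.random() < 0.35
    ]
    hier = []
    for ids, kind in ((microbes, "microbe"), (diseases, "disease")):
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):  # parent index < child: acyclic
                if rng.random() < 0.2:
                    hier.append((ids[i], ids[j], kind))
    return make_graph(microbes, diseases, rel, hier)


@pytest.fixture
def tiny_graph() -> KnowledgeGraph:
    """Two microbes (one under a genus), two diseases, two signed edges."""
    return make_graph(
        microbes=["gG", "mA", "mB"],
        diseases=["dX", "dY"],
        rel=[("mA", "dX", 1.0), ("gG", "dY", -2.0)],
        hier=[("gG", "mA", "microbe")],
    )
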