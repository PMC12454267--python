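"""Path discovery, graph embeddings, similarity, and clustering.

All traversal is undirected (edges encode association, not causation) and
spans both relation and hierarchy edges, so multi-hop routes such as
species -> genus -> disease are discoverable.  Two cost modes: ``hop``
(unit cost per edge) and ``inverse_strength`` (relation edges cost
1/(1+|w|), so strongly evidenced links are "shorter"; hierarchy edges stay
at unit cost).

Embeddings use FastRP: a sparse random sign projection followed by a
weighted sum of powers of the degree-normalized adjacency matrix.  FastRP
is deterministic given a seed, needs no training, and preserves the
neighborhood structure that similarity search and k-means clustering
consume.  Other embedding families (node2vec, metapath2vec, GNNs) can be
plugged in: any callable returning an :class:`EmbeddingSet` works
downstream.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Callable, Iterator, Literal, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from microkg.model import KnowledgeGraph

CostMode = Literal["hop", "inverse_strength"]


@dataclass(frozen=True)
class PathResult:
    """A path through the graph with its cost and per-step edge kinds."""

    nodes: tuple[str, ...]
    cost: float
    edge_kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.edge_kinds) != max(len(self.nodes) - 1, 0):
            raise ValueError("edge_kinds must have one entry per step")


@dataclass
class EmbeddingSet:
    """Fixed-dimension vectors for a set of entities.

    Deterministic function of (method, seed, params, graph); vectors are
    L2-normalized rows of ``vectors`` aligned with ``entity_ids``.
    """

    entity_ids: tuple[str, ...]
    vectors: np.ndarray
    method: str
    seed: int
    params: dict
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.entity_ids):
            raise ValueError("one vector per entity required")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding vectors must be finite")
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    def vector(self, entity_id: str) -> np.ndarray:
        try:
            return self.vectors[self._index[entity_id]]
        except KeyError:
            raise KeyError(f"entity {entity_id!r} not embedded") from None

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


# ---------------------------------------------------------------------------
# path discovery
# ---------------------------------------------------------------------------

def _edge_cost(mode: CostMode) -> Callable[[str, str, dict], float]:
    if mode == "hop":
        return lambda u, v, d: 1.0
    if mode == "inverse_strength":
        def cost(u: str, v: str, d: dict) -> float:
            if d.get("edge_type") == "relation":
                return 1.0 / (1.0 + abs(d.get("strength", 0.0)))
            return 1.0
        return cost
    raise ValueError(f"unknown cost mode {mode!r}")


def _path_result(g: nx.Graph, nodes: Sequence[str], mode: CostMode) -> PathResult:
    weight = _edge_cost(mode)
    cost = 0.0
    kinds = []
    for u, v in zip(nodes, nodes[1:]):
        d = g.edges[u, v]
        cost += weight(u, v, d)
        kinds.append(d.get("edge_type", "relation"))
    return PathResult(nodes=tuple(nodes), cost=cost, edge_kinds=tuple(kinds))


def shortest_path(
    graph: KnowledgeGraph,
    source: str,
    target: str,
    cost_mode: CostMode = "hop",
) -> PathResult | None:
    """Minimum-cost path between two entities, or None when disconnected.

    Dijkstra over the undirected view of relation + hierarchy edges.
    """
    graph.entity(source)
    graph.entity(target)
    g = graph.to_networkx()
    if source == target:
        return PathResult(nodes=(source,), cost=0.0, edge_kinds=())
    try:
        nodes = nx.dijkstra_path(g, source, target, weight=_edge_cost(cost_mode))
    except nx.NetworkXNoPath:
        return None
    return _path_result(g, nodes, cost_mode)


def alternative_paths(
    graph: KnowledgeGraph,
    source: str,
    target: str,
    k: int = 3,
    cost_mode: CostMode = "hop",
) -> list[PathResult]:
    """The k lowest-cost loopless paths, in (cost, lexicographic) order.

    Yen-style enumeration via :func:`networkx.shortest_simple_paths`;
    because that generator breaks cost ties arbitrarily, candidates are
    drained until the next path is strictly costlier than the k-th, then
    sorted deterministically by (cost, node sequence) and truncated to k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    graph.entity(source)
    graph.entity(target)
    g = graph.to_networkx()
    if source == target:
        return [PathResult(nodes=(source,), cost=0.0, edge_kinds=())]
    weight = _edge_cost(cost_mode)
    results: list[PathResult] = []
    try:
        gen = nx.shortest_simple_paths(g, source, target, weight=weight)
        for nodes in gen:
            pr = _path_result(g, nodes, cost_mode)
            if len(results) >= k and pr.cost > results[k - 1].cost + 1e-12:
                break
            results.append(pr)
    except nx.NetworkXNoPath:
        return []
    results.sort(key=lambda p: (p.cost, p.nodes))
    return results[:k]


# ---------------------------------------------------------------------------
# FastRP embeddings
# ---------------------------------------------------------------------------

def embed_graph(
    graph: KnowledgeGraph,
    dim: int = 128,
    seed: int = 0,
    iteration_weights: Sequence[float] = (0.0, 0.5, 1.0),
    normalization_exponent: float = -0.5,
) -> EmbeddingSet:
    """FastRP embedding of the full (relation + hierarchy) graph.

    Construction: a very sparse random projection matrix R (entries
    +-sqrt(s) with probability 1/(2s) each, zero otherwise, s = 3), then

        X = sum_i  w_i * M^i R,      M = D^e A D^e

    with A the unweighted undirected adjacency, D the degree matrix and
    e = ``normalization_exponent`` (symmetric normalization at the default
    -0.5).  ``iteration_weights[i-1]`` weights the i-th power, so the
    default (0, 0.5, 1) mixes 2- and 3-step neighborhoods.  Rows are
    L2-normalized; isolated nodes embed at the origin.  Bit-identical
    output for identical inputs and seed; node insertion order is
    irrelevant because nodes are processed in sorted-id order.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    ids = tuple(sorted(graph.entities))
    if not ids:
        raise ValueError("cannot embed an empty graph")
    g = graph.to_networkx()
    a = nx.to_scipy_sparse_array(g, nodelist=list(ids), weight=None, format="csr")
    a = a.astype(np.float64)

    deg = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        scale = np.where(deg > 0, deg ** normalization_exponent, 0.0)
    d_scale = sp.diags(scale)
    m = d_scale @ a @ d_scale

    rng = np.random.default_rng(seed)
    s = 3.0
    u = rng.random((len(ids), dim))
    r = np.zeros((len(ids), dim))
    r[u < 1 / (2 * s)] = np.sqrt(s)
    r[u > 1 - 1 / (2 * s)] = -np.sqrt(s)

    x = r
    out = np.zeros_like(r)
    for w in iteration_weights:
        x = m @ x
        if w != 0.0:
            out = out + w * x

    norms = np.linalg.norm(out, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    out = out / norms
    kinds = {eid: graph.entities[eid].kind for eid in ids}
    return EmbeddingSet(
        entity_ids=ids,
        vectors=out,
        method="fastrp",
        seed=seed,
        params={
            "dim": dim,
            "iteration_weights": tuple(iteration_weights),
            "normalization_exponent": normalization_exponent,
        },
        kinds=kinds,
    )


def top_similar(
    emb: EmbeddingSet,
    entity: str,
    k: int,
    same_kind_only: bool = True,
) -> list[tuple[str, float]]:
    """Top-k entities by cosine similarity to the query, query excluded.

    Restricted to the query's kind when ``same_kind_only``; cosine ties are
    broken lexicographically by entity id.
    """
    q = emb.vector(entity)
    qkind = emb.kinds[entity]
    scored: list[tuple[str, float]] = []
    for eid in emb.entity_ids:
        if eid == entity:
            continue
        if same_kind_only and emb.kinds[eid] != qkind:
            continue
        v = emb.vector(eid)
        denom = np.linalg.norm(q) * np.linalg.norm(v)
        cos = float(q @ v / denom) if denom > 0 else 0.0
        scored.append((eid, cos))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


def cluster_entities(
    emb: EmbeddingSet,
    k: int,
    seed: int = 0,
    restarts: int = 10,
) -> dict[str, int]:
    """k-means over the embedding vectors; deterministic given the seed.

    k-means++ initialization, best of ``restarts`` runs by within-cluster
    sum of squares.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(emb.entity_ids):
        raise ValueError("k exceeds the number of embedded entities")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(emb.vectors)
    return {eid: int(lab) for eid, lab in zip(emb.entity_ids, labels)}


def export_embeddings_tsv(emb: EmbeddingSet, path: str) -> None:
    """Write entity_id + one column per dimension, tab-separated."""
    import pandas as pd

    df = pd.DataFrame(emb.vectors, index=list(emb.entity_ids))
    df.index.name = "entity_id"
    df.columns = [f"dim_{i}" for i in range(emb.dim)]
    df.to_csv(path, sep="\t")
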