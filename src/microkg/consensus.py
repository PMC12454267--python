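"""Evidence consolidation: from sentence-level labels to weighted edges.

Three-step pipeline, precision over coverage at every step:

1. **Self-consistency filter** -- a sentence-level record survives only if
   every one of its repeated label samples agrees; anything short of
   unanimity is discarded.
2. **Within-paper majority vote** -- for each (paper, microbe, disease)
   group the modal label wins; groups whose winner is *unrelated* are
   dropped, as are exact ties under the default policy.
3. **Cross-paper aggregation** -- each paper contributes a signed strength
   r = sign * log10(F), with F the journal impact factor (clamped below at
   ``impact_floor`` so no paper contributes negative magnitude), and the
   edge strength is w = sum of r over papers.  w > 0 gives a positive edge,
   w < 0 negative, and exact cancellation a *contested* edge.

Hierarchical enrichment attaches taxonomy/nosology parent-child edges, and
:func:`infer_hierarchical_relations` answers relation queries by matching
entities up to one parent/child step away without ever materializing
inferred edges (inferred != asserted).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from microkg.model import (
    Entity,
    ExtractionRecord,
    GraphIntegrityError,
    HierarchyEdge,
    KnowledgeGraph,
    Label,
    PaperMeta,
    PaperRelation,
    RelationEdge,
)

HopKind = Literal[
    "microbe_parent", "microbe_child", "disease_parent", "disease_child"
]


@dataclass(frozen=True)
class ConsensusConfig:
    """Operational parameters of the consolidation pipeline.

    min_samples
        Minimum number of label samples a record needs to be eligible for
        the unanimity check (default 3 repeated samples).
    tie_policy
        How to resolve an exact within-paper voting tie: ``discard`` drops
        the pair for that paper; ``prefer_none`` resolves the tie to
        *unrelated* when unrelated is among the tied labels (the pair is
        then dropped by the positive/negative-only rule) and otherwise
        discards.  Either way no direction is asserted from a tie.
    impact_floor
        Impact factors are clamped below at this value so log10 never goes
        negative and no paper subtracts evidence merely by venue.
    default_impact
        Impact factor assumed for papers missing from the metadata table.
    keep_contested
        Whether edges whose strengths cancel exactly (w = 0) are kept,
        flagged as contested, or dropped.
    """

    min_samples: int = 3
    tie_policy: Literal["discard", "prefer_none"] = "discard"
    impact_floor: float = 1.0
    default_impact: float = 2.0
    keep_contested: bool = True

    def __post_init__(self) -> None:
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.impact_floor < 1:
            raise ValueError("impact_floor must be >= 1")
        if self.tie_policy not in ("discard", "prefer_none"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")


@dataclass(frozen=True)
class InferredRelation:
    """A relation reached by at most one hierarchy hop from the query pair.

    Query-time only: inferred relations are never written back into the
    graph.  ``hops = 0`` means the source edge matches the query directly
    (``via_entity_id`` and ``hop_kind`` are then None).
    """

    microbe_id: str
    disease_id: str
    via_entity_id: str | None
    hop_kind: HopKind | None
    source_edge: RelationEdge
    hops: int = 1


# ---------------------------------------------------------------------------
# step A: self-consistency
# ---------------------------------------------------------------------------

def filter_self_consistency(
    records: Iterable[ExtractionRecord],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> list[tuple[ExtractionRecord, Label]]:
    """Keep only records whose repeated label samples are unanimous.

    Records with fewer than ``cfg.min_samples`` samples are discarded with a
    warning (they never met the sampling protocol); records with any
    disagreement among samples are silently dropped.  Returns the surviving
    records paired with their consensus label.
    """
    kept: list[tuple[ExtractionRecord, Label]] = []
    n_short = 0
    for rec in records:
        if len(rec.label_samples) < cfg.min_samples:
            n_short += 1
            continue
        first = rec.label_samples[0]
        if all(lab == first for lab in rec.label_samples):
            kept.append((rec, first))
    if n_short:
        warnings.warn(
            f"discarded {n_short} record(s) with fewer than "
            f"{cfg.min_samples} label samples",
            stacklevel=2,
        )
    return kept


# ---------------------------------------------------------------------------
# step B: within-paper majority vote
# ---------------------------------------------------------------------------

def vote_within_paper(
    labelled: Iterable[tuple[ExtractionRecord, Label]],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> list[PaperRelation]:
    """Resolve each (paper, microbe, disease) group by majority vote.

    The modal label across the paper's sentences wins; groups whose winner
    is *unrelated* are dropped (only directional relations are retained),
    and exact ties are handled per ``cfg.tie_policy``.  The returned
    relations carry zero strength (strength is assigned later from paper
    metadata) and the full list of contributing (paper, sentence, label)
    evidence for the group.
    """
    groups: dict[tuple[str, str, str], list[tuple[ExtractionRecord, Label]]] = (
        defaultdict(list)
    )
    for rec, lab in labelled:
        groups[(rec.paper_id, rec.microbe_id, rec.disease_id)].append((rec, lab))

    out: list[PaperRelation] = []
    for key in sorted(groups):
        paper_id, microbe_id, disease_id = key
        members = groups[key]
        counts = Counter(lab for _, lab in members)
        top = max(counts.values())
        winners = sorted(lab for lab, c in counts.items() if c == top)
        if len(winners) == 1:
            winner = winners[0]
        elif cfg.tie_policy == "prefer_none" and "unrelated" in winners:
            winner = "unrelated"
        else:
            continue  # tie discarded: no direction asserted
        if winner == "unrelated":
            continue
        evidence = tuple(sorted(
            (rec.paper_id, rec.sentence_id, lab) for rec, lab in members
        ))
        out.append(PaperRelation(
            paper_id=paper_id,
            microbe_id=microbe_id,
            disease_id=disease_id,
            label=winner,
            strength=0.0,
            evidence=evidence,
        ))
    return out


# ---------------------------------------------------------------------------
# step C: strength and cross-paper aggregation
# ---------------------------------------------------------------------------

def paper_relation_strength(
    label: Literal["positive", "negative"],
    paper: PaperMeta | None,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> float:
    """Signed per-paper strength r = sign * log10(max(F, impact_floor)).

    sign is +1 for a positive label, -1 for negative.  F is the paper's
    journal impact factor, or ``cfg.default_impact`` when no metadata is
    available; F is clamped below at ``cfg.impact_floor`` so the magnitude
    is never negative.
    """
    if label not in ("positive", "negative"):
        raise ValueError("label must be positive or negative")
    f = paper.impact_factor if paper is not None else cfg.default_impact
    sign = 1.0 if label == "positive" else -1.0
    return sign * math.log10(max(f, cfg.impact_floor))


def aggregate_cross_paper(
    relations: Iterable[PaperRelation],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> list[RelationEdge]:
    """Sum per-paper strengths into one edge per (microbe, disease) pair.

    w = sum_k r_k over contributing papers; direction follows sign(w), with
    w = 0 kept as a contested edge iff ``cfg.keep_contested``.  Duplicate
    (paper, pair) inputs are an error -- the within-paper vote guarantees at
    most one relation per paper per pair.
    """
    seen: set[tuple[str, str, str]] = set()
    by_pair: dict[tuple[str, str], list[PaperRelation]] = defaultdict(list)
    for rel in relations:
        key = (rel.paper_id, rel.microbe_id, rel.disease_id)
        if key in seen:
            raise ValueError(f"duplicate paper relation for {key}")
        seen.add(key)
        by_pair[(rel.microbe_id, rel.disease_id)].append(rel)

    edges: list[RelationEdge] = []
    for pair in sorted(by_pair):
        rels = by_pair[pair]
        w = sum(r.strength for r in rels)
        if w > 0:
            direction = "positive"
        elif w < 0:
            direction = "negative"
        else:
            if not cfg.keep_contested:
                continue
            direction = "contested"
        evidence = tuple(sorted(ev for r in rels for ev in r.evidence))
        edges.append(RelationEdge(
            microbe_id=pair[0], disease_id=pair[1],
            strength=w, n_papers=len(rels),
            direction=direction, evidence=evidence,
        ))
    return edges


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def build_graph(
    records: Iterable[ExtractionRecord],
    meta: Mapping[str, PaperMeta],
    hierarchy_edges: Iterable[HierarchyEdge],
    entities: Iterable[Entity],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> KnowledgeGraph:
    """Compose filter -> vote -> strength -> aggregate, then attach hierarchy.

    All supplied entities become nodes, including hierarchy parents that
    carry no relation edge.  Records referencing unknown entities, or
    hierarchy edges with mismatched endpoint kinds, raise
    :class:`GraphIntegrityError`.
    """
    graph = KnowledgeGraph(entities=entities)

    labelled = filter_self_consistency(records, cfg)
    voted = vote_within_paper(labelled, cfg)
    with_strength = [
        PaperRelation(
            paper_id=r.paper_id, microbe_id=r.microbe_id,
            disease_id=r.disease_id, label=r.label,
            strength=paper_relation_strength(r.label, meta.get(r.paper_id), cfg),
            evidence=r.evidence,
        )
        for r in voted
    ]
    for edge in aggregate_cross_paper(with_strength, cfg):
        graph.add_relation_edge(edge)
    for h in hierarchy_edges:
        graph.add_hierarchy_edge(h)
    return graph


# ---------------------------------------------------------------------------
# hierarchical inference
# ---------------------------------------------------------------------------

def _hierarchy_neighborhood(
    graph: KnowledgeGraph, entity_id: str, max_hops: int
) -> dict[str, int]:
    """Entities within ``max_hops`` parent/child steps, with hop distance."""
    dist = {entity_id: 0}
    frontier = [entity_id]
    for hop in range(1, max_hops + 1):
        nxt = []
        for eid in frontier:
            for nb in graph.parents_of(eid) + graph.children_of(eid):
                if nb not in dist:
                    dist[nb] = hop
                    nxt.append(nb)
        frontier = nxt
    return dist


def _classify_hop(
    graph: KnowledgeGraph, query_id: str, via_id: str, side: Literal["microbe", "disease"]
) -> HopKind:
    if via_id in graph.parents_of(query_id):
        return f"{side}_parent"  # type: ignore[return-value]
    return f"{side}_child"  # type: ignore[return-value]


def infer_hierarchical_relations(
    graph: KnowledgeGraph,
    microbe_id: str,
    disease_id: str,
    max_hops: int = 1,
) -> list[InferredRelation]:
    """Answer a relation query allowing one endpoint to move in its hierarchy.

    Returns every relation edge whose pair matches the query after replacing
    *either* the microbe or the disease (never both) by an entity at most
    ``max_hops`` parent/child steps away.  A direct edge is reported with
    hop count 0.  The graph is never mutated; results are query-time
    inferences, not asserted edges.
    """
    graph.entity(microbe_id)
    graph.entity(disease_id)
    results: list[InferredRelation] = []

    direct = graph.get_relation(microbe_id, disease_id)
    if direct is not None:
        results.append(InferredRelation(
            microbe_id=microbe_id, disease_id=disease_id,
            via_entity_id=None, hop_kind=None, source_edge=direct, hops=0,
        ))

    for m_alt, hops in sorted(
        _hierarchy_neighborhood(graph, microbe_id, max_hops).items()
    ):
        if m_alt == microbe_id:
            continue
        edge = graph.get_relation(m_alt, disease_id)
        if edge is not None:
            kind = _classify_hop(graph, microbe_id, m_alt, "microbe") if hops == 1 else None
            results.append(InferredRelation(
                microbe_id=microbe_id, disease_id=disease_id,
                via_entity_id=m_alt, hop_kind=kind, source_edge=edge, hops=hops,
            ))
    for d_alt, hops in sorted(
        _hierarchy_neighborhood(graph, disease_id, max_hops).items()
    ):
        if d_alt == disease_id:
            continue
        edge = graph.get_relation(microbe_id, d_alt)
        if edge is not None:
            kind = _classify_hop(graph, disease_id, d_alt, "disease") if hops == 1 else None
            results.append(InferredRelation(
                microbe_id=microbe_id, disease_id=disease_id,
                via_entity_id=d_alt, hop_kind=kind, source_edge=edge, hops=hops,
            ))
    return results
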