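"""Core domain types and file I/O for the knowledge-graph pipeline.

The central object is the :class:`KnowledgeGraph`: a bipartite set of signed
microbe-disease relation edges plus intra-kind hierarchy (parent/child)
edges for taxonomy and disease nosology.  Upstream of the graph sit
sentence-level :class:`ExtractionRecord` objects -- one microbe-disease
mention per sentence, with the repeated label samples produced by a
self-consistency extraction protocol -- and per-paper metadata carrying the
journal impact factor used for evidence weighting.

File formats: JSON Lines for extraction records, TSV for paper metadata and
hierarchy edge lists, GraphML (faithful round-trip) or edge TSV (lossy for
node metadata) for graphs, and a taxa-by-samples TSV for abundance tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

LABELS = ("positive", "negative", "unrelated")
Kind = Literal["microbe", "disease"]
Label = Literal["positive", "negative", "unrelated"]
Direction = Literal["positive", "negative", "contested"]


class GraphIntegrityError(ValueError):
    """Raised when an operation would violate a knowledge-graph invariant."""


class MalformedRecordError(ValueError):
    """Raised (in strict mode) when an input line cannot be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Entity:
    """A microbe or disease node with an opaque, CUI-like identifier."""

    entity_id: str
    name: str
    kind: Kind
    level: str | None = None

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValueError("entity_id must be non-empty")
        if self.kind not in ("microbe", "disease"):
            raise ValueError(f"unknown entity kind {self.kind!r}")


@dataclass(frozen=True)
class ExtractionRecord:
    """One sentence-level microbe-disease mention with repeated label samples.

    ``label_samples`` holds the labels returned by repeatedly sampling the
    extraction model for the same sentence; unanimity across samples is what
    the downstream self-consistency filter checks.
    """

    paper_id: str
    sentence_id: str
    microbe_id: str
    disease_id: str
    label_samples: tuple[Label, ...]

    def __post_init__(self) -> None:
        if not self.label_samples:
            raise ValueError("label_samples must be non-empty")
        if self.microbe_id == self.disease_id:
            raise ValueError("microbe_id and disease_id must differ")
        for lab in self.label_samples:
            if lab not in LABELS:
                raise ValueError(f"unknown label {lab!r}")
        object.__setattr__(self, "label_samples", tuple(self.label_samples))


@dataclass(frozen=True)
class PaperMeta:
    """Journal metadata for one paper; the impact factor weights its evidence."""

    paper_id: str
    impact_factor: float
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.impact_factor > 0:
            raise ValueError("impact_factor must be > 0")


@dataclass(frozen=True)
class PaperRelation:
    """Per-paper consolidated label for one pair, with signed strength r.

    ``strength`` is sign * log10(F) after impact-factor clamping: positive
    labels carry +|r|, negative labels -|r|.
    """

    paper_id: str
    microbe_id: str
    disease_id: str
    label: Literal["positive", "negative"]
    strength: float
    evidence: tuple[tuple[str, str, str], ...] = ()  # (paper, sentence, label)

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError("label must be positive or negative")
        sign = 1.0 if self.label == "positive" else -1.0
        if self.strength != 0 and np.sign(self.strength) != sign:
            raise ValueError("strength sign inconsistent with label")


@dataclass(frozen=True)
class RelationEdge:
    """Aggregated microbe-disease edge: strength w summed across papers.

    ``direction`` follows the sign of ``strength``; exact cancellation across
    papers yields a *contested* edge whose evidence is preserved but whose
    direction is not asserted.
    """

    microbe_id: str
    disease_id: str
    strength: float
    n_papers: int
    direction: Direction
    evidence: tuple[tuple[str, str, str], ...]  # (paper_id, sentence_id, label)

    def __post_init__(self) -> None:
        if self.n_papers < 1:
            raise ValueError("n_papers must be positive")
        if not self.evidence:
            raise ValueError("relation edge must carry evidence")
        expect = (
            "positive" if self.strength > 0
            else "negative" if self.strength < 0
            else "contested"
        )
        if self.direction != expect:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with strength {self.strength}"
            )


@dataclass(frozen=True)
class HierarchyEdge:
    """A parent -> child edge inside one kind's hierarchy (taxonomy/nosology)."""

    parent_id: str
    child_id: str
    kind: Kind

    def __post_init__(self) -> None:
        if self.parent_id == self.child_id:
            raise ValueError("hierarchy edge cannot be a self-loop")
        if self.kind not in ("microbe", "disease"):
            raise ValueError(f"unknown kind {self.kind!r}")


class KnowledgeGraph:
    """Bipartite relation edges plus intra-kind hierarchy edges.

    Invariants enforced at mutation time: every relation edge links a microbe
    to a disease; at most one relation edge per (microbe, disease) pair; all
    edge endpoints are registered entities; hierarchy edges connect entities
    of one kind and the hierarchy stays acyclic.
    """

    def __init__(
        self,
        entities: Iterable[Entity] = (),
        relation_edges: Iterable[RelationEdge] = (),
        hierarchy_edges: Iterable[HierarchyEdge] = (),
    ) -> None:
        self._entities: dict[str, Entity] = {}
        self._relations: dict[tuple[str, str], RelationEdge] = {}
        self._hierarchy: dict[tuple[str, str], HierarchyEdge] = {}
        for e in entities:
            self.add_entity(e)
        for r in relation_edges:
            self.add_relation_edge(r)
        for h in hierarchy_edges:
            self.add_hierarchy_edge(h)

    # -- mutation -----------------------------------------------------------
    def add_entity(self, entity: Entity) -> None:
        prior = self._entities.get(entity.entity_id)
        if prior is not None and prior != entity:
            raise GraphIntegrityError(
                f"conflicting redefinition of entity {entity.entity_id!r}"
            )
        self._entities[entity.entity_id] = entity

    def add_relation_edge(self, edge: RelationEdge) -> None:
        m = self._entities.get(edge.microbe_id)
        d = self._entities.get(edge.disease_id)
        if m is None or d is None:
            raise GraphIntegrityError(
                f"relation edge endpoints {edge.microbe_id!r}/{edge.disease_id!r} "
                "must be registered entities"
            )
        if m.kind != "microbe" or d.kind != "disease":
            raise GraphIntegrityError(
                "relation edges must link a microbe to a disease "
                f"(got {m.kind} -> {d.kind})"
            )
        key = (edge.microbe_id, edge.disease_id)
        if key in self._relations:
            raise GraphIntegrityError(f"duplicate relation edge for pair {key}")
        self._relations[key] = edge

    def add_hierarchy_edge(self, edge: HierarchyEdge) -> None:
        p = self._entities.get(edge.parent_id)
        c = self._entities.get(edge.child_id)
        if p is None or c is None:
            raise GraphIntegrityError(
                f"hierarchy edge endpoints {edge.parent_id!r}/{edge.child_id!r} "
                "must be registered entities"
            )
        if p.kind != edge.kind or c.kind != edge.kind:
            raise GraphIntegrityError(
                f"hierarchy edge kind {edge.kind!r} does not match endpoint kinds"
            )
        key = (edge.parent_id, edge.child_id)
        if key in self._hierarchy:
            return
        self._hierarchy[key] = edge
        if self._hierarchy_has_cycle():
            del self._hierarchy[key]
            raise GraphIntegrityError(
                f"hierarchy edge {edge.parent_id!r}->{edge.child_id!r} creates a cycle"
            )

    def _hierarchy_has_cycle(self) -> bool:
        dag = nx.DiGraph()
        dag.add_edges_from(self._hierarchy)
        return not nx.is_directed_acyclic_graph(dag)

    # -- access -------------------------------------------------------------
    @property
    def entities(self) -> Mapping[str, Entity]:
        return dict(self._entities)

    @property
    def relation_edges(self) -> tuple[RelationEdge, ...]:
        return tuple(self._relations[k] for k in sorted(self._relations))

    @property
    def hierarchy_edges(self) -> tuple[HierarchyEdge, ...]:
        return tuple(self._hierarchy[k] for k in sorted(self._hierarchy))

    def entity(self, entity_id: str) -> Entity:
        try:
            return self._entities[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity {entity_id!r}") from None

    def has_relation(self, microbe_id: str, disease_id: str) -> bool:
        return (microbe_id, disease_id) in self._relations

    def get_relation(self, microbe_id: str, disease_id: str) -> RelationEdge | None:
        return self._relations.get((microbe_id, disease_id))

    def relations_of(self, entity_id: str) -> tuple[RelationEdge, ...]:
        """All relation edges incident to one entity, in sorted pair order."""
        self.entity(entity_id)
        return tuple(
            e for e in self.relation_edges
            if entity_id in (e.microbe_id, e.disease_id)
        )

    def parents_of(self, entity_id: str) -> tuple[str, ...]:
        return tuple(sorted(
            h.parent_id for h in self._hierarchy.values() if h.child_id == entity_id
        ))

    def children_of(self, entity_id: str) -> tuple[str, ...]:
        return tuple(sorted(
            h.child_id for h in self._hierarchy.values() if h.parent_id == entity_id
        ))

    def microbes(self) -> tuple[str, ...]:
        return tuple(sorted(
            i for i, e in self._entities.items() if e.kind == "microbe"
        ))

    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted(
            i for i, e in self._entities.items() if e.kind == "disease"
        ))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            self._entities == other._entities
            and self._relations == other._relations
            and self._hierarchy == other._hierarchy
        )

    def __repr__(self) -> str:
        return (
            f"KnowledgeGraph(entities={len(self._entities)}, "
            f"relations={len(self._relations)}, hierarchy={len(self._hierarchy)})"
        )

    def to_networkx(self) -> nx.Graph:
        """Undirected analytics view: relation + hierarchy edges on one graph.

        Relation and hierarchy edges can never collide on the same node pair
        (cross-kind vs same-kind), so a plain ``nx.Graph`` suffices.
        """
        g = nx.Graph()
        for eid in sorted(self._entities):
            e = self._entities[eid]
            g.add_node(eid, name=e.name, kind=e.kind)
        for edge in self.relation_edges:
            g.add_edge(
                edge.microbe_id, edge.disease_id,
                edge_type="relation", strength=edge.strength,
                n_papers=edge.n_papers, direction=edge.direction,
            )
        for h in self.hierarchy_edges:
            g.add_edge(h.parent_id, h.child_id, edge_type="hierarchy")
        return g


# ---------------------------------------------------------------------------
# extraction-record JSONL I/O
# ---------------------------------------------------------------------------

def _parse_record_line(obj: dict) -> ExtractionRecord:
    samples = obj["label_samples"]
    if not isinstance(samples, list) or not samples:
        raise MalformedRecordError("label_samples must be a non-empty list")
    return ExtractionRecord(
        paper_id=str(obj["paper_id"]),
        sentence_id=str(obj["sentence_id"]),
        microbe_id=str(obj["microbe_id"]),
        disease_id=str(obj["disease_id"]),
        label_samples=tuple(samples),
    )


def read_extraction_records(
    path: str | Path, strict: bool = True
) -> list[ExtractionRecord]:
    """Read sentence-level extraction records from a JSON Lines file.

    In strict mode any malformed line raises :class:`MalformedRecordError`;
    otherwise malformed lines are skipped with a single summary warning.
    """
    path = Path(path)
    records: list[ExtractionRecord] = []
    n_bad = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(_parse_record_line(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
                if strict:
                    raise MalformedRecordError(
                        f"{path}:{lineno}: {exc}"
                    ) from exc
                n_bad += 1
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed line(s) in {path}", stacklevel=2)
    return records


def write_extraction_records(
    records: Iterable[ExtractionRecord], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps({
                "paper_id": r.paper_id,
                "sentence_id": r.sentence_id,
                "microbe_id": r.microbe_id,
                "disease_id": r.disease_id,
                "label_samples": list(r.label_samples),
            }) + "\n")


# ---------------------------------------------------------------------------
# paper-metadata TSV I/O
# ---------------------------------------------------------------------------

def read_paper_meta(path: str | Path) -> dict[str, PaperMeta]:
    """Read paper metadata (impact factors) from a headered TSV.

    Duplicate ``paper_id`` rows and non-positive impact factors are errors:
    clamping of small impact factors happens later, at strength computation,
    so F must still parse as a positive real here.
    """
    df = pd.read_csv(path, sep="\t", dtype={"paper_id": str},
                     float_precision="round_trip")
    required = {"paper_id", "impact_factor"}
    if not required.issubset(df.columns):
        raise ValueError(f"paper-meta TSV must have columns {sorted(required)}")
    if df["paper_id"].duplicated().any():
        dups = df.loc[df["paper_id"].duplicated(), "paper_id"].tolist()
        raise ValueError(f"duplicate paper_id rows: {dups}")
    out: dict[str, PaperMeta] = {}
    for row in df.itertuples(index=False):
        year = None
        if "year" in df.columns and pd.notna(getattr(row, "year", None)):
            year = int(row.year)
        out[row.paper_id] = PaperMeta(
            paper_id=row.paper_id,
            impact_factor=float(row.impact_factor),
            year=year,
        )
    return out


def write_paper_meta(meta: Mapping[str, PaperMeta], path: str | Path) -> None:
    rows = []
    for pid in sorted(meta):
        m = meta[pid]
        rows.append({
            "paper_id": m.paper_id,
            "impact_factor": m.impact_factor,
            "year": "" if m.year is None else m.year,
        })
    pd.DataFrame(rows, columns=["paper_id", "impact_factor", "year"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# entity TSV I/O
# ---------------------------------------------------------------------------

def read_entities(path: str | Path) -> list[Entity]:
    """Read entities from a TSV (columns entity_id, name, kind[, level])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"entity_id", "name", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"entity TSV must have columns {sorted(required)}")
    out = []
    for r in df.itertuples(index=False):
        level = getattr(r, "level", None)
        if level is not None and pd.isna(level):
            level = None
        out.append(Entity(r.entity_id, r.name, r.kind, level=level))
    return out


def write_entities(entities: Iterable[Entity], path: str | Path) -> None:
    rows = [
        {"entity_id": e.entity_id, "name": e.name, "kind": e.kind,
         "level": "" if e.level is None else e.level}
        for e in sorted(entities, key=lambda e: e.entity_id)
    ]
    pd.DataFrame(rows, columns=["entity_id", "name", "kind", "level"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# hierarchy TSV I/O
# ---------------------------------------------------------------------------

def read_hierarchy_edges(path: str | Path) -> list[HierarchyEdge]:
    """Read parent->child edges from a TSV (columns parent_id, child_id, kind).

    The combined edge list must be acyclic; a cyclic input is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"parent_id", "child_id", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"hierarchy TSV must have columns {sorted(required)}")
    edges = [
        HierarchyEdge(parent_id=r.parent_id, child_id=r.child_id, kind=r.kind)
        for r in df.itertuples(index=False)
    ]
    dag = nx.DiGraph()
    dag.add_edges_from((e.parent_id, e.child_id) for e in edges)
    if not nx.is_directed_acyclic_graph(dag):
        raise GraphIntegrityError(f"hierarchy edge list in {path} contains a cycle")
    return edges


def write_hierarchy_edges(edges: Iterable[HierarchyEdge], path: str | Path) -> None:
    rows = [
        {"parent_id": e.parent_id, "child_id": e.child_id, "kind": e.kind}
        for e in sorted(edges, key=lambda e: (e.parent_id, e.child_id))
    ]
    pd.DataFrame(rows, columns=["parent_id", "child_id", "kind"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# graph export / import
# ---------------------------------------------------------------------------

def _graph_to_digraph(graph: KnowledgeGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    for eid in sorted(graph.entities):
        e = graph.entities[eid]
        attrs = {"name": e.name, "kind": e.kind}
        if e.level is not None:
            attrs["level"] = e.level
        g.add_node(eid, **attrs)
    for edge in graph.relation_edges:
        g.add_edge(
            edge.microbe_id, edge.disease_id,
            edge_type="relation",
            strength=float(edge.strength),
            n_papers=int(edge.n_papers),
            direction=edge.direction,
            evidence=json.dumps([list(t) for t in edge.evidence]),
        )
    for h in graph.hierarchy_edges:
        g.add_edge(h.parent_id, h.child_id, edge_type="hierarchy", kind=h.kind)
    return g


def write_graph(
    graph: KnowledgeGraph,
    path: str | Path,
    format: Literal["graphml", "edge_tsv"] = "graphml",
) -> None:
    """Export a knowledge graph.

    ``graphml`` is the faithful format: node attributes (name, kind, level)
    and edge attributes (strength, n_papers, direction, evidence, edge_type)
    round-trip exactly through :func:`read_graph`.  ``edge_tsv`` writes one
    edge per row with the same columns; it is lossy for node display names
    and for isolated nodes.
    """
    if format == "graphml":
        nx.write_graphml(_graph_to_digraph(graph), str(path))
    elif format == "edge_tsv":
        rows = []
        for e in graph.relation_edges:
            rows.append({
                "source": e.microbe_id, "target": e.disease_id,
                "edge_type": "relation", "kind": "",
                "strength": e.strength, "n_papers": e.n_papers,
                "direction": e.direction,
                "evidence": json.dumps([list(t) for t in e.evidence]),
            })
        for h in graph.hierarchy_edges:
            rows.append({
                "source": h.parent_id, "target": h.child_id,
                "edge_type": "hierarchy", "kind": h.kind,
                "strength": "", "n_papers": "", "direction": "", "evidence": "",
            })
        cols = ["source", "target", "edge_type", "kind",
                "strength", "n_papers", "direction", "evidence"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graph(
    path: str | Path, format: Literal["graphml", "edge_tsv"] = "graphml"
) -> KnowledgeGraph:
    """Import a knowledge graph written by :func:`write_graph`."""
    if format == "graphml":
        g = nx.read_graphml(str(path))
        kg = KnowledgeGraph()
        for nid, attrs in g.nodes(data=True):
            kg.add_entity(Entity(
                entity_id=str(nid),
                name=attrs.get("name", str(nid)),
                kind=attrs["kind"],
                level=attrs.get("level"),
            ))
        for u, v, attrs in g.edges(data=True):
            if attrs["edge_type"] == "relation":
                kg.add_relation_edge(RelationEdge(
                    microbe_id=str(u), disease_id=str(v),
                    strength=float(attrs["strength"]),
                    n_papers=int(attrs["n_papers"]),
                    direction=attrs["direction"],
                    evidence=tuple(
                        tuple(t) for t in json.loads(attrs.get("evidence", "[]"))
                    ),
                ))
            else:
                kg.add_hierarchy_edge(HierarchyEdge(
                    parent_id=str(u), child_id=str(v), kind=attrs["kind"],
                ))
        return kg
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str},
                         float_precision="round_trip")
        kg = KnowledgeGraph()
        for r in df.itertuples(index=False):  # first pass: entities
            if r.edge_type == "relation":
                kg.add_entity(Entity(r.source, r.source, "microbe"))
                kg.add_entity(Entity(r.target, r.target, "disease"))
            else:
                kg.add_entity(Entity(r.source, r.source, r.kind))
                kg.add_entity(Entity(r.target, r.target, r.kind))
        for r in df.itertuples(index=False):
            if r.edge_type == "relation":
                kg.add_relation_edge(RelationEdge(
                    microbe_id=r.source, disease_id=r.target,
                    strength=float(r.strength), n_papers=int(r.n_papers),
                    direction=r.direction,
                    evidence=tuple(tuple(t) for t in json.loads(r.evidence)),
                ))
            else:
                kg.add_hierarchy_edge(
                    HierarchyEdge(parent_id=r.source, child_id=r.target, kind=r.kind)
                )
        return kg
    raise ValueError(f"unknown graph format {format!r}")


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

class AbundanceTable:
    """Samples x taxa relative-abundance matrix.

    Values are nonnegative; :meth:`normalize` scales every sample (row) to
    sum to one.  The on-disk dialect is a TSV whose first column is
    ``taxon_id`` and whose remaining columns are one per sample (taxa as
    rows, matching common repository exports); in memory the orientation is
    samples x taxa.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        if (data.values < 0).any():
            raise ValueError("abundance values must be nonnegative")
        self.data = data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample(self, sample_id: str) -> pd.Series:
        return self.data.loc[sample_id]

    def is_normalized(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.data.sum(axis=1), 1.0, atol=tol))

    def normalize(self) -> "AbundanceTable":
        """Divide each sample by its total; idempotent; rejects all-zero samples."""
        totals = self.data.sum(axis=1)
        zero = totals[totals == 0]
        if len(zero):
            raise ValueError(f"all-zero sample(s): {list(zero.index)}")
        if self.is_normalized():  # exact idempotence: avoid re-dividing by 1 +- ulp
            return AbundanceTable(self.data)
        return AbundanceTable(self.data.div(totals, axis=0))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df.T)  # file is taxa x samples

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.T
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"AbundanceTable(samples={len(self.sample_ids)}, taxa={len(self.taxon_ids)})"
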