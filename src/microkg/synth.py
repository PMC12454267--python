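"""Seeded generators emulating the upstream extraction stage and cohorts.

Every generator is a pure function of its spec (seed included), so tests
and end-to-end runs never need external downloads.  What they emulate:

* :func:`gen_extraction_corpus` -- the output contract of a sentence-level
  relation-extraction stage: per-sentence records with repeated label
  samples, corrupted by a within-record *disagreement* rate (a sample is
  replaced by a uniform draw over the three classes) and a whole-paper
  *contradiction* rate (a paper's stance opposes the planted direction).
  Journal impact factors are uniform in a configurable range.
* :func:`gen_cohort` -- control samples from a shared log-normal
  compositional baseline with multiplicative noise, plus target samples
  shifted on planted taxa by stated effect sizes.  The generator refuses
  effect sizes too small to clear the quantile band at the stated noise,
  rather than emitting an untestable fixture.
* :func:`gen_planted_bipartite` -- a bipartite stochastic-block graph with
  positive edge strengths, for link-prediction evaluation with known
  community ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from microkg.model import (
    AbundanceTable,
    Entity,
    ExtractionRecord,
    HierarchyEdge,
    KnowledgeGraph,
    PaperMeta,
    RelationEdge,
)

LABELS = ("positive", "negative", "unrelated")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a planted extraction corpus."""

    n_papers: int = 40
    n_microbes: int = 15
    n_diseases: int = 8
    true_edges: tuple[tuple[str, str, str], ...] | None = None  # (m, d, direction)
    n_true_edges: int = 20
    mentions_per_edge: tuple[int, int] = (3, 8)
    samples_per_record: int = 3
    disagreement_rate: float = 0.0
    contradiction_rate: float = 0.0
    impact_factor_range: tuple[float, float] = (1.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.disagreement_rate, self.contradiction_rate):
            if not 0 <= p <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.impact_factor_range[0] <= 0:
            raise ValueError("impact factors must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a planted target/control cohort pair."""

    n_taxa: int = 30
    n_target: int = 25
    n_control: int = 50
    taxon_ids: tuple[str, ...] | None = None
    planted_imbalances: tuple[tuple[str, str, float], ...] = ()  # (taxon, high/low, effect)
    baseline_sigma: float = 1.0
    noise_scale: float = 0.3
    q_low: float = 0.05
    q_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        taxa = {t for t, _, _ in self.planted_imbalances}
        if len(taxa) != len(self.planted_imbalances):
            raise ValueError("planted taxa must be distinct")
        for _, direction, effect in self.planted_imbalances:
            if direction not in ("high", "low"):
                raise ValueError("imbalance direction must be high or low")
            if effect <= 0:
                raise ValueError("effect sizes must be positive")


def unanimity_probability(disagreement_rate: float, n_samples: int) -> float:
    """Probability that all label samples of one record agree.

    Under the corruption model (each sample is the paper's stance with
    probability 1-p, a uniform draw over the three classes with probability
    p): P = (1 - 2p/3)^k + 2 (p/3)^k.  At p = 1 this is the multinomial
    unanimity probability (1/3)^(k-1).
    """
    p = disagreement_rate
    stay = (1 - p) + p / 3
    return stay ** n_samples + 2 * (p / 3) ** n_samples


# ---------------------------------------------------------------------------
# extraction corpus
# ---------------------------------------------------------------------------

def gen_extraction_corpus(
    spec: CorpusSpec,
) -> tuple[list[ExtractionRecord], dict[str, PaperMeta], list[Entity],
           dict[tuple[str, str], str]]:
    """Generate records, paper metadata, entities and planted ground truth.

    For each planted edge a set of mentions is drawn; each mention is
    assigned to a paper whose stance is the planted direction flipped with
    ``contradiction_rate``, and each of its label samples is replaced by a
    uniform label with ``disagreement_rate``.
    """
    if spec.n_microbes < 1 or spec.n_diseases < 1:
        raise ValueError("need at least one microbe and one disease")
    rng = np.random.default_rng(spec.seed)
    microbes = [f"M{i:03d}" for i in range(spec.n_microbes)]
    diseases = [f"D{i:03d}" for i in range(spec.n_diseases)]
    entities = (
        [Entity(m, f"Microbe {m}", "microbe", level="genus") for m in microbes]
        + [Entity(d, f"Disease {d}", "disease") for d in diseases]
    )

    if spec.true_edges is not None:
        planted = list(spec.true_edges)
    else:
        all_pairs = [(m, d) for m in microbes for d in diseases]
        n_edges = min(spec.n_true_edges, len(all_pairs))
        idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
        planted = [
            (all_pairs[i][0], all_pairs[i][1],
             "positive" if rng.random() < 0.5 else "negative")
            for i in idx
        ]

    papers = [f"P{i:03d}" for i in range(spec.n_papers)]
    lo, hi = spec.impact_factor_range
    meta = {
        pid: PaperMeta(pid, impact_factor=float(rng.uniform(lo, hi)))
        for pid in papers
    }

    records: list[ExtractionRecord] = []
    ground_truth: dict[tuple[str, str], str] = {}
    sentence_counter = 0
    for m, d, direction in planted:
        ground_truth[(m, d)] = direction
        n_mentions = int(rng.integers(
            spec.mentions_per_edge[0], spec.mentions_per_edge[1] + 1
        ))
        paper_stance: dict[str, str] = {}
        for _ in range(n_mentions):
            pid = papers[int(rng.integers(len(papers)))]
            if pid not in paper_stance:
                flipped = rng.random() < spec.contradiction_rate
                stance = (
                    ("negative" if direction == "positive" else "positive")
                    if flipped else direction
                )
                paper_stance[pid] = stance
            stance = paper_stance[pid]
            samples = []
            for _ in range(spec.samples_per_record):
                if rng.random() < spec.disagreement_rate:
                    samples.append(LABELS[int(rng.integers(3))])
                else:
                    samples.append(stance)
            records.append(ExtractionRecord(
                paper_id=pid,
                sentence_id=f"s{sentence_counter:05d}",
                microbe_id=m,
                disease_id=d,
                label_samples=tuple(samples),
            ))
            sentence_counter += 1
    return records, meta, entities, ground_truth


def gen_hierarchy(
    entities: Sequence[Entity],
    group_size: int = 5,
) -> tuple[list[Entity], list[HierarchyEdge]]:
    """Attach a toy two-level hierarchy: every ``group_size`` same-kind
    entities share a fresh parent node (a genus-above / disease-category
    layer).  Returns the parent entities and the parent->child edges."""
    parents: list[Entity] = []
    edges: list[HierarchyEdge] = []
    for kind, prefix, level in (("microbe", "MF", "family"), ("disease", "DC", None)):
        members = sorted(
            e.entity_id for e in entities if e.kind == kind
        )
        for gi in range(0, len(members), group_size):
            pid = f"{prefix}{gi // group_size:03d}"
            parents.append(Entity(pid, f"Group {pid}", kind, level=level))
            for child in members[gi:gi + group_size]:
                edges.append(HierarchyEdge(parent_id=pid, child_id=child, kind=kind))
    return parents, edges


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def gen_cohort(
    spec: CohortSpec,
    graph: KnowledgeGraph | None = None,
) -> tuple[AbundanceTable, AbundanceTable,
           list[tuple[str, str, str]], str | None]:
    """Generate (target_table, control_table, expected_flags, expected_top_disease).

    Control and target samples share per-taxon log-normal baselines with
    multiplicative log-normal noise; planted taxa in target samples are
    multiplied (high) or divided (low) by their effect size before
    renormalization to the simplex.  Effect sizes must satisfy
    ln(effect) >= (z(q_band) + z(0.95)) * noise_scale so the planted
    excursion clears the control band with high probability; smaller
    effects are refused with a diagnostic.

    ``expected_flags`` lists (sample_id, taxon, direction) for every target
    sample and planted imbalance.  ``expected_top_disease`` is the disease
    a direction-aware scorer should rank first given the planted flags and
    the supplied graph (None without a graph or without matching edges).
    """
    rng = np.random.default_rng(spec.seed)
    taxa = (
        list(spec.taxon_ids) if spec.taxon_ids is not None
        else [f"T{i:03d}" for i in range(spec.n_taxa)]
    )
    for taxon, _, _ in spec.planted_imbalances:
        if taxon not in taxa:
            raise ValueError(f"planted taxon {taxon!r} not in taxon set")

    z_hi = norm.ppf(spec.q_high)
    z_lo = -norm.ppf(spec.q_low)
    margin = norm.ppf(0.95)
    for taxon, direction, effect in spec.planted_imbalances:
        band_z = z_hi if direction == "high" else z_lo
        required = math.exp((band_z + margin) * spec.noise_scale)
        if effect < required:
            raise ValueError(
                f"effect {effect:.3g} for taxon {taxon!r} too small to clear the "
                f"{direction} quantile band at noise {spec.noise_scale} "
                f"(need >= {required:.3g})"
            )

    baseline = np.exp(rng.normal(0.0, spec.baseline_sigma, size=len(taxa)))
    # Rescale planted baselines so the planted excursion is approximately
    # mass-neutral: otherwise renormalization to the simplex would depress
    # every other taxon and leak the planted signal across the whole table.
    mean_b = baseline.mean()
    for taxon, direction, effect in spec.planted_imbalances:
        j = taxa.index(taxon)
        baseline[j] = 0.5 * mean_b / effect if direction == "high" else 0.5 * mean_b

    def draw(n: int, prefix: str, planted: bool) -> pd.DataFrame:
        vals = baseline * np.exp(
            rng.normal(0.0, spec.noise_scale, size=(n, len(taxa)))
        )
        if planted:
            for taxon, direction, effect in spec.planted_imbalances:
                j = taxa.index(taxon)
                vals[:, j] = (
                    vals[:, j] * effect if direction == "high"
                    else vals[:, j] / effect
                )
        vals = vals / vals.sum(axis=1, keepdims=True)
        return pd.DataFrame(
            vals, index=[f"{prefix}{i:03d}" for i in range(n)], columns=taxa
        )

    control = AbundanceTable(draw(spec.n_control, "ctrl_", planted=False))
    target = AbundanceTable(draw(spec.n_target, "tgt_", planted=True))

    expected_flags = [
        (sid, taxon, direction)
        for sid in target.sample_ids
        for taxon, direction, _ in spec.planted_imbalances
    ]

    expected_top: str | None = None
    if graph is not None and spec.planted_imbalances:
        totals: dict[str, int] = {}
        for taxon, direction, _ in spec.planted_imbalances:
            if taxon not in graph.entities:
                continue
            flag_sign = 1 if direction == "high" else -1
            for edge in graph.relations_of(taxon):
                if edge.direction == "contested":
                    continue
                assoc = 1 if edge.direction == "positive" else -1
                totals[edge.disease_id] = totals.get(edge.disease_id, 0) + flag_sign * assoc
        if totals:
            expected_top = sorted(totals.items(), key=lambda t: (-t[1], t[0]))[0][0]
    return target, control, expected_flags, expected_top


def plant_for_disease(
    graph: KnowledgeGraph,
    n_taxa: int = 4,
    effect: float = 6.0,
    disease: str | None = None,
    min_margin: int = 2,
) -> tuple[tuple[tuple[str, str, float], ...], str]:
    """Choose planted imbalances that point (direction-aware) at one disease.

    For each candidate disease, take up to ``n_taxa`` of its non-contested
    edges and plant a *high* imbalance on positively associated microbes, a
    *low* one on negatively associated microbes.  The candidate is accepted
    when the direction-aware score it implies makes that disease the unique
    top-ranked one with margin >= ``min_margin`` over the runner-up (planted
    microbes may also carry edges to other diseases).  Returns the planted
    set and the disease.
    """
    candidates = (
        [disease] if disease is not None
        else sorted(
            graph.diseases(),
            key=lambda d: (-len(graph.relations_of(d)), d),
        )
    )
    for d in candidates:
        edges = [e for e in graph.relations_of(d) if e.direction != "contested"]
        if not edges:
            continue
        edges = edges[:n_taxa]
        planted = tuple(
            (e.microbe_id, "high" if e.direction == "positive" else "low", effect)
            for e in edges
        )
        totals: dict[str, int] = {}
        for taxon, direction, _ in planted:
            flag_sign = 1 if direction == "high" else -1
            for edge in graph.relations_of(taxon):
                if edge.direction == "contested":
                    continue
                assoc = 1 if edge.direction == "positive" else -1
                totals[edge.disease_id] = (
                    totals.get(edge.disease_id, 0) + flag_sign * assoc
                )
        ranked = sorted(totals.items(), key=lambda t: (-t[1], t[0]))
        if ranked[0][0] == d and (
            len(ranked) == 1 or ranked[0][1] - ranked[1][1] >= min_margin
        ):
            return planted, d
    raise ValueError(
        "no disease admits a planted imbalance set with the requested margin"
    )


# ---------------------------------------------------------------------------
# planted bipartite graphs
# ---------------------------------------------------------------------------

def gen_planted_bipartite(
    n_microbes: int = 40,
    n_diseases: int = 40,
    blocks: int = 2,
    p_in: float = 0.9,
    p_out: float = 0.05,
    seed: int = 0,
) -> tuple[KnowledgeGraph, dict[str, int]]:
    """Bipartite stochastic-block graph with positive edge strengths.

    Microbes and diseases are split into ``blocks`` contiguous groups; a
    (microbe, disease) pair in matching groups gets an edge with
    probability ``p_in``, otherwise ``p_out``.  Strengths are uniform in
    [0.5, 2].  Returns the graph and the block membership ground truth.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("require 0 <= p_out < p_in <= 1")
    if blocks < 1 or n_microbes < blocks or n_diseases < blocks:
        raise ValueError("each block needs at least one node per side")
    rng = np.random.default_rng(seed)
    microbes = [f"M{i:03d}" for i in range(n_microbes)]
    diseases = [f"D{i:03d}" for i in range(n_diseases)]
    membership = {m: i * blocks // n_microbes for i, m in enumerate(microbes)}
    membership.update(
        {d: i * blocks // n_diseases for i, d in enumerate(diseases)}
    )
    graph = KnowledgeGraph(entities=(
        [Entity(m, m, "microbe") for m in microbes]
        + [Entity(d, d, "disease") for d in diseases]
    ))
    for m in microbes:
        for d in diseases:
            p = p_in if membership[m] == membership[d] else p_out
            if rng.random() < p:
                graph.add_relation_edge(RelationEdge(
                    microbe_id=m, disease_id=d,
                    strength=float(rng.uniform(0.5, 2.0)),
                    n_papers=1, direction="positive",
                    evidence=(("synthetic", f"{m}-{d}", "positive"),),
                ))
    return graph, membership
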