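"""Microbiome-composition risk assessment against a healthy reference.

Given relative-abundance tables for a target cohort and a control cohort
(one taxonomic level, genus by convention), the module provides:

* standard diversity statistics -- Shannon alpha-diversity and Bray-Curtis
  beta-diversity;
* PLS-DA with VIP scores, identifying the taxa that best discriminate the
  two cohorts without any disease knowledge;
* quantile-band imbalance detection: a taxon is flagged in a target sample
  when its relative abundance falls outside the control cohort's empirical
  [q_low, q_high] band (5th-95th percentile by default) -- the operational
  definition of dysbiosis used throughout;
* literature-grounded risk scoring: each flagged taxon contributes +-1 to
  every disease it is linked to in the knowledge graph, per-sample scores
  are summed across the population, and diseases are ranked.

Scoring modes.  The +-1 rule is ambiguous about how a *low* abundance of a
disease-promoting taxon should count.  ``association_only`` applies the
literal rule (+1 per positively associated flagged taxon, -1 per negatively
associated one, regardless of flag direction).  ``direction_aware`` (the
default) multiplies the flag direction (+1 high / -1 low) by the
association sign, so a depleted protective taxon raises risk -- the
biologically coherent reading.  Contested edges contribute 0 in both modes.

These scores aggregate literature evidence for hypothesis generation; they
are not diagnostic quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from sklearn.cross_decomposition import PLSRegression

from microkg.consensus import infer_hierarchical_relations
from microkg.model import AbundanceTable, KnowledgeGraph

ScoringMode = Literal["direction_aware", "association_only"]


@dataclass(frozen=True)
class RiskConfig:
    """Quantile band and scoring behaviour for the risk pipeline."""

    q_low: float = 0.05
    q_high: float = 0.95
    scoring_mode: ScoringMode = "direction_aware"
    taxonomic_level: str = "genus"

    def __post_init__(self) -> None:
        if not 0 <= self.q_low < self.q_high <= 1:
            raise ValueError("require 0 <= q_low < q_high <= 1")
        if self.scoring_mode not in ("direction_aware", "association_only"):
            raise ValueError(f"unknown scoring_mode {self.scoring_mode!r}")


@dataclass(frozen=True)
class ImbalanceFlag:
    """A taxon outside the control quantile band in one target sample."""

    sample_id: str
    taxon_id: str
    direction: Literal["high", "low"]
    observed: float
    control_low_q: float
    control_high_q: float

    def __post_init__(self) -> None:
        if self.direction == "high" and not self.observed > self.control_high_q:
            raise ValueError("high flag requires observed > control_high_q")
        if self.direction == "low" and not self.observed < self.control_low_q:
            raise ValueError("low flag requires observed < control_low_q")


@dataclass
class RiskReport:
    """Per-sample disease risk scores with contributing flags."""

    sample_id: str
    scores: dict[str, int]
    contributions: list[tuple[ImbalanceFlag, str, int]]  # (flag, disease, +-1)

    def ranking(self) -> list[tuple[str, int]]:
        return sorted(self.scores.items(), key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def normalize_abundance(table: AbundanceTable) -> AbundanceTable:
    """Scale each sample to relative abundances (rows sum to one)."""
    return table.normalize()


def alpha_diversity(sample: Sequence[float] | pd.Series) -> float:
    """Shannon index H = -sum p ln p over a normalized composition."""
    p = np.asarray(sample, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("sample must be normalized to sum 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def beta_diversity(
    sample_a: Sequence[float] | pd.Series, sample_b: Sequence[float] | pd.Series
) -> float:
    """Bray-Curtis dissimilarity between two normalized compositions.

    For relative abundances this equals 1 - sum_i min(p_i, q_i).  Samples
    must share one taxon ordering (zero-fill the union beforehand).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("samples must share a non-empty taxon set")
    return float(_braycurtis(a, b))


def beta_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis matrix (symmetric, zero diagonal)."""
    from scipy.spatial.distance import pdist, squareform

    mat = squareform(pdist(table.data.values, metric="braycurtis"))
    return pd.DataFrame(mat, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def plsda_discriminate(
    table_target: AbundanceTable,
    table_control: AbundanceTable,
    n_components: int = 2,
) -> dict:
    """PLS-DA of target vs control with per-taxon VIP scores.

    Columns are aligned on the union of taxa (zero fill), data are
    column-centered, and PLS regression (NIPALS iteration) is fitted
    against a +-1 group indicator.  VIP for taxon j is

        VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

    with p the number of taxa and SSY_a the Y-variance captured by
    component a; by construction mean(VIP^2) = 1.  Deterministic and
    invariant to sample order.
    """
    n_t, n_c = len(table_target.sample_ids), len(table_control.sample_ids)
    if n_t < 3 or n_c < 3:
        raise ValueError("need at least 3 samples per group")
    if n_t + n_c <= n_components:
        raise ValueError("fewer samples than components")
    taxa = sorted(set(table_target.taxon_ids) | set(table_control.taxon_ids))
    xt = table_target.data.reindex(columns=taxa, fill_value=0.0)
    xc = table_control.data.reindex(columns=taxa, fill_value=0.0)
    x = pd.concat([xt, xc]).values
    y = np.concatenate([np.ones(n_t), -np.ones(n_c)])

    x_centered = x - x.mean(axis=0)
    y_centered = (y - y.mean()).reshape(-1, 1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(x_centered, y_centered)

    w = pls.x_weights_            # p x A
    t = pls.x_scores_             # n x A
    q = pls.y_loadings_           # 1 x A
    ssy = (t ** 2).sum(axis=0) * (q.ravel() ** 2)
    wnorm2 = (w ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    p = len(taxa)
    vip = np.sqrt(p * ((w ** 2 / wnorm2) @ ssy) / ssy.sum())

    sample_ids = table_target.sample_ids + table_control.sample_ids
    return {
        "taxa": taxa,
        "sample_ids": sample_ids,
        "groups": ["target"] * n_t + ["control"] * n_c,
        "scores": pd.DataFrame(
            t, index=sample_ids,
            columns=[f"comp_{a + 1}" for a in range(n_components)],
        ),
        "loadings": pd.DataFrame(
            pls.x_loadings_, index=taxa,
            columns=[f"comp_{a + 1}" for a in range(n_components)],
        ),
        "vip": pd.Series(vip, index=taxa, name="vip"),
    }


# ---------------------------------------------------------------------------
# imbalance detection
# ---------------------------------------------------------------------------

def detect_imbalances(
    target: AbundanceTable,
    control: AbundanceTable,
    cfg: RiskConfig = RiskConfig(),
) -> list[ImbalanceFlag]:
    """Flag target abundances outside the control quantile band.

    Control quantiles are empirical with linear interpolation between order
    statistics.  A taxon absent from the control table is treated as an
    all-zero control distribution, so any positive target abundance for it
    flags high.  Flags are strict: observed must exceed q_high or fall
    below q_low.
    """
    if not control.sample_ids:
        raise ValueError("control cohort is empty")
    if not target.is_normalized() or not control.is_normalized():
        raise ValueError("tables must be normalized (rows sum to 1)")
    n_ctrl = len(control.sample_ids)
    flags: list[ImbalanceFlag] = []
    for taxon in target.taxon_ids:
        if taxon in control.data.columns:
            ctrl_vals = control.data[taxon].values
        else:
            ctrl_vals = np.zeros(n_ctrl)
        lo, hi = np.quantile(ctrl_vals, [cfg.q_low, cfg.q_high], method="linear")
        for sid in target.sample_ids:
            obs = float(target.data.at[sid, taxon])
            if obs > hi:
                flags.append(ImbalanceFlag(sid, taxon, "high", obs, float(lo), float(hi)))
            elif obs < lo:
                flags.append(ImbalanceFlag(sid, taxon, "low", obs, float(lo), float(hi)))
    return flags


# ---------------------------------------------------------------------------
# risk scoring
# ---------------------------------------------------------------------------

def disease_risk_scores(
    flags: Iterable[ImbalanceFlag],
    graph: KnowledgeGraph,
    cfg: RiskConfig = RiskConfig(),
) -> list[RiskReport]:
    """Turn imbalance flags into per-sample, per-disease +-1 sums.

    For each flagged taxon every direct knowledge-graph edge to a disease
    contributes one increment; contested edges contribute zero.  Taxa with
    no graph entity are skipped with a warning.
    """
    by_sample: dict[str, list[ImbalanceFlag]] = {}
    for f in flags:
        by_sample.setdefault(f.sample_id, []).append(f)

    unresolved: set[str] = set()
    reports: list[RiskReport] = []
    for sid in sorted(by_sample):
        scores: dict[str, int] = {}
        contribs: list[tuple[ImbalanceFlag, str, int]] = []
        for f in by_sample[sid]:
            if f.taxon_id not in graph.entities:
                unresolved.add(f.taxon_id)
                continue
            for edge in graph.relations_of(f.taxon_id):
                if edge.direction == "contested":
                    continue
                assoc = 1 if edge.direction == "positive" else -1
                if cfg.scoring_mode == "association_only":
                    delta = assoc
                else:
                    flag_sign = 1 if f.direction == "high" else -1
                    delta = flag_sign * assoc
                disease = edge.disease_id
                scores[disease] = scores.get(disease, 0) + delta
                contribs.append((f, disease, delta))
        reports.append(RiskReport(sample_id=sid, scores=scores, contributions=contribs))
    if unresolved:
        warnings.warn(
            f"skipped flags for {len(unresolved)} taxa absent from the graph: "
            f"{sorted(unresolved)[:5]}...",
            stacklevel=2,
        )
    return reports


def aggregate_population(reports: Sequence[RiskReport]) -> list[tuple[str, int]]:
    """Sum per-sample scores across the population; rank descending.

    Ties break lexicographically by disease id.
    """
    if not reports:
        raise ValueError("need at least one report")
    totals: dict[str, int] = {}
    for rep in reports:
        for disease, score in rep.scores.items():
            totals[disease] = totals.get(disease, 0) + score
    return sorted(totals.items(), key=lambda t: (-t[1], t[0]))


def disease_specific_report(
    target_disease: str,
    target: AbundanceTable,
    control: AbundanceTable,
    graph: KnowledgeGraph,
    cfg: RiskConfig = RiskConfig(),
    include_inferred: bool = False,
) -> list[dict]:
    """Imbalances restricted to taxa with known links to one disease.

    Each entry carries the flag, the association direction from the
    literature edge, and the direction-aware interpretation: a flag whose
    direction-aware contribution is positive indicates *elevated* risk,
    negative indicates *reduced* risk, contested is *indeterminate*.
    Always a subset of :func:`detect_imbalances` output.
    """
    if graph.entity(target_disease).kind != "disease":
        raise ValueError(f"{target_disease!r} is not a disease entity")
    associated: dict[str, str] = {}
    for edge in graph.relations_of(target_disease):
        associated[edge.microbe_id] = edge.direction
    if include_inferred:
        for m in graph.microbes():
            if m in associated:
                continue
            inferred = infer_hierarchical_relations(graph, m, target_disease, max_hops=1)
            hits = [i for i in inferred if i.hops == 1]
            if hits:
                associated[m] = hits[0].source_edge.direction

    rows: list[dict] = []
    for flag in detect_imbalances(target, control, cfg):
        direction = associated.get(flag.taxon_id)
        if direction is None:
            continue
        if direction == "contested":
            interp = "indeterminate"
        else:
            assoc = 1 if direction == "positive" else -1
            flag_sign = 1 if flag.direction == "high" else -1
            interp = "elevated risk" if flag_sign * assoc > 0 else "reduced risk"
        rows.append({
            "sample_id": flag.sample_id,
            "taxon_id": flag.taxon_id,
            "flag_direction": flag.direction,
            "observed": flag.observed,
            "control_low_q": flag.control_low_q,
            "control_high_q": flag.control_high_q,
            "association": direction,
            "interpretation": interp,
        })
    return rows
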