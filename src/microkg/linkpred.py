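"""Link prediction: scoring unobserved microbe-disease pairs.

Protocol: relation edges are split into train/test positives; an equal
number of negatives is sampled uniformly from bipartite non-edges;
embeddings are computed on the *training graph only* (test edges removed)
so no test signal leaks into features; a logistic classifier is fitted on
embedding-pair features (Hadamard product by default) and evaluated on the
held-out set.  A second, independent classifier trained on observed edge
directions (positive vs negative strength) assigns a likely sign to
candidate links, so each entity gets a ranked list of probable positive
and probable negative associations.

The classifier is a deliberate linear baseline; richer models (e.g. graph
neural networks) can be swapped in through :class:`EdgeClassifier`'s
``model`` attribute, since ranking and evaluation only require
``predict_proba``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from microkg.analytics import EmbeddingSet
from microkg.model import KnowledgeGraph, RelationEdge

FeatureOp = Literal["hadamard", "average", "l1", "l2"]
Pair = tuple[str, str]


@dataclass
class EdgeSplit:
    """Train/test positives and matched sampled negatives."""

    train_pos: tuple[Pair, ...]
    test_pos: tuple[Pair, ...]
    train_neg: tuple[Pair, ...]
    test_neg: tuple[Pair, ...]
    seed: int
    test_fraction: float

    def __post_init__(self) -> None:
        if set(self.train_pos) & set(self.test_pos):
            raise ValueError("train and test positives overlap")
        if len(self.train_neg) != len(self.train_pos):
            raise ValueError("train negatives must match train positives 1:1")
        if len(self.test_neg) != len(self.test_pos):
            raise ValueError("test negatives must match test positives 1:1")


@dataclass
class EdgeClassifier:
    """Logistic link classifier over embedding-pair features."""

    model: LogisticRegression
    feature_op: FeatureOp
    regularization: float
    threshold: float = 0.5

    @property
    def weights(self) -> np.ndarray:
        return self.model.coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.model.intercept_[0])

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each feature row."""
        return self.model.predict_proba(features)[:, 1]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_edges(
    graph: KnowledgeGraph,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> EdgeSplit:
    """Uniform random positive split plus 1:1 uniform negative sampling.

    Negatives are bipartite (microbe, disease) pairs with no relation edge
    in the *full* graph, sampled without replacement.  Deterministic given
    the seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    pos = [(e.microbe_id, e.disease_id) for e in graph.relation_edges]
    if len(pos) < 5:
        raise ValueError("graph must have at least 5 relation edges to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos))
    n_test = int(round(test_fraction * len(pos)))
    n_test = min(max(n_test, 1), len(pos) - 1)
    test_pos = tuple(pos[i] for i in sorted(order[:n_test]))
    train_pos = tuple(pos[i] for i in sorted(order[n_test:]))

    non_edges = [
        (m, d)
        for m in graph.microbes()
        for d in graph.diseases()
        if not graph.has_relation(m, d)
    ]
    if len(non_edges) < len(pos):
        raise ValueError("not enough bipartite non-edges to sample negatives")
    neg_idx = rng.choice(len(non_edges), size=len(pos), replace=False)
    negs = [non_edges[i] for i in neg_idx]
    return EdgeSplit(
        train_pos=train_pos,
        test_pos=test_pos,
        train_neg=tuple(negs[n_test:]),
        test_neg=tuple(negs[:n_test]),
        seed=seed,
        test_fraction=test_fraction,
    )


def training_graph(graph: KnowledgeGraph, split: EdgeSplit) -> KnowledgeGraph:
    """Copy of the graph with test positives removed (for leak-free embedding)."""
    held_out = set(split.test_pos)
    return KnowledgeGraph(
        entities=graph.entities.values(),
        relation_edges=[
            e for e in graph.relation_edges
            if (e.microbe_id, e.disease_id) not in held_out
        ],
        hierarchy_edges=graph.hierarchy_edges,
    )


# ---------------------------------------------------------------------------
# features and training
# ---------------------------------------------------------------------------

def edge_features(
    emb: EmbeddingSet,
    microbe_id: str,
    disease_id: str,
    feature_op: FeatureOp = "hadamard",
) -> np.ndarray:
    """Combine two entity embeddings into one edge feature vector."""
    u = emb.vector(microbe_id)
    v = emb.vector(disease_id)
    if feature_op == "hadamard":
        return u * v
    if feature_op == "average":
        return (u + v) / 2.0
    if feature_op == "l1":
        return np.abs(u - v)
    if feature_op == "l2":
        return (u - v) ** 2
    raise ValueError(f"unknown feature_op {feature_op!r}")


def _feature_matrix(
    emb: EmbeddingSet, pairs: Sequence[Pair], feature_op: FeatureOp
) -> np.ndarray:
    if not pairs:
        return np.empty((0, emb.dim))
    return np.vstack([edge_features(emb, m, d, feature_op) for m, d in pairs])


def train_edge_classifier(
    split: EdgeSplit,
    emb: EmbeddingSet,
    feature_op: FeatureOp = "hadamard",
    regularization: float = 1.0,
) -> EdgeClassifier:
    """Fit the logistic link classifier on training pairs (label 1 = edge)."""
    if not split.train_pos or not split.train_neg:
        raise ValueError("train sets must be non-empty")
    x = np.vstack([
        _feature_matrix(emb, split.train_pos, feature_op),
        _feature_matrix(emb, split.train_neg, feature_op),
    ])
    y = np.concatenate([
        np.ones(len(split.train_pos)), np.zeros(len(split.train_neg)),
    ])
    model = _fit_logistic(x, y, regularization)
    return EdgeClassifier(
        model=model, feature_op=feature_op, regularization=regularization
    )


def _fit_logistic(
    x: np.ndarray, y: np.ndarray, regularization: float
) -> LogisticRegression:
    if len(set(y.tolist())) < 2:
        raise ValueError("degenerate single-class training set")
    if regularization > 0:
        model = LogisticRegression(
            C=1.0 / regularization, tol=1e-6, max_iter=2000, solver="lbfgs"
        )
    else:
        model = LogisticRegression(
            penalty=None, tol=1e-6, max_iter=2000, solver="lbfgs"
        )
    model.fit(x, y)
    return model


def train_sign_classifier(
    graph: KnowledgeGraph,
    emb: EmbeddingSet,
    feature_op: FeatureOp = "hadamard",
    regularization: float = 1.0,
) -> EdgeClassifier | None:
    """Fit a direction classifier on observed edges (label 1 = negative w).

    Contested edges (w = 0) carry no direction and are excluded.  Returns
    None when the observed directions are single-class (nothing to learn).
    """
    pairs, labels = [], []
    for e in graph.relation_edges:
        if e.direction == "contested":
            continue
        if e.microbe_id not in emb or e.disease_id not in emb:
            continue
        pairs.append((e.microbe_id, e.disease_id))
        labels.append(1.0 if e.direction == "negative" else 0.0)
    if len(set(labels)) < 2:
        return None
    x = _feature_matrix(emb, pairs, feature_op)
    model = _fit_logistic(x, np.asarray(labels), regularization)
    return EdgeClassifier(
        model=model, feature_op=feature_op, regularization=regularization
    )


# ---------------------------------------------------------------------------
# ranking and evaluation
# ---------------------------------------------------------------------------

def rank_candidate_links(
    graph: KnowledgeGraph,
    emb: EmbeddingSet,
    clf: EdgeClassifier,
    entity: str,
    top_k: int = 10,
    sign_clf: EdgeClassifier | None = None,
) -> tuple[list[tuple[Pair, float]], list[tuple[Pair, float]]]:
    """Rank unobserved pairs involving one entity.

    Returns ``(likely_positive, likely_negative)``: the first list holds the
    top_k candidate pairs by descending link probability; the second ranks
    candidates by the sign classifier's probability of a *negative*
    association (trained here on observed edge directions when not passed
    in).  Observed pairs are excluded from both lists; ties break
    lexicographically, so enumeration order never matters.
    """
    ent = graph.entity(entity)
    if ent.kind == "microbe":
        candidates = [
            (entity, d) for d in graph.diseases()
            if not graph.has_relation(entity, d) and d in emb
        ]
    else:
        candidates = [
            (m, entity) for m in graph.microbes()
            if not graph.has_relation(m, entity) and m in emb
        ]
    if entity not in emb or not candidates:
        return [], []

    feats = _feature_matrix(emb, candidates, clf.feature_op)
    p_link = clf.predict_proba(feats)
    ranked = sorted(zip(candidates, p_link), key=lambda t: (-t[1], t[0]))
    likely_positive = [(pair, float(p)) for pair, p in ranked[:top_k]]

    if sign_clf is None:
        sign_clf = train_sign_classifier(
            graph, emb, clf.feature_op, clf.regularization
        )
    if sign_clf is None:
        return likely_positive, []
    p_neg = sign_clf.predict_proba(
        _feature_matrix(emb, candidates, sign_clf.feature_op)
    )
    ranked_neg = sorted(
        zip(candidates, p_neg, p_link), key=lambda t: (-t[1], -t[2], t[0])
    )
    likely_negative = [(pair, float(p)) for pair, p, _ in ranked_neg[:top_k]]
    return likely_positive, likely_negative


def evaluate_predictions(
    clf: EdgeClassifier,
    split: EdgeSplit,
    emb: EmbeddingSet,
) -> dict[str, float]:
    """Held-out binary metrics (accuracy/precision/recall/F1 at the
    classifier threshold, AUC by rank statistic over scores)."""
    if not split.test_pos or not split.test_neg:
        raise ValueError("test sets must be non-empty")
    x = np.vstack([
        _feature_matrix(emb, split.test_pos, clf.feature_op),
        _feature_matrix(emb, split.test_neg, clf.feature_op),
    ])
    y = np.concatenate([
        np.ones(len(split.test_pos)), np.zeros(len(split.test_neg)),
    ])
    scores = clf.predict_proba(x)
    pred = (scores >= clf.threshold).astype(float)
    tp = float(np.sum((pred == 1) & (y == 1)))
    tn = float(np.sum((pred == 0) & (y == 0)))
    fp = float(np.sum((pred == 1) & (y == 0)))
    fn = float(np.sum((pred == 0) & (y == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall else 0.0
    )
    return {
        "accuracy": (tp + tn) / len(y),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": float(roc_auc_score(y, scores)),
    }
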