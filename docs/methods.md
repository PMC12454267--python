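# Methods

## Evidence model

The unit of evidence is a sentence-level extraction record: one
(microbe, disease) mention in one sentence of one paper, carrying the
repeated label samples produced by sampling the extraction model several
times (default 3). Consolidation is deliberately conservative:

* **Unanimity filter.** A record survives only if every sample agrees.
  Under the corruption model used by the synthetic generator — each
  sample is the paper's stance with probability 1−p and a uniform draw
  over the three classes with probability p — the retention probability
  is (1 − 2p/3)^k + 2(p/3)^k, which reduces to the multinomial unanimity
  probability (1/3)^(k−1) at p = 1. This closed form
  (`synth.unanimity_probability`) is the oracle for the calibration
  tests.
* **Within-paper vote.** The modal label per (paper, pair) group wins;
  *unrelated* winners and exact ties assert no direction. The
  `tie_policy` options (`discard`, `prefer_none`) differ only in how the
  tie is recorded, never in the surviving edge set.
* **Cross-paper weight.** r = sign·log₁₀(max(F, F_min)) per paper, summed
  into w. The floor F_min = 1 guarantees no paper contributes negative
  magnitude; papers missing from the metadata table count with a default
  impact factor of 2.0 (a typical mid-range journal) rather than being
  dropped, so evidence is never silently lost. w = 0 edges are kept as
  *contested* and excluded from every direction-dependent consumer
  (risk scoring, sign classification).

Hierarchical inference is query-time only: a relation query may move one
endpoint (never both) up to `max_hops` parent/child steps (default 1),
returning the matched edges with their hop provenance. Materializing
inferred edges would conflate asserted with derived knowledge and let
repeated queries compound inferences.

## Graph analytics

Traversal is undirected — edges encode association, not causation — and
spans relation and hierarchy edges alike, so species → genus → disease
routes exist. Two cost modes: `hop` (unit) and `inverse_strength`
(1/(1+|w|) per relation edge, 1 per hierarchy edge), since no canonical
cost is established for evidence-weighted graphs. Alternative routes are
Yen's k loopless shortest paths; because the underlying generator breaks
cost ties arbitrarily, candidates are drained past the k-th cost and
re-sorted by (cost, lexicographic node sequence), making output
deterministic.

Embeddings are FastRP: a sparse ±√3 sign projection R (density 1/3)
propagated through powers of the symmetrically degree-normalized
adjacency M = D^e A D^e (e = −0.5), combined as Σᵢ wᵢ Mⁱ R with default
weights (0, 0.5, 1) over powers 1–3 — first-order structure is dropped
and 2–3-step neighborhoods dominate, which suits bipartite graphs where
same-kind similarity is inherently a two-step property. Rows are
L2-normalized; nodes are processed in sorted-id order so insertion order
is irrelevant; everything is a pure function of (graph, seed). Nodes
with identical neighbor sets get identical rows of M and hence cosine
similarity exactly 1 — the invariant the structural-twin tests check.
node2vec-family or GNN embeddings can be substituted anywhere an
`EmbeddingSet` is accepted.

## Link prediction

A linear baseline chosen for determinism and auditability: logistic
regression (L2, tolerance 1e-6) on Hadamard features of the endpoint
embeddings, 1:1 uniform negative sampling from bipartite non-edges, and —
critically — embeddings computed on the training graph with test
positives removed, because embedding the full graph leaks the held-out
edges into the features. The direction of a candidate association is a
separate binary task trained on observed edge signs and applied post
hoc; the "likely negative" list ranks by P(negative direction) with link
probability as tie-break. Richer models plug in through the
`EdgeClassifier.model` attribute (anything with `predict_proba`).

## Risk assessment

Dysbiosis is operationalized as a quantile excursion: a taxon is flagged
in a target sample when its relative abundance falls strictly outside
the control cohort's empirical [q_low, q_high] band (defaults 0.05 and
0.95; linear interpolation between order statistics). Taxa absent from
the control table are treated as an all-zero control distribution, so
any positive target abundance flags high.

Scoring: each flagged taxon contributes ±1 per non-contested graph edge
to the linked disease. The literal reading of the rule
(`association_only`) scores +1 for positively associated and −1 for
negatively associated taxa regardless of flag direction; the default
(`direction_aware`) multiplies flag direction by association sign, so a
*depleted* disease-promoting microbe lowers the score and a depleted
protective microbe raises it. Both modes are implemented because the
rule as stated does not resolve the low-abundance case; direction-aware
is the default for biological coherence. Population aggregation sums
per-sample scores; all rankings break ties lexicographically.

PLS-DA fits a NIPALS-style PLS regression (two components by default) of
column-centered abundances against a ±1 group indicator; VIP_j =
√(p·Σₐ SSYₐ(w_ja/‖wₐ‖)² / Σₐ SSYₐ), which satisfies mean(VIP²) = 1
exactly — the identity the null-fixture test asserts. Analyses run at a
single taxonomic level per invocation (genus by convention); α-diversity
is the natural-log Shannon index, β-diversity Bray–Curtis.

## Synthetic data

The generators define the test conditions; they model the statistical
structure the pipeline assumes, not microbial ecology:

* **Corpus** (`gen_extraction_corpus`): defaults of 40 papers, 15
  microbes, 8 diseases, 20 planted directed edges with 3–8 mentions
  each, impact factors uniform on [1, 30], and clean labels unless a
  disagreement (within-record) or contradiction (whole-paper) rate is
  set — desk-scale sizes that keep every oracle exhaustive while
  exercising multi-paper aggregation.
* **Cohorts** (`gen_cohort`): shared per-taxon log-normal baselines
  (σ = 1) with multiplicative log-normal noise (σ = 0.3), 25 target and
  50 control samples over 30 taxa by default. Planted taxa are
  multiplied/divided by their effect size; their baselines are rescaled
  (0.5·mean/effect for high, 0.5·mean for low) so the excursion is
  approximately mass-neutral after renormalization — otherwise the
  boost deflates every other relative abundance and floods the table
  with spurious low flags. The generator refuses effect sizes below
  exp((z(q_band)+z(0.95))·σ_noise), the size needed to clear the band in
  ~95 % of samples; an uncalibrated fixture would make planted-truth
  tests meaningless rather than strict.
* **Bipartite blocks** (`gen_planted_bipartite`): 40+40 nodes, two
  blocks, within-block edge probability 0.9 vs 0.05 across — strong
  enough structure that a linear classifier on FastRP features should
  exceed 0.8 held-out accuracy, which is what the acceptance property
  demands.

What passing these tests does *not* show: robustness to compositional
correlations between taxa, realistic phylogenetic structure, batch
effects between cohorts, extraction-model biases that correlate across
sentences, or impact-factor distributions with heavy tails. Real-data
behaviour must be validated separately.

## Numerical and interface choices

* TSV dialect: tab-separated, UTF-8, header row, `.` decimals; floats
  are read with round-trip precision so write→read is bit-exact.
* GraphML is the faithful graph format (node names, levels, evidence
  lists as JSON-encoded attributes); edge TSV is provided for
  interchange but cannot carry isolated nodes or display names.
* `AbundanceTable.normalize` is exactly idempotent: rows already on the
  simplex are returned untouched instead of re-divided by 1 ± ulp.
* k-means uses k-means++ with 10 restarts and a fixed seed; logistic
  fits use lbfgs to tolerance 1e-6; all stochastic steps consume
  `numpy.random.default_rng(seed)`.
* Problem sizes in the test suite and acceptance script (corpora ≤ 200
  relations, graphs ≤ 10 nodes for path oracles, 80-node link-prediction
  graphs, 5-seed repetitions) are chosen so every check has an
  exhaustive or closed-form oracle and the whole suite runs in seconds.

## Known limitations

Impact factors are a crude reliability proxy (and the only weighting
implemented); no year matching or study-size weighting. Entity ids are
opaque strings — no ontology normalization or synonym resolution.
Link-prediction metrics depend on the uniform negative-sampling
assumption; degree-biased sampling would yield harder negatives. The
risk score treats edges as independent and unweighted (±1, not w), per
its definition. Species-level scoring and PERMANOVA-style significance
testing of β-diversity are out of scope.
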