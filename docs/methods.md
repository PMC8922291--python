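# Methods

This note documents the models, algorithms, and design choices behind
`interatlas`, including the points where the design was genuinely open and
the package had to commit to one reading.

## Data model

All learning operates on **fold-change observations**: for a two-group
design with n_t test and n_c control samples, every (test, control) pairing
contributes one row of per-gene log2 fold changes, giving n_t × n_c
exchangeable observations (400 for the default 20+20 design). Rows are
discretized into three states — down (≤ −τ), unchanged, up (≥ +τ) — with
τ = 1.0 (two-fold change) by default. τ is configurable because the
literature offers no single canonical cutoff; 1.0 is the conventional one.
Clustering uses the same (undiscretized) observation vectors, so one
preprocessing path feeds both clustering and learning.

## Structure learning

**Score.** Discrete BIC with natural logarithms:
Σ_v [max-likelihood multinomial log-likelihood of v given Pa(v)] −
(log N / 2) · (free parameters). The score is decomposable per node, which
the search exploits.

**Search.** Steepest-ascent hill climbing over single-arc add / delete /
reverse moves preserving acyclicity. Ties between equal-gain moves are
broken delete > reverse > add, then by lexicographic arc order — a
deliberate bias toward sparsity plus full determinism. The first climb
starts from the empty graph (so the result never scores below it); optional
random restarts (default 2 for standalone use) start from sparse random
DAGs and the best local optimum wins. A `max_parents` cap (default 4)
bounds the candidate space; with 3-state nodes and N = 400 the BIC penalty
makes larger families unreachable in practice anyway. Implementation notes:
add-move gains are cached in a matrix and refreshed only for the node whose
family the last move changed, with the refresh computed for all candidate
parents at once via one-hot contingency products; acyclicity is tested
against a transitive-closure matrix rebuilt once per applied move. On
≤3-variable problems the search provably reaches the global optimum in the
test suite's exhaustive-enumeration comparisons.

**Bootstrap model averaging.** B resamples of the observation rows (with
replacement), one hill climb each; the strength of an unordered pair is the
fraction of replicate networks containing an arc between them in either
direction (the evaluation target is undirected, so direction is collapsed).
Replicates draw their seeds from a spawned child-seed stream, so enlarging
B extends the stream without reshuffling earlier replicates. Rows are
canonically sorted before resampling, making strengths exactly invariant to
input row order. Within bootstrap averaging each climb uses no restarts:
the averaging itself explores structure space, and the saved factor of
(restarts+1) is spent on more replicates instead.

**Significance threshold.** Given a set of strengths, the cutoff t̂
minimises the L1 distance between the empirical CDF of the strengths and
the ideal one-step CDF that is 0 below t and 1 at/above t, with candidates
restricted to observed strength values; edges are significant iff
strength > t̂. Two conventions deserve note. (1) When several candidates tie
on the L1 objective — e.g. strengths {0,0,1,1}, where every candidate ties
— t̂ is the mean of the tied minimisers, which lands strictly between the
modes of a bimodal strength set. (2) A degenerate all-identical strength
set thresholds just below the common value (retain-all), with a warning.
The threshold is computed over **all** candidate pairs of the node set,
pairs never recovered counting as strength 0, matching the convention of
averaged-network construction in the R structure-learning ecosystem. A
caveat documented here because it shows up in testing: on noise-only
strength sets (no true signal at all) the one-step-CDF construction can
retain the top of the noise floor as "significant"; the method presumes a
bimodal signal/noise mixture.

## The knowledge prior (BNP)

The prior is itself a small discrete Bayesian network over binary evidence
types plus one GI ("these genes interact") node. A pair is labelled GI = 1
iff it carries **two or more knowledge evidence types**; experimental
columns (below) do not count toward the label. The network is learned from
the evidence matrix by the machinery above (bootstrap averaging, default
B = 1000 at full scale; smaller B in desk-scale runs); consensus arcs are
those above the significance threshold, oriented by bootstrap majority
(ties lexicographic), added in decreasing strength order and skipping any
orientation that would close a cycle. CPTs are fit on the full dataset with
one pseudo-count per cell.

**Injecting expression data.** The mechanism by which a gene pair's
expression profiles enter GI inference is a declared reconstruction: one
evidence type, `coexpression`, is computed from the supplied expression
matrix as the indicator |Pearson r| ≥ ρ₀ (default 0.5, configurable) and
appended to the evidence matrix before BNP learning, so the BNP itself
learns how coexpression relates to GI. At inference time a pair's evidence
vector combines its knowledge-base columns (pairs absent from the matrix
count as all-zero knowledge evidence, not missing data) with its computed
coexpression bit. Posteriors P(GI=1 | evidence) are clamped to
[ε, 1−ε], ε = 10⁻³, so log priors stay finite.

**Graph prior.** log P(G) = κ Σ over unordered node pairs of
[log π(pair) if adjacent else log(1−π(pair))], with prior weight κ
(default 1) exposed because the original weighting between data likelihood
and knowledge prior is not pinned down. The prior is edge-decomposable, so
the search folds it into per-move gains as κ·log(π/(1−π)).

## Clustering and validation

K is derived from an expected cluster size: K = max(1, round(n/size)).
Hierarchical clustering uses distance 1 − Pearson r between gene
observation vectors with average linkage (a common, robust default for
expression data; linkage and distance are configurable); k-means runs on
per-gene standardized vectors with k-means++ initialisation, deterministic
given the seed. Labels are renumbered contiguously by decreasing cluster
size. Genes with constant observation vectors have undefined correlation
and fall back to the zero-correlation convention with a warning.

Validation indices: V-measure and ARI (standard implementations), and BHI =
mean over clusters of the fraction of annotated gene pairs sharing a
functional class. Clusters with fewer than two annotated genes contribute 1
to BHI by convention (the defining publication leaves the case open;
retain-neutral was chosen and the count is reported via a warning).

## Representative selection

Per cluster, centralities are computed on the largest connected component
of the consensus network: degree, betweenness, closeness, harmonic
closeness, eigenvector, PageRank. This fixed six-measure battery replaces
the ~50-measure catalogue of centrality-survey tools: it covers the main
centrality families while staying deterministic and applicable to small
components (measures undefined on a component are dropped). Columns are
standardized and the measure with the largest absolute loading on the first
principal component is chosen (sign ambiguity of the PC is irrelevant under
absolute loadings; ties resolve in battery order; an all-constant profile
falls back to degree). The representative is the most central node under
that measure, ties broken by higher degree then lexicographic order.
Degenerate clusters have defined fallbacks: an edgeless cluster is
represented by the gene with the highest total absolute correlation to its
cluster mates; a singleton by its only gene.

## Merging and aggregation

The network learned over the representative genes is the merge map: every
significant edge between representatives merges the corresponding cluster
pair by re-learning a network on the union of their genes (merges are
mutually independent and could run in parallel; results do not depend on
execution order). A within-cluster pair in a cluster that joined k merges
therefore has 1 + k strengths (its within-cluster run plus one per merge);
a cross-cluster pair has one strength per merge that co-examined it; pairs
never co-examined are absent and score 0 at evaluation. Aggregation
methods: first (within-cluster-only value), min, max, mean (default, the
best performer in the benchmark sweeps), median, and the one-step Tukey
biweight with c = 5 and ε = 10⁻⁴ (the standard one-step biweight
constants). The final discrete atlas applies the significance threshold to
the pooled aggregated scores; evaluation always uses the continuous scores,
so this cutoff affects only the reported edge list, not AUC of PRC.

Per-stage child seeds are derived from the master seed by fixed
(stage, item) keys, so any stage can be rerun in isolation and per-cluster
or per-merge results are independent of execution order.

## Evaluation

AUC of PRC is computed as average precision over all C(n,2) candidate
pairs ranked by score. Pairs sharing a score enter as one threshold group
and contribute the group's end-of-group cumulative precision. This tie
convention is load-bearing: the dominant group of unexamined (score-0)
pairs must not be ordered arbitrarily, and it makes a constant scorer
recover the class prevalence exactly — which is also why the random
baseline equals prevalence. ROC curves are deliberately not offered: at
prevalences of 10⁻⁴..10⁻² they are uninformative.

## Synthetic data generator

The generator defines the package's study conditions; it emulates, not
reproduces, the real pipeline inputs.

- **Atlas.** Pathway sizes are rounded lognormal (median = mean pathway
  size, log-sd = dispersion, floor 3); a fraction of each pathway's genes
  is reused from earlier pathways (overlap); within a pathway a
  preferential-attachment spanning tree is densified to the target mean
  degree. Desk-scale defaults — 10 pathways, mean size 30, overlap 0.1,
  mean degree 3, 20+20 samples — mirror the real benchmark's per-pathway
  scale (~34 genes per pathway) at about 1/34 of its total size.
- **Expression.** Each connected component is oriented away from a random
  root by BFS (the truth graph stays undirected; orientation exists only
  for simulation). Roots draw basal log2 abundances ~ N(7, 1); in the test
  condition a fraction of roots (default 0.5) shift their basal level by
  ±2 log2 units. A non-root's mean is its basal level times one Hill term
  per parent — v^h/(K^h+v^h) for activation, K^h/(K^h+v^h) for repression,
  h = 2, K = the parent's population median, activation/repression drawn
  per edge — so both perturbations and biological noise propagate
  downstream. Terms are floored at a leakage of 0.01 (basal leaky
  expression); without the floor, deviations amplify double-exponentially
  along deep chains (the activator tail has log-slope h) and underflow.
  Multiplicative lognormal biological noise (log-sd 0.2) applies before
  propagation; experimental noise (log-sd 0.1) applies last and does not
  propagate. Defaults were chosen once as moderate, realistic noise for
  simulated transcriptomics; the published simulator this emulates does not
  document its settings, so these are declared, not inferred.
- **Evidence.** Rows are all true edges plus a sampled multiple of
  non-edges (default 3×, without replacement); each evidence column is 1
  with per-type sensitivity on edges and false-positive rate on non-edges,
  independently.

What the generator does **not** model: hub-biased cross-pathway structure,
measurement-platform effects, correlated evidence types, batch effects,
unequal group sizes. Passing tests therefore demonstrate that the workflow
recovers planted structure under its own generative assumptions — a
necessary condition, not evidence about any particular real dataset.

## Problem sizes and numerics

Desk-scale runs (≈300 genes, B = 100 bootstraps, clusters of ~25) complete
in minutes on one CPU; the full-scale configuration (≈11k genes, B = 1000)
is the same code at larger B and K. Numerical conventions: natural-log
scores; move gains must exceed 10⁻⁹ to count as improvements (guards
against float noise between the vectorised and scalar scoring paths);
posterior clamp ε = 10⁻³; Tukey constants c = 5, ε = 10⁻⁴; BFS orientation
and all tie-breaks deterministic. Degenerate inputs (singleton clusters,
edgeless networks, constant gene vectors, all-identical strength sets,
folds with a single GI class) have defined behaviours with warnings rather
than failures.

## Known limitations

- The coexpression-evidence route is the package's committed reading of how
  expression profiles reach GI inference; alternatives (e.g. soft evidence
  on a continuous correlation node) are plausible.
- "Indirect" gene-to-map links in KGML are read as paths whose intermediate
  entries are all non-gene entries (compounds, groups); other readings of
  indirection exist.
- The significance threshold misbehaves on pure-noise strength sets (see
  above) — harmless in signal-bearing runs, visible in null experiments.
- Cross-linking of pathways requires reciprocal map references; one-sided
  references contribute no edges.
- Merging runs a single pass; no iterative re-merging.
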