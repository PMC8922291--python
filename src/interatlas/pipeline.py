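"""End-to-end atlas reconstruction workflow.

Cluster the genes on their fold-change profiles, learn a within-cluster
network for each cluster under the BNP prior, pick one representative gene
per cluster, learn the network of representatives, merge every pair of
clusters whose representatives are linked by re-learning on the union of
their genes, collect all bootstrap strengths observed for each gene pair,
aggregate them, and threshold the aggregated scores into the final atlas.

A pair inside a cluster that joined k merges accrues 1 + k strengths (the
within-cluster run plus one per merge); a cross-cluster pair accrues one
per merge that co-examined it; pairs never co-examined are absent and score
zero at evaluation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .bn_core import significance_threshold
from .bnp_prior import (
    BNPModel,
    EvidenceMatrix,
    add_coexpression,
    label_gi,
    learn_bnp,
)
from .clustering import GeneClustering, cluster_genes, n_clusters
from .netlearn import (
    FoldChangeObservations,
    GeneNetwork,
    learn_network,
    pairwise_fold_changes,
)
from .pathway_atlas import Atlas
from .representative import select_representative
from .synthetic_data import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AtlasConfig",
    "MergePlan",
    "AggregatedScores",
    "PipelineResult",
    "build_merge_plan",
    "merge_and_learn",
    "aggregate",
    "tukey_biweight",
    "build_atlas",
    "write_scores",
]

AGGREGATION_METHODS = ("first", "min", "max", "mean", "median", "tukey")


@dataclass
class AtlasConfig:
    """Run configuration for the full workflow."""

    expected_size: int = 25
    clustering_method: str = "hierarchical"
    aggregation: str = "mean"
    kappa: float = 1.0
    B: int = 100
    B_bnp: int | None = None  # defaults to B
    tau: float = 1.0
    rho0: float = 0.5
    seed: int = 0
    restarts: int = 0
    max_parents: int = 4

    def validate(self) -> None:
        if self.aggregation not in AGGREGATION_METHODS:
            raise ValueError(
                f"unknown aggregation method: {self.aggregation}"
            )
        if self.clustering_method not in ("hierarchical", "kmeans"):
            raise ValueError(
                f"unknown clustering method: {self.clustering_method}"
            )
        if self.B < 1 or (self.B_bnp is not None and self.B_bnp < 1):
            raise ValueError("bootstrap counts must be >= 1")
        if self.expected_size < 1:
            raise ValueError("expected_size must be >= 1")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AtlasConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for section in ("simulate", "clustering", "bnp", "learning",
                        "merge", "evaluate"):
            flat.update(raw.get(section, {}) or {})
        flat.update({k: v for k, v in raw.items() if not isinstance(v, dict)})
        known = {f for f in cls.__dataclass_fields__}
        cfg = cls(**{k: v for k, v in flat.items() if k in known})
        cfg.validate()
        return cfg


@dataclass
class MergePlan:
    """Which clusters merge, per the network of representative genes."""

    rep_network: GeneNetwork | None
    merge_pairs: list[tuple[int, int]]
    k_per_cluster: dict[int, int]

    def __post_init__(self) -> None:
        if len(set(self.merge_pairs)) != len(self.merge_pairs):
            raise ValueError("merge pairs must be deduplicated")
        for c, k in self.k_per_cluster.items():
            tally = sum(1 for p in self.merge_pairs if c in p)
            if tally != k:
                raise ValueError(f"k_per_cluster[{c}] != tally {tally}")


@dataclass
class AggregatedScores:
    """Per-pair strength lists and their aggregated score."""

    pairs: dict[tuple[str, str], tuple[list[float], float]]
    method: str

    def __post_init__(self) -> None:
        for pair, (lst, score) in self.pairs.items():
            if not lst:
                raise ValueError(f"empty strength list for {pair}")
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"aggregated score for {pair} outside [0,1]")

    def score_map(self) -> dict[tuple[str, str], float]:
        return {p: s for p, (_, s) in self.pairs.items()}


@dataclass
class PipelineResult:
    scores: AggregatedScores
    atlas: Atlas
    threshold: float
    provenance: dict = field(default_factory=dict)


def _stage_seed(master: int, *key: int) -> int:
    """Stable per-stage child seed; independent of execution order."""
    ss = np.random.SeedSequence((int(master),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# merge machinery


def build_merge_plan(
    expr: ExpressionMatrix,
    clustering: GeneClustering,
    representatives: Mapping[int, str],
    bnp: BNPModel | None,
    E: EvidenceMatrix | None,
    kappa: float = 1.0,
    B: int = 100,
    seed: int = 0,
    **learn_kwargs,
) -> MergePlan:
    """Learn the network of representative genes and derive merge pairs:
    one per significant edge between representatives."""
    k_per_cluster = {c: 0 for c in range(1, clustering.K + 1)}
    if clustering.K < 2:
        return MergePlan(None, [], k_per_cluster)
    rep_genes = sorted(set(representatives.values()))
    by_gene: dict[str, int] = {}
    for c, g in representatives.items():
        if g in by_gene:
            raise ValueError(f"gene {g} represents two clusters")
        by_gene[g] = c
    rep_net = learn_network(
        expr, rep_genes, bnp, kappa=kappa, B=B, seed=seed, E=E, **learn_kwargs
    )
    merge_pairs: list[tuple[int, int]] = []
    for a, b in sorted(rep_net.consensus_edges):
        ca, cb = by_gene[a], by_gene[b]
        pair = (min(ca, cb), max(ca, cb))
        if pair not in merge_pairs:
            merge_pairs.append(pair)
    for ca, cb in merge_pairs:
        k_per_cluster[ca] += 1
        k_per_cluster[cb] += 1
    return MergePlan(rep_net, merge_pairs, k_per_cluster)


def merge_and_learn(
    expr: ExpressionMatrix,
    cluster_a: Sequence[str],
    cluster_b: Sequence[str],
    bnp: BNPModel | None,
    E: EvidenceMatrix | None,
    kappa: float = 1.0,
    B: int = 100,
    seed: int = 0,
    **learn_kwargs,
) -> GeneNetwork:
    """Learn a network on the union of two clusters' genes; its strength
    table carries within-a, within-b, and cross pairs."""
    if set(cluster_a) & set(cluster_b):
        raise ValueError("clusters must be disjoint")
    union = sorted(set(cluster_a) | set(cluster_b))
    return learn_network(
        expr, union, bnp, kappa=kappa, B=B, seed=seed, E=E, **learn_kwargs
    )


# ---------------------------------------------------------------------------
# aggregation


def tukey_biweight(
    values: Sequence[float], c: float = 5.0, eps: float = 1e-4
) -> float:
    """One-step Tukey biweight location estimate: weights (1 - u^2)^2 for
    |u| < 1 with u = (x - median) / (c * MAD + eps)."""
    x = np.asarray(values, dtype=float)
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    u = (x - m) / (c * mad + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    if w.sum() == 0:
        return m
    return float(np.sum(w * x) / np.sum(w))


def aggregate(
    strength_lists: Mapping[tuple[str, str], Sequence[float]],
    method: str = "mean",
) -> AggregatedScores:
    """Collapse each pair's strength list to one score.

    ``first`` keeps the first recorded value (for within-cluster pairs the
    within-cluster-only run); min/max/mean/median as named; ``tukey`` is the
    one-step Tukey biweight with c=5.
    """
    if method not in AGGREGATION_METHODS:
        raise ValueError(f"unknown aggregation method: {method}")
    out: dict[tuple[str, str], tuple[list[float], float]] = {}
    for pair, lst in strength_lists.items():
        vals = [float(v) for v in lst]
        if not vals:
            raise ValueError(f"empty strength list for {pair}")
        if method == "first":
            score = vals[0]
        elif method == "min":
            score = min(vals)
        elif method == "max":
            score = max(vals)
        elif method == "mean":
            score = float(np.mean(vals))
        elif method == "median":
            score = float(np.median(vals))
        else:
            score = tukey_biweight(vals)
        out[pair] = (vals, float(np.clip(score, 0.0, 1.0)))
    return AggregatedScores(out, method)


# ---------------------------------------------------------------------------
# the full workflow


def build_atlas(
    expr: ExpressionMatrix,
    E: EvidenceMatrix,
    config: AtlasConfig,
    clustering: GeneClustering | None = None,
) -> PipelineResult:
    """Run the full divide-and-conquer reconstruction.

    ``clustering`` may be supplied to bypass the clustering stage (e.g. a
    planted partition for benchmarking); otherwise genes are clustered per
    the config. Deterministic given the config seed.
    """
    config.validate()
    seed = config.seed
    b_bnp = config.B_bnp if config.B_bnp is not None else config.B
    genes = expr.genes
    learn_kwargs = dict(
        tau=config.tau,
        rho0=config.rho0,
        restarts=config.restarts,
        max_parents=config.max_parents,
    )

    obs = pairwise_fold_changes(expr)

    if clustering is None:
        K = n_clusters(len(genes), config.expected_size)
        clustering = cluster_genes(
            obs,
            method=config.clustering_method,
            K=K,
            seed=_stage_seed(seed, 1),
            expected_size=config.expected_size,
        )
    logger.info("clustering: K=%d", clustering.K)

    E_feat = add_coexpression(E, expr, rho0=config.rho0)
    E_labeled = label_gi(E_feat)
    bnp = learn_bnp(E_labeled, B=b_bnp, seed=_stage_seed(seed, 2))
    logger.info(
        "BNP: %d consensus arcs, threshold %.3f",
        len(bnp.dag.arcs), bnp.threshold,
    )

    lists: dict[tuple[str, str], list[float]] = {}
    cluster_nets: dict[int, GeneNetwork] = {}
    for c in range(1, clustering.K + 1):
        members = clustering.members(c)
        net = learn_network(
            expr, members, bnp,
            kappa=config.kappa, B=config.B,
            seed=_stage_seed(seed, 3, c), E=E_labeled, **learn_kwargs,
        )
        cluster_nets[c] = net
        for pair, s in net.strengths.pairs.items():
            lists[pair] = [s]

    representatives = {
        c: select_representative(cluster_nets[c], obs)
        for c in cluster_nets
    }
    plan = build_merge_plan(
        expr, clustering, representatives, bnp, E_labeled,
        kappa=config.kappa, B=config.B, seed=_stage_seed(seed, 4),
        **learn_kwargs,
    )
    logger.info("merge plan: %d merges", len(plan.merge_pairs))

    for ca, cb in plan.merge_pairs:
        merged = merge_and_learn(
            expr, clustering.members(ca), clustering.members(cb), bnp,
            E_labeled, kappa=config.kappa, B=config.B,
            seed=_stage_seed(seed, 5, ca, cb), **learn_kwargs,
        )
        for pair, s in merged.strengths.pairs.items():
            lists.setdefault(pair, []).append(s)

    scores = aggregate(lists, config.aggregation)
    score_map = scores.score_map()
    threshold = significance_threshold(list(score_map.values()))
    edge_set = {p for p, s in score_map.items() if s > threshold}
    membership = {
        g: {f"cluster{clustering.labels[g]}"} for g in genes
    }
    atlas = Atlas(nodes=set(genes), edges=edge_set, membership=membership)
    provenance = {
        "config": asdict(config),
        "n_genes": len(genes),
        "K": clustering.K,
        "cluster_sizes": {
            c: len(clustering.members(c)) for c in range(1, clustering.K + 1)
        },
        "representatives": representatives,
        "merge_pairs": plan.merge_pairs,
        "k_per_cluster": plan.k_per_cluster,
        "bnp_threshold": bnp.threshold,
        "bnp_arcs": sorted(bnp.dag.arcs),
        "final_threshold": threshold,
        "n_scored_pairs": len(score_map),
        "n_final_edges": len(edge_set),
    }
    return PipelineResult(scores, atlas, threshold, provenance)


def write_scores(result: PipelineResult, path: str | Path) -> None:
    """Scores TSV: gene_a, gene_b, n_strengths, aggregated_score,
    significant."""
    with open(path, "w") as fh:
        fh.write(f"# significance_threshold\t{result.threshold:.6g}\n")
        fh.write("gene_a\tgene_b\tn_strengths\taggregated_score\tsignificant\n")
        for (a, b), (lst, score) in sorted(result.scores.pairs.items()):
            sig = int((a, b) in result.atlas.edges)
            fh.write(f"{a}\t{b}\t{len(lst)}\t{score:.6g}\t{sig}\n")
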