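"""Synthetic ground truth, expression, and evidence generators.

Everything downstream of the real KEGG/GEO-derived inputs can be exercised
on data produced here: a multi-pathway sparse atlas (pathway sizes drawn
lognormally, genes shared between pathways, edges by preferential
attachment), two-condition transcriptomic profiles propagated through the
atlas with Hill-type transfer kinetics, and a binary evidence matrix with
per-type sensitivity and false-positive rates.

Default desk-scale conditions: 10 pathways of mean size 30 with 10% gene
overlap and mean degree 3; 20 test and 20 control samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pathway_atlas import Atlas
from .bnp_prior import EvidenceMatrix

__all__ = [
    "AtlasSpec",
    "ExpressionMatrix",
    "EvidenceSpec",
    "generate_atlas",
    "simulate_expression",
    "generate_evidence",
    "write_expression",
    "read_expression",
    "DEFAULT_EVIDENCE_TYPES",
]

DEFAULT_EVIDENCE_TYPES = (
    "affinity_capture",
    "two_hybrid",
    "colocalization",
    "coexpression_db",
    "text_mining",
    "genetic_interaction",
    "orthology",
    "database_curated",
)


@dataclass(frozen=True)
class AtlasSpec:
    """Conditions for the synthetic ground-truth atlas."""

    n_pathways: int = 10
    mean_pathway_size: int = 30
    size_dispersion: float = 0.25
    overlap_fraction: float = 0.1
    mean_degree: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")
        if self.mean_pathway_size < 2:
            raise ValueError("mean pathway size must be >= 2")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.size_dispersion < 0:
            raise ValueError("size_dispersion must be nonnegative")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with a test/control sample design."""

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    group: dict[str, str]
    values: np.ndarray  # (n_genes, n_samples), positive

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape must be genes x samples")
        if (self.values <= 0).any():
            raise ValueError("abundances must be positive")
        groups = {self.group[s] for s in self.samples}
        if groups != {"test", "control"}:
            raise ValueError("both test and control groups must be nonempty")

    @property
    def test_samples(self) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.group[s] == "test")

    @property
    def control_samples(self) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.group[s] == "control")

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        gidx = {g: i for i, g in enumerate(self.genes)}
        rows = [gidx[g] for g in genes]
        return ExpressionMatrix(
            tuple(genes), self.samples, dict(self.group), self.values[rows]
        )


@dataclass(frozen=True)
class EvidenceSpec:
    """Conditions for the synthetic evidence matrix."""

    n_types: int = 8
    sensitivity: float = 0.8
    fpr: float = 0.05
    nonedge_sample_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError("need at least one evidence type")
        if not (0.0 <= self.fpr <= self.sensitivity <= 1.0):
            raise ValueError("require 0 <= fpr <= sensitivity <= 1")
        if self.nonedge_sample_factor < 0:
            raise ValueError("nonedge_sample_factor must be nonnegative")


# ---------------------------------------------------------------------------
# atlas generation


def generate_atlas(spec: AtlasSpec) -> Atlas:
    """Draw a multi-pathway ground-truth atlas.

    Pathway sizes are rounded lognormal (median ``mean_pathway_size``,
    log-sd ``size_dispersion``, floor 3); ``overlap_fraction`` of each later
    pathway's genes are reused from earlier pathways; within each pathway a
    preferential-attachment spanning tree is grown and densified to about
    ``mean_degree`` average degree. Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    membership: dict[str, set[str]] = {}
    pool: list[str] = []
    counter = 0
    for p in range(spec.n_pathways):
        pid = f"P{p + 1:03d}"
        if spec.size_dispersion > 0:
            size = int(round(rng.lognormal(
                math.log(spec.mean_pathway_size), spec.size_dispersion
            )))
        else:
            size = spec.mean_pathway_size
        size = max(size, 3)
        if spec.mean_degree >= size:
            raise ValueError(
                f"mean_degree {spec.mean_degree} infeasible for pathway of "
                f"size {size}"
            )
        n_shared = min(int(round(spec.overlap_fraction * size)), len(pool))
        shared = (
            list(rng.choice(pool, size=n_shared, replace=False))
            if n_shared
            else []
        )
        fresh = []
        for _ in range(size - n_shared):
            fresh.append(f"g{counter:05d}")
            counter += 1
        members = shared + fresh
        for g in members:
            membership.setdefault(g, set()).add(pid)
        nodes.update(members)
        pool.extend(fresh)
        edges |= _pathway_edges(members, spec.mean_degree, rng)
    return Atlas(nodes=nodes, edges=edges, membership=membership)


def _pathway_edges(
    members: Sequence[str], mean_degree: float, rng: np.random.Generator
) -> set[tuple[str, str]]:
    n = len(members)
    target = min(int(round(n * mean_degree / 2)), n * (n - 1) // 2)
    order = rng.permutation(n)
    deg = np.zeros(n, dtype=float)
    edges: set[tuple[int, int]] = set()

    def add(i: int, j: int) -> None:
        edges.add((min(i, j), max(i, j)))
        deg[i] += 1
        deg[j] += 1

    # preferential-attachment spanning tree
    for k in range(1, n):
        if len(edges) >= target:
            break
        prev = order[:k]
        w = deg[prev] + 1.0
        j = int(rng.choice(prev, p=w / w.sum()))
        add(int(order[k]), j)
    # densify preferentially
    attempts = 0
    while len(edges) < target and attempts < 50 * target + 1000:
        attempts += 1
        w = deg + 1.0
        i, j = rng.choice(n, size=2, replace=False, p=w / w.sum())
        key = (min(int(i), int(j)), max(int(i), int(j)))
        if key not in edges:
            add(*key)
    if len(edges) < target:  # dense corner: fill from the remaining pairs
        missing = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in edges
        ]
        pick = rng.choice(len(missing), size=target - len(edges), replace=False)
        for k in pick:
            add(*missing[int(k)])
    return {
        tuple(sorted((members[i], members[j]))) for i, j in edges
    }


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    atlas: Atlas,
    n_test: int = 20,
    n_control: int = 20,
    noise_bio: float = 0.2,
    noise_exp: float = 0.1,
    perturb_fraction: float = 0.5,
    seed: int = 0,
    basal_log2_mean: float = 7.0,
    basal_log2_sd: float = 1.0,
    perturb_log2_shift: float = 2.0,
    hill_coefficient: float = 2.0,
    leakage: float = 0.01,
) -> ExpressionMatrix:
    """Simulate two-condition transcriptomic abundances over the atlas.

    Each connected component is oriented away from a random root by
    breadth-first search (the truth graph itself stays undirected). Roots
    draw a basal log2 abundance; a ``perturb_fraction`` of roots receive a
    shifted basal level in the test condition (random sign). A non-root's
    mean is its basal level times one saturating Hill term per parent —
    activation v^h / (K^h + v^h) or repression K^h / (K^h + v^h) with h = 2
    and K the parent's population median — so regulatory influence and
    biological noise propagate downstream. Each regulation term is floored
    at ``leakage`` (basal leaky expression), which also keeps deviations
    from amplifying without bound along deep regulatory chains. Multiplicative lognormal
    biological noise (log-sd ``noise_bio``) is applied per gene and sample
    before propagation; experimental noise (log-sd ``noise_exp``) is applied
    last and does not propagate. All outputs are positive; deterministic
    given the seed.
    """
    if n_test < 1 or n_control < 1:
        raise ValueError("need at least one sample per group")
    if not atlas.nodes:
        raise ValueError("atlas is empty")
    rng = np.random.default_rng(seed)
    genes = tuple(sorted(atlas.nodes))
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    n_samples = n_test + n_control
    samples = tuple(
        [f"T{i + 1:02d}" for i in range(n_test)]
        + [f"C{i + 1:02d}" for i in range(n_control)]
    )
    group = {s: ("test" if s.startswith("T") else "control") for s in samples}
    is_test = np.array([group[s] == "test" for s in samples])

    adj: dict[int, list[int]] = {i: [] for i in range(n_genes)}
    for a, b in atlas.edges:
        adj[gidx[a]].append(gidx[b])
        adj[gidx[b]].append(gidx[a])

    # BFS orientation per component from a random root; parents precede
    # children in discovery order, so the oriented graph is acyclic and any
    # feedback edge simply becomes a forward arc
    order: list[int] = []
    parent_of: list[list[int]] = [[] for _ in range(n_genes)]
    visited = np.zeros(n_genes, dtype=bool)
    roots: list[int] = []
    for start in rng.permutation(n_genes):
        if visited[start]:
            continue
        roots.append(int(start))
        visited[start] = True
        queue = [int(start)]
        rank = {int(start): 0}
        while queue:
            v = queue.pop(0)
            order.append(v)
            for w in sorted(adj[v]):
                if not visited[w]:
                    visited[w] = True
                    rank[w] = len(rank)
                    queue.append(w)
        # orient every edge of the component from earlier- to later-discovered
        for v in rank:
            for w in adj[v]:
                if w in rank and rank[w] < rank[v]:
                    parent_of[v].append(w)

    basal_log2 = rng.normal(basal_log2_mean, basal_log2_sd, size=n_genes)
    n_perturb = int(round(perturb_fraction * len(roots)))
    if perturb_fraction > 0 and n_perturb == 0:
        n_perturb = 1
    perturbed = set(
        int(r)
        for r in rng.choice(roots, size=min(n_perturb, len(roots)),
                            replace=False)
    ) if n_perturb else set()
    shift_sign = {
        r: (1.0 if rng.random() < 0.5 else -1.0) for r in sorted(perturbed)
    }
    edge_sign: dict[tuple[int, int], float] = {}
    for v in range(n_genes):
        for p in sorted(parent_of[v]):
            edge_sign[(p, v)] = 1.0 if rng.random() < 0.5 else -1.0

    h = hill_coefficient
    values = np.zeros((n_genes, n_samples))
    bio = rng.normal(0.0, noise_bio, size=(n_genes, n_samples)) \
        if noise_bio > 0 else np.zeros((n_genes, n_samples))
    for v in order:
        mean_log2 = np.full(n_samples, basal_log2[v])
        if v in perturbed:
            mean_log2 = mean_log2 + shift_sign[v] * perturb_log2_shift * is_test
        row = np.exp2(mean_log2)
        for p in sorted(parent_of[v]):
            k = float(np.median(values[p]))
            ratio_h = (values[p] / k) ** h
            term = ratio_h / (1.0 + ratio_h) if edge_sign[(p, v)] > 0 \
                else 1.0 / (1.0 + ratio_h)
            row = row * np.clip(term, leakage, 1.0)
        values[v] = row * np.exp(bio[v])

    if noise_exp > 0:
        values = values * np.exp(
            rng.normal(0.0, noise_exp, size=values.shape)
        )
    return ExpressionMatrix(genes, samples, group, values)


# ---------------------------------------------------------------------------
# evidence generation


def generate_evidence(atlas: Atlas, spec: EvidenceSpec) -> EvidenceMatrix:
    """Draw a binary evidence matrix over the atlas's true edges plus a
    sample of non-edges.

    Rows are all true edges and ``nonedge_sample_factor x n_edges``
    uniformly sampled non-edges (no self-pairs, without replacement). Each
    evidence column is 1 with probability ``sensitivity`` on edge rows and
    ``fpr`` on non-edge rows, independently. Deterministic given the spec's
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes = sorted(atlas.nodes)
    n = len(genes)
    edge_set = set(atlas.edges)
    n_nonedge = int(round(spec.nonedge_sample_factor * len(edge_set)))
    n_possible = n * (n - 1) // 2 - len(edge_set)
    if n_nonedge > n_possible:
        raise ValueError(
            f"cannot sample {n_nonedge} non-edges; only {n_possible} exist"
        )
    nonedges: set[tuple[str, str]] = set()
    attempts = 0
    while len(nonedges) < n_nonedge:
        attempts += 1
        if attempts > 200 * max(n_nonedge, 1) + 10000:
            # dense graph: fall back to exhaustive enumeration
            remaining = [
                (genes[i], genes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if (genes[i], genes[j]) not in edge_set
                and (genes[i], genes[j]) not in nonedges
            ]
            pick = rng.choice(
                len(remaining), size=n_nonedge - len(nonedges), replace=False
            )
            nonedges.update(remaining[int(k)] for k in pick)
            break
        i, j = rng.choice(n, size=2, replace=False)
        pair = tuple(sorted((genes[int(i)], genes[int(j)])))
        if pair not in edge_set:
            nonedges.add(pair)

    pairs = sorted(edge_set) + sorted(nonedges)
    is_edge = np.array([p in edge_set for p in pairs])
    if spec.n_types <= len(DEFAULT_EVIDENCE_TYPES):
        names = DEFAULT_EVIDENCE_TYPES[: spec.n_types]
    else:
        names = tuple(f"evidence_{k + 1}" for k in range(spec.n_types))
    prob = np.where(is_edge[:, None], spec.sensitivity, spec.fpr)
    draws = (rng.random((len(pairs), spec.n_types)) < prob).astype(np.int8)
    df = pd.DataFrame(
        draws, index=pd.MultiIndex.from_tuples(pairs), columns=list(names)
    )
    return EvidenceMatrix(df)


# ---------------------------------------------------------------------------
# serialisation


def write_expression(
    expr: ExpressionMatrix, values_path: str | Path,
    design_path: str | Path | None = None,
) -> None:
    """TSV writer: genes in rows, one header row of sample ids; the optional
    side-car design table maps sample to group."""
    df = pd.DataFrame(
        expr.values, index=list(expr.genes), columns=list(expr.samples)
    )
    df.index.name = "gene"
    df.to_csv(values_path, sep="\t")
    if design_path is not None:
        with open(design_path, "w") as fh:
            fh.write("sample\tgroup\n")
            for s in expr.samples:
                fh.write(f"{s}\t{expr.group[s]}\n")


def read_expression(
    values_path: str | Path, design_path: str | Path
) -> ExpressionMatrix:
    df = pd.read_csv(values_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    group = {s: str(design.loc[s, "group"]) for s in df.columns}
    return ExpressionMatrix(
        tuple(df.index), tuple(df.columns), group, df.to_numpy()
    )
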