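"""Representative-gene selection from a cluster's learned network.

Each cluster is summarised by one gene so that a "network of clusters" can
be learned over real expression profiles (an eigengene or average profile
would have no entry in the knowledge base and so could not use the prior).
Selection runs a fixed battery of six centrality measures on the largest
connected component of the consensus network, picks the measure carrying
the largest absolute loading on the first principal component of the
standardized node-by-measure matrix, and takes the most central node under
that measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .netlearn import FoldChangeObservations, GeneNetwork

__all__ = [
    "CentralityProfile",
    "NoNetworkError",
    "centrality_battery",
    "most_informative_measure",
    "select_representative",
    "write_representatives",
]

BATTERY = (
    "degree",
    "betweenness",
    "closeness",
    "harmonic",
    "eigenvector",
    "pagerank",
)


class NoNetworkError(ValueError):
    """Raised when a network has no edges to compute centralities on."""


@dataclass
class CentralityProfile:
    nodes: tuple[str, ...]
    measures: tuple[str, ...]
    values: np.ndarray  # (n_nodes, n_measures)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.nodes), len(self.measures)):
            raise ValueError("values shape must be nodes x measures")
        if not np.isfinite(self.values).all():
            raise ValueError("centrality values must be finite")


def _largest_component(net: GeneNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.genes)
    g.add_edges_from(net.consensus_edges)
    if g.number_of_edges() == 0:
        raise NoNetworkError("network has no significant edges")
    comp = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    return g.subgraph(comp).copy()


def centrality_battery(net: GeneNetwork) -> CentralityProfile:
    """Compute the six-measure centrality battery on the largest connected
    component of the consensus network; measures undefined on the component
    are dropped."""
    g = _largest_component(net)
    nodes = tuple(sorted(g.nodes))
    columns: dict[str, dict] = {}
    columns["degree"] = nx.degree_centrality(g)
    columns["betweenness"] = nx.betweenness_centrality(g)
    columns["closeness"] = nx.closeness_centrality(g)
    columns["harmonic"] = nx.harmonic_centrality(g)
    if len(nodes) > 1:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # small-matrix solver switch
                columns["eigenvector"] = nx.eigenvector_centrality_numpy(g)
        except Exception:  # pragma: no cover - defensive
            pass
    columns["pagerank"] = nx.pagerank(g)
    measures = tuple(m for m in BATTERY if m in columns)
    values = np.array(
        [[columns[m][v] for m in measures] for v in nodes], dtype=float
    )
    return CentralityProfile(nodes, measures, values)


def most_informative_measure(profile: CentralityProfile) -> str:
    """Measure with the largest absolute loading on the first principal
    component of the standardized centrality matrix (constant columns
    dropped; ties resolved by battery order; all-constant profiles fall
    back to degree)."""
    if len(profile.nodes) < 2:
        return "degree"
    x = profile.values
    sd = x.std(axis=0)
    keep = sd > 1e-12
    if not keep.any():
        return "degree"
    names = [m for m, k in zip(profile.measures, keep) if k]
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    # PC1 loadings via SVD of the standardized matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    loadings = np.abs(vt[0])
    best = loadings.max()
    for name, l in zip(names, loadings):  # battery order breaks ties
        if l >= best - 1e-12:
            return name
    return names[int(np.argmax(loadings))]  # pragma: no cover


def select_representative(
    net: GeneNetwork, obs: FoldChangeObservations
) -> str:
    """The cluster's representative gene.

    Most central node of the largest component under the most informative
    measure; ties broken by higher degree then lexicographic order. For
    edgeless networks the gene with the highest total absolute correlation
    to the cluster's other members is used; a singleton cluster returns its
    only gene.
    """
    if len(net.genes) == 0:
        raise ValueError("empty gene set")
    if len(net.genes) == 1:
        return net.genes[0]
    try:
        profile = centrality_battery(net)
    except NoNetworkError:
        return _correlation_fallback(net, obs)
    measure = most_informative_measure(profile)
    col = profile.values[:, profile.measures.index(measure)]
    degree = {
        v: profile.values[i, profile.measures.index("degree")]
        for i, v in enumerate(profile.nodes)
    }
    best_val = col.max()
    candidates = [
        v for v, x in zip(profile.nodes, col) if x >= best_val - 1e-12
    ]
    candidates.sort(key=lambda v: (-degree[v], v))
    return candidates[0]


def _correlation_fallback(
    net: GeneNetwork, obs: FoldChangeObservations
) -> str:
    sub = obs.subset(net.genes)
    vectors = sub.gene_vectors()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vectors)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    totals = np.abs(corr).sum(axis=1)
    best = totals.max()
    candidates = sorted(
        g for g, t in zip(sub.genes, totals) if t >= best - 1e-12
    )
    return candidates[0]


def write_representatives(
    reps: Mapping[int, tuple[str, str]], path: str | Path
) -> None:
    """TSV of (cluster_id, gene, chosen_measure)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tgene\tchosen_measure\n")
        for cid in sorted(reps):
            gene, measure = reps[cid]
            fh.write(f"{cid}\t{gene}\t{measure}\n")
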