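"""Ground-truth interaction atlas construction from pathway graphs.

A pathway graph carries gene nodes, gene–gene edges, and "map" nodes that
reference other pathways. Merging pathways into an atlas unions the
per-pathway gene graphs and, for every pair of pathways that reference each
other, links the genes attached to the reciprocal map nodes: with G_XY the
genes of pathway X linked (directly or indirectly) to the map node for Y,
and G_YX defined symmetrically, every pair in G_XY x G_YX becomes an edge.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "PathwayGraph",
    "Atlas",
    "linked_gene_set",
    "merge_pathways",
    "read_kgml",
    "write_atlas",
    "read_atlas",
]


def _pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-loop on {a}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class PathwayGraph:
    """One pathway: gene nodes, intra-pathway gene edges, and references to
    other pathways via map nodes. ``gene_map_links`` maps (gene, referenced
    pathway id) to ``"direct"`` or ``"indirect"``."""

    pathway_id: str
    gene_nodes: frozenset[str]
    map_nodes: frozenset[str]
    gene_edges: frozenset[tuple[str, str]]
    gene_map_links: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        for a, b in self.gene_edges:
            if a not in self.gene_nodes or b not in self.gene_nodes:
                raise ValueError(f"edge ({a}, {b}) endpoint not a gene node")
            if a == b:
                raise ValueError(f"self-loop on {a}")
        for (g, m), kind in self.gene_map_links.items():
            if g not in self.gene_nodes:
                raise ValueError(f"link gene {g} not a gene node")
            if m not in self.map_nodes:
                raise ValueError(f"link target {m} not a map node")
            if kind not in ("direct", "indirect"):
                raise ValueError(f"link flag must be direct/indirect, got {kind}")


@dataclass
class Atlas:
    """Undirected gene–gene interaction graph with pathway memberships."""

    nodes: set[str]
    edges: set[tuple[str, str]]
    membership: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a >= b:
                raise ValueError(f"edge ({a}, {b}) endpoints not ordered")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) endpoint not a node")
        for g in self.nodes:
            if not self.membership.get(g):
                raise ValueError(f"node {g} has no pathway membership")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _pair(a, b) in self.edges


def linked_gene_set(p: PathwayGraph, target: str) -> set[str]:
    """Genes of pathway ``p`` linked (directly or indirectly) to the map
    node referencing pathway ``target`` — the set G_XY."""
    if target not in p.map_nodes:
        raise KeyError(
            f"pathway {p.pathway_id} has no map node for {target}"
        )
    return {g for (g, m) in p.gene_map_links if m == target}


def merge_pathways(pathways: Iterable[PathwayGraph]) -> Atlas:
    """Union the pathway gene graphs and add cross-pathway edges.

    For every unordered pathway pair {X, Y} where each references the other
    through a map node, all pairs in G_XY x G_YX become atlas edges
    (self-pairs excluded, duplicates collapsed). One-sided references add
    nothing.
    """
    pw = list(pathways)
    if not pw:
        raise ValueError("merge_pathways needs at least one pathway")
    ids = [p.pathway_id for p in pw]
    if len(set(ids)) != len(ids):
        raise ValueError("pathway ids must be unique")
    by_id = {p.pathway_id: p for p in pw}

    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    membership: dict[str, set[str]] = {}
    for p in pw:
        nodes |= p.gene_nodes
        edges |= set(p.gene_edges)
        for g in p.gene_nodes:
            membership.setdefault(g, set()).add(p.pathway_id)

    for x_id in sorted(by_id):
        x = by_id[x_id]
        for y_id in sorted(x.map_nodes):
            if y_id <= x_id or y_id not in by_id:
                continue
            y = by_id[y_id]
            if x_id not in y.map_nodes:
                continue  # reciprocity required
            g_xy = linked_gene_set(x, y_id)
            g_yx = linked_gene_set(y, x_id)
            for a in g_xy:
                for b in g_yx:
                    if a != b:
                        edges.add(_pair(a, b))
    return Atlas(nodes=nodes, edges=edges, membership=membership)


# ---------------------------------------------------------------------------
# KGML


def _strip_path_prefix(name: str) -> str:
    return name.split(":", 1)[1] if name.startswith("path:") else name


def read_kgml(path: str | Path) -> PathwayGraph:
    """Parse a KGML pathway file.

    Gene entries become gene nodes (an entry naming several genes yields all
    of them), map entries become map nodes, and relations between two gene
    entries become gene edges (all cross pairs for multi-gene entries). A
    gene is linked to a map node if a relation connects their entries
    directly, or indirectly through a chain of non-gene entries such as
    compounds or groups.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise ValueError(
            f"malformed KGML in {path} at line {line}, column {col}: {exc}"
        ) from exc
    root = tree.getroot()
    pathway_id = _strip_path_prefix(root.get("name", path.stem))

    entry_type: dict[str, str] = {}
    entry_genes: dict[str, tuple[str, ...]] = {}
    entry_map: dict[str, str] = {}
    for entry in root.iter("entry"):
        eid = entry.get("id")
        etype = entry.get("type", "")
        entry_type[eid] = etype
        if etype == "gene":
            entry_genes[eid] = tuple(entry.get("name", "").split())
        elif etype == "map":
            entry_map[eid] = _strip_path_prefix(entry.get("name", ""))

    adj: dict[str, set[str]] = {}
    for rel in root.iter("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        if e1 in entry_type and e2 in entry_type and e1 != e2:
            adj.setdefault(e1, set()).add(e2)
            adj.setdefault(e2, set()).add(e1)

    gene_nodes: set[str] = set()
    for genes in entry_genes.values():
        gene_nodes |= set(genes)
    map_nodes = {m for m in entry_map.values() if m}

    gene_edges: set[tuple[str, str]] = set()
    for e1, neighbours in adj.items():
        if entry_type.get(e1) != "gene":
            continue
        for e2 in neighbours:
            if entry_type.get(e2) != "gene" or e2 <= e1:
                continue
            for a in entry_genes[e1]:
                for b in entry_genes[e2]:
                    if a != b:
                        gene_edges.add(_pair(a, b))

    # gene -> map links: BFS from each map entry through non-gene entries
    links: dict[tuple[str, str], str] = {}
    for mid, map_name in entry_map.items():
        if not map_name:
            continue
        frontier = [mid]
        seen = {mid}
        depth = {mid: 0}
        while frontier:
            nxt: list[str] = []
            for e in frontier:
                for nb in adj.get(e, ()):
                    if nb in seen:
                        continue
                    seen.add(nb)
                    depth[nb] = depth[e] + 1
                    if entry_type.get(nb) == "gene":
                        kind = "direct" if depth[nb] == 1 else "indirect"
                        for g in entry_genes[nb]:
                            key = (g, map_name)
                            if links.get(key) != "direct":
                                links[key] = kind
                        # genes terminate the chain: no propagation through genes
                    else:
                        nxt.append(nb)
            frontier = nxt
    return PathwayGraph(
        pathway_id=pathway_id,
        gene_nodes=frozenset(gene_nodes),
        map_nodes=frozenset(map_nodes),
        gene_edges=frozenset(gene_edges),
        gene_map_links=links,
    )


# ---------------------------------------------------------------------------
# atlas serialisation


def write_atlas(atlas: Atlas, edges_path: str | Path,
                membership_path: str | Path | None = None) -> None:
    """Write a 2-column tab-separated edge list (lexicographic endpoints)
    and, optionally, a (gene, pathway_id) membership table."""
    with open(edges_path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(atlas.edges):
            fh.write(f"{a}\t{b}\n")
    if membership_path is not None:
        with open(membership_path, "w") as fh:
            fh.write("gene\tpathway_id\n")
            for g in sorted(atlas.nodes):
                for pid in sorted(atlas.membership[g]):
                    fh.write(f"{g}\t{pid}\n")


def read_atlas(edges_path: str | Path,
               membership_path: str | Path | None = None) -> Atlas:
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    with open(edges_path) as fh:
        next(fh)  # header
        for line in fh:
            a, b = line.rstrip("\n").split("\t")
            edges.add(_pair(a, b))
            nodes |= {a, b}
    membership: dict[str, set[str]] = {}
    if membership_path is not None:
        with open(membership_path) as fh:
            next(fh)
            for line in fh:
                g, pid = line.rstrip("\n").split("\t")
                nodes.add(g)
                membership.setdefault(g, set()).add(pid)
    else:
        membership = {g: {"unknown"} for g in nodes}
    for g in nodes:
        membership.setdefault(g, {"unknown"})
    return Atlas(nodes=nodes, edges=edges, membership=membership)
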