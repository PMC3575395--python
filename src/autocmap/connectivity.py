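"""Semantic connectivity map: MST filter over the weight-derived distances.

The minimum spanning tree keeps, of all N(N-1)/2 pairwise associations,
only the N-1 strongest links needed to connect every variable — the
skeleton of the association structure.  Edges carry the link strength
ls in [0, 1]; node degree in the tree is the hub score (high-degree
nodes organize the scheme).

The MST is computed by Kruskal's greedy algorithm over a *deterministic*
edge ordering — candidates sorted by (distance, name_a, name_b) — so that
tied distances always resolve the same way.  The tie-break is part of the
public contract, not an implementation detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .autocm import DistanceMatrix, LinkStrengthMatrix
from .preprocessing import display_value

EXPORT_FORMATS = ("graphml", "dot", "edge-tsv")


@dataclass
class ConnectivityMap:
    """The MST graph: nodes with polarity tags, edges with link strengths.

    ``edges`` holds ``(node_a, node_b, ls, distance)`` with node_a < node_b
    lexicographically within each edge, and the list sorted by descending
    ls (ties broken lexicographically).  ``hub_scores`` maps each node to
    its tree degree.
    """

    nodes: dict[str, str]
    edges: list[tuple[str, str, float, float]]
    hub_scores: dict[str, int] = field(default_factory=dict)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(dm: DistanceMatrix) -> list[tuple[str, str]]:
    """Kruskal MST over a symmetric zero-diagonal distance matrix.

    Returns the N-1 tree edges as ``(name_a, name_b)`` pairs with
    name_a < name_b, in selection order.  Candidate edges are considered
    in (distance, name_a, name_b) order, which makes the result unique
    and reproducible even under exact ties.
    """
    d = np.asarray(dm.values, dtype=float)
    names = list(dm.names)
    n = d.shape[0]
    if d.ndim != 2 or d.shape != (n, n) or len(names) != n:
        raise ValueError("distance matrix and names are inconsistent")
    if n < 2:
        raise ValueError("MST is undefined for fewer than 2 nodes")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.array_equal(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((names[i], names[j]))
            candidates.append((float(d[i, j]), a, b))
    candidates.sort()

    uf = _UnionFind(names)
    edges: list[tuple[str, str]] = []
    for _, a, b in candidates:
        if uf.union(a, b):
            edges.append((a, b))
            if len(edges) == n - 1:
                break
    return edges


def build_map(
    dm: DistanceMatrix,
    lsm: LinkStrengthMatrix,
    polarities: Mapping[str, str] | None = None,
) -> ConnectivityMap:
    """Assemble the connectivity map from distance and link-strength matrices.

    ``polarities`` tags each node high/low/indicator; if omitted, tags are
    inferred from the ``"high "`` / ``"low "`` name prefixes.
    """
    if list(dm.names) != list(lsm.names):
        raise ValueError("distance and link-strength matrices disagree on variables")
    names = list(dm.names)
    index = {name: i for i, name in enumerate(names)}

    def tag(name: str) -> str:
        if polarities is not None:
            return polarities[name]
        if name.startswith("high "):
            return "high"
        if name.startswith("low "):
            return "low"
        return "indicator"

    tree = minimum_spanning_tree(dm)
    edges = [
        (a, b, float(lsm.values[index[a], index[b]]), float(dm.values[index[a], index[b]]))
        for a, b in tree
    ]
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))

    degrees = {name: 0 for name in names}
    for a, b, _, _ in edges:
        degrees[a] += 1
        degrees[b] += 1

    return ConnectivityMap(
        nodes={name: tag(name) for name in names},
        edges=edges,
        hub_scores=degrees,
    )


def hub_scores(cmap: ConnectivityMap) -> dict[str, int]:
    """Node degrees in the tree; their sum is 2(N-1)."""
    degrees = {name: 0 for name in cmap.nodes}
    for a, b, _, _ in cmap.edges:
        degrees[a] += 1
        degrees[b] += 1
    return degrees


def to_networkx(cmap: ConnectivityMap) -> nx.Graph:
    """The map as a networkx Graph with node and edge attributes."""
    g = nx.Graph()
    for name, polarity in cmap.nodes.items():
        g.add_node(name, polarity=polarity, hub_degree=cmap.hub_scores.get(name, 0))
    for a, b, ls, dist in cmap.edges:
        g.add_edge(a, b, ls=ls, distance=dist)
    return g


def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def export_graph(cmap: ConnectivityMap, fmt: str, path: str | Path) -> Path:
    """Write the map as GraphML, DOT or a TSV edge list.

    GraphML keeps full precision and round-trips through
    :func:`read_graphml`; DOT labels edges with the two-decimal truncated
    link strength (display convention of the map figures); the TSV edge
    list keeps full precision.
    """
    path = Path(path)
    if not cmap.edges:
        raise ValueError("cannot export a map with no edges (MST undefined)")
    if fmt == "graphml":
        nx.write_graphml(to_networkx(cmap), path)
    elif fmt == "dot":
        lines = ["graph connectivity_map {"]
        for name, polarity in sorted(cmap.nodes.items()):
            lines.append(
                f"  {_dot_quote(name)} [polarity={_dot_quote(polarity)}, "
                f"hub_degree={cmap.hub_scores.get(name, 0)}];"
            )
        for a, b, ls, _ in cmap.edges:
            lines.append(
                f"  {_dot_quote(a)} -- {_dot_quote(b)} "
                f"[label={_dot_quote(display_value(ls))}];"
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "edge-tsv":
        rows = ["node_a\tnode_b\tlink_strength\tdistance"]
        rows += [f"{a}\t{b}\t{ls!r}\t{dist!r}" for a, b, ls, dist in cmap.edges]
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    else:
        raise ValueError(
            f"unknown export format {fmt!r}; options: {', '.join(EXPORT_FORMATS)}"
        )
    return path


def read_graphml(path: str | Path) -> ConnectivityMap:
    """Reconstruct a :class:`ConnectivityMap` from its GraphML export."""
    g = nx.read_graphml(path)
    nodes = {str(n): str(data["polarity"]) for n, data in g.nodes(data=True)}
    edges = []
    for a, b, data in g.edges(data=True):
        a, b = sorted((str(a), str(b)))
        edges.append((a, b, float(data["ls"]), float(data["distance"])))
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    hub = {str(n): int(data["hub_degree"]) for n, data in g.nodes(data=True)}
    return ConnectivityMap(nodes=nodes, edges=edges, hub_scores=hub)
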