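"""Minimum Spanning Tree backbone of the PLI network and its measures.

The MST connects all 16 electrode nodes with exactly 15 edges, chosen
by Kruskal's algorithm on edge costs ``1/PLI``: the strongest
functional connection (highest PLI, lowest cost) is added first, and
so on, skipping edges that would close a cycle.  Because the MST has a
fixed number of nodes and edges it is density-independent and
threshold-free, at the price of ignoring all non-backbone connections.

Ties in cost are broken lexicographically on the sorted label pair, so
the tree is reproducible even when PLI values collide.  The six tree
measures (with ``n = 16`` nodes, ``m = n − 1 = 15`` edges):

* ``Degr`` — maximum degree fraction, ``max_i degree_i / m``;
* ``Ecc``  — average eccentricity; per-node eccentricity is the
  longest hop path from that node to any other, divided by ``m``;
* ``BC``   — maximum betweenness fraction; per node, the number of the
  n(n−1)/2 unique tree paths having that node as an *interior* vertex,
  divided by n(n−1)/2 (every tree path is the shortest path);
* ``Leaf`` — leaf number (degree-1 nodes) over ``n``;
* ``Diam`` — tree diameter in hops over ``m``;
* ``TH``   — tree hierarchy, ``leaf_number / (2·(n−1)·BC)``, balancing
  star-like integration against overload of the central node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix

#: recorded in output metadata
MST_CONVENTIONS = {
    "cost": "1/PLI (zero-PLI edges carry infinite cost, considered last)",
    "tie_break": "lexicographic on the sorted (label_i, label_j) pair",
    "distances": "hop counts within the tree, normalized by m = n - 1",
    "betweenness": "interior-vertex path counting over all n(n-1)/2 tree paths",
}


@dataclass
class MSTResult:
    """A spanning tree over the analysis channels plus its measures."""

    channel_labels: tuple[str, ...]
    edges: list[tuple[str, str]]               # m sorted label pairs
    edge_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    degree: dict[str, int] = field(default_factory=dict)
    degree_fraction: dict[str, float] = field(default_factory=dict)
    ecc_node: dict[str, float] = field(default_factory=dict)
    bc_node: dict[str, float] = field(default_factory=dict)
    Degr: float = float("nan")
    Ecc: float = float("nan")
    BC: float = float("nan")
    Leaf: float = float("nan")
    Diam: float = float("nan")
    TH: float = float("nan")

    @property
    def n_nodes(self) -> int:
        return len(self.channel_labels)

    def as_dict(self) -> dict[str, float]:
        return {"Degr": self.Degr, "Ecc": self.Ecc, "BC": self.BC,
                "Leaf": self.Leaf, "Diam": self.Diam, "TH": self.TH}


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:      # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(cm: ConnectivityMatrix) -> MSTResult:
    """Kruskal's algorithm on costs ``1/PLI`` with deterministic ties.

    Zero-PLI pairs get infinite cost and are only used if nothing else
    connects the tree.  Raises if the graph cannot be spanned (some
    node pair has no connecting path even through zero-cost edges —
    impossible for a complete PLI matrix).
    """
    labels = cm.channel_labels
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 nodes to build a spanning tree")
    candidates = []
    for i in range(n):
        for j in range(i + 1, n):
            w = cm.values[i, j]
            cost = 1.0 / w if w > 0 else float("inf")
            a, b = sorted((labels[i], labels[j]))
            candidates.append((cost, a, b, w))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    uf = _UnionFind(labels)
    edges: list[tuple[str, str]] = []
    weights: dict[tuple[str, str], float] = {}
    for cost, a, b, w in candidates:
        if uf.union(a, b):
            edges.append((a, b))
            weights[(a, b)] = w
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        raise ValueError("input graph is disconnected; no spanning tree exists")
    return MSTResult(channel_labels=labels, edges=edges, edge_weights=weights)


def _adjacency(tree: MSTResult) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {lab: [] for lab in tree.channel_labels}
    for a, b in tree.edges:
        adj[a].append(b)
        adj[b].append(a)
    return adj


def _hop_distances(adj: dict[str, list[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _interior_path_counts(adj: dict[str, list[str]], labels) -> dict[str, int]:
    """Paths through each node as interior vertex, via subtree sizes.

    Removing node v splits the tree into components of sizes s_1..s_k;
    the number of unique paths with v strictly inside is
    Σ_{i<j} s_i s_j.
    """
    counts = {}
    for v in labels:
        sizes = []
        seen = {v}
        for nb in adj[v]:
            if nb in seen:
                continue
            # BFS the component containing nb with v removed
            comp = {nb}
            frontier = [nb]
            while frontier:
                nxt = []
                for u in frontier:
                    for w in adj[u]:
                        if w != v and w not in comp:
                            comp.add(w)
                            nxt.append(w)
                frontier = nxt
            sizes.append(len(comp))
            seen |= comp
        total = sum(sizes)
        counts[v] = (total * total - sum(s * s for s in sizes)) // 2
    return counts


def mst_measures(tree: MSTResult) -> MSTResult:
    """Fill in per-node and global MST measures (in place, returned).

    Validates the tree structure first (n−1 edges, connected, acyclic).
    """
    labels = tree.channel_labels
    n = len(labels)
    m = n - 1
    if len(tree.edges) != m:
        raise ValueError(f"not a spanning tree: {len(tree.edges)} edges for {n} nodes")
    adj = _adjacency(tree)
    dist0 = _hop_distances(adj, labels[0])
    if len(dist0) != n:
        raise ValueError("not a spanning tree: graph is disconnected")

    tree.degree = {lab: len(adj[lab]) for lab in labels}
    tree.degree_fraction = {lab: tree.degree[lab] / m for lab in labels}

    ecc_hops = {}
    diam_hops = 0
    for lab in labels:
        d = _hop_distances(adj, lab)
        e = max(d.values())
        ecc_hops[lab] = e
        diam_hops = max(diam_hops, e)
    tree.ecc_node = {lab: ecc_hops[lab] / m for lab in labels}

    n_paths = n * (n - 1) // 2
    interior = _interior_path_counts(adj, labels)
    tree.bc_node = {lab: interior[lab] / n_paths for lab in labels}

    leaf_number = sum(1 for lab in labels if tree.degree[lab] == 1)
    tree.Degr = max(tree.degree_fraction.values())
    tree.Ecc = float(np.mean(list(tree.ecc_node.values())))
    tree.BC = max(tree.bc_node.values())
    tree.Leaf = leaf_number / n
    tree.Diam = diam_hops / m
    tree.TH = leaf_number / (2.0 * m * tree.BC)
    return tree


def top_nodes(tree: MSTResult) -> tuple[list[str], list[str]]:
    """All nodes tied for the highest degree fraction and highest BC.

    A network with several nodes sharing the highest ranking returns
    them all (ties are included, not broken).
    """
    if not tree.degree_fraction:
        raise ValueError("call mst_measures before top_nodes")
    max_deg = max(tree.degree_fraction.values())
    max_bc = max(tree.bc_node.values())
    by_deg = [lab for lab in tree.channel_labels
              if tree.degree_fraction[lab] == max_deg]
    by_bc = [lab for lab in tree.channel_labels if tree.bc_node[lab] == max_bc]
    return by_deg, by_bc


def mst_from_matrix(cm: ConnectivityMatrix) -> MSTResult:
    """Convenience: build the MST and compute all measures."""
    return mst_measures(build_mst(cm))
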