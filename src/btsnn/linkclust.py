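"""Tanimoto hierarchical link clustering.

Communities are found over *links* rather than nodes: every edge starts
in its own cluster and pairs of edges sharing an endpoint are merged in
descending order of the Tanimoto similarity between the weighted
neighbor profiles of their two non-shared endpoints.  Cutting the merge
history at a similarity threshold yields link communities; the partition
density D scores a cut, and the community connectedness C_i scores how
strongly a single community talks to the rest of the network.

Definitions
-----------
Neighbor profile of node i: the vector a_i with a_i[j] = w_ij for
neighbors j, and a_i[i] = (1/k_i) Σ_{j in n(i)} w_ij, where
n(i) = {j : w_ij > 0} and k_i = |n(i)|.

Tanimoto similarity: S(a_i, a_j) = a_i·a_j / (|a_i|² + |a_j|² − a_i·a_j),
in (0, 1] for profiles with positive self terms.

Partition density: D = (2/M) Σ_c m_c (m_c + 1 − n_c) /
((n_c − 2)(n_c − 1)); a single-link cluster (n_c = 2) contributes 0.

Community connectedness: C_i = (n_i − 1) e_b(i) / (2 e_w(i) d̂), where
e_w(i) = m_i is the cluster's internal link count, e_b(i) the number of
outside links touching the cluster's node set, and d̂ = 2M/N the
whole-network average degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import WeightedGraph

__all__ = [
    "NeighborProfile",
    "LinkDendrogram",
    "LinkPartition",
    "neighbor_profile",
    "tanimoto_similarity",
    "link_pair_similarities",
    "hierarchical_link_clustering",
    "cut_dendrogram",
    "partition_density",
    "density_profile",
    "best_density_cut",
    "community_connectedness",
]

Link = tuple[str, str]


@dataclass
class NeighborProfile:
    """Weighted first-order neighborhood vector of one node."""

    node: str
    values: dict[str, float]
    k: int


@dataclass
class LinkDendrogram:
    """Merge history of the agglomeration over links.

    ``links`` lists all edges (leaves) in lexicographic order; leaf
    ``i`` is cluster id ``i``.  Each merge ``(a, b, h)`` joins clusters
    ``a`` and ``b`` at similarity height ``h``, creating cluster id
    ``len(links) + merge_index``.  Heights are non-increasing.
    """

    links: list[Link]
    merges: list[tuple[int, int, float]]

    @property
    def M(self) -> int:
        return len(self.links)


@dataclass
class LinkPartition:
    """Link communities at a fixed cut, with per-cluster statistics."""

    clusters: list[list[Link]]
    threshold: float
    M: int
    m: list[int] = field(init=False)
    n: list[int] = field(init=False)
    e_w: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.m = [len(c) for c in self.clusters]
        self.n = [len({x for lk in c for x in lk}) for c in self.clusters]
        self.e_w = list(self.m)
        if sum(self.m) != self.M:
            raise ValueError("clusters do not partition the link set")

    def node_sets(self) -> list[set[str]]:
        return [{x for lk in c for x in lk} for c in self.clusters]

    def e_b(self, i: int) -> int:
        """Links outside cluster i that touch cluster i's node set."""
        nodes = {x for lk in self.clusters[i] for x in lk}
        inside = set(self.clusters[i])
        return sum(
            1
            for c in self.clusters
            for lk in c
            if lk not in inside and (lk[0] in nodes or lk[1] in nodes)
        )

    @property
    def D(self) -> float:
        return partition_density(self)


def neighbor_profile(g: WeightedGraph, i: str) -> NeighborProfile:
    """Weighted neighborhood vector a_i of node ``i``.

    Raises on isolated nodes: a node with no links has no profile.
    """
    nbrs = g.neighbors(i)
    if not nbrs:
        raise ValueError(f"isolated node {i!r} has no neighbor profile")
    values = {j: g.weight(i, j) for j in nbrs}
    values[i] = sum(values.values()) / len(nbrs)
    return NeighborProfile(node=i, values=values, k=len(nbrs))


def tanimoto_similarity(a_i: NeighborProfile, a_j: NeighborProfile) -> float:
    """S = a_i·a_j / (|a_i|² + |a_j|² − a_i·a_j), absent keys read as 0."""
    dot = sum(v * a_j.values.get(k, 0.0) for k, v in a_i.values.items())
    sq_i = sum(v * v for v in a_i.values.values())
    sq_j = sum(v * v for v in a_j.values.values())
    denom = sq_i + sq_j - dot
    if denom <= 0.0:
        raise ValueError("all-zero profiles have undefined similarity")
    return dot / denom


def link_pair_similarities(
    g: WeightedGraph,
) -> list[tuple[Link, Link, float]]:
    """Similarity for every unordered pair of links sharing an endpoint.

    For links (i, k) and (j, k) with shared node k, S is computed
    between the profiles of the non-shared endpoints i and j.
    """
    profiles = {u: neighbor_profile(g, u) for u in g.nodes if g.neighbors(u)}
    incident: dict[str, list[Link]] = {}
    for lk in g.links():
        incident.setdefault(lk[0], []).append(lk)
        incident.setdefault(lk[1], []).append(lk)
    out: list[tuple[Link, Link, float]] = []
    for k, links in incident.items():
        for a in range(len(links)):
            for b in range(a + 1, len(links)):
                la, lb = links[a], links[b]
                i = la[0] if la[1] == k else la[1]
                j = lb[0] if lb[1] == k else lb[1]
                s = tanimoto_similarity(profiles[i], profiles[j])
                out.append((la, lb, s) if la < lb else (lb, la, s))
    return out


def hierarchical_link_clustering(g: WeightedGraph) -> LinkDendrogram:
    """Single-linkage agglomeration of links by Tanimoto similarity.

    Every link starts as its own cluster; adjacent link pairs are
    visited in descending similarity (ties broken lexicographically by
    link labels for determinism) and their clusters merged, recording
    the pair's similarity as the merge height.  Pairs already
    co-clustered are skipped.
    """
    links = g.links()
    if not links:
        raise ValueError("graph has no links to cluster")
    index = {lk: i for i, lk in enumerate(links)}
    pairs = link_pair_similarities(g)
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))

    # union-find with explicit dendrogram cluster ids (scipy convention:
    # leaves 0..M-1, merge j creates id M+j)
    parent = list(range(len(links)))
    cluster_id = list(range(len(links)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merges: list[tuple[int, int, float]] = []
    for la, lb, s in pairs:
        ra, rb = find(index[la]), find(index[lb])
        if ra == rb:
            continue
        merges.append((cluster_id[ra], cluster_id[rb], s))
        parent[rb] = ra
        cluster_id[ra] = len(links) + len(merges) - 1
    return LinkDendrogram(links=links, merges=merges)


def cut_dendrogram(d: LinkDendrogram, height: float) -> LinkPartition:
    """Apply exactly the merges with similarity >= ``height``.

    ``height`` is a similarity threshold in [0, 1]; at 1 + epsilon
    behavior, i.e. height 1.0 with no S = 1 pairs, every link is its
    own cluster; at 0 the partition is the connected components of the
    line graph.
    """
    if not 0.0 <= height <= 1.0:
        raise ValueError("cut height must lie in [0, 1]")
    parent = list(range(len(d.links)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # merge j joined the clusters whose current ids were (a, b); replay
    # in order, tracking which leaf represents each dendrogram id
    rep = {i: i for i in range(len(d.links))}
    for j, (a, b, h) in enumerate(d.merges):
        new_id = len(d.links) + j
        ra, rb = find(rep[a]), find(rep[b])
        if h >= height:
            parent[rb] = ra
        rep[new_id] = ra

    groups: dict[int, list[Link]] = {}
    for i, lk in enumerate(d.links):
        groups.setdefault(find(i), []).append(lk)
    clusters = [sorted(groups[r]) for r in sorted(groups)]
    return LinkPartition(clusters=clusters, threshold=height, M=d.M)


def partition_density(p: LinkPartition) -> float:
    """D = (2/M) Σ_c m_c (m_c + 1 − n_c) / ((n_c − 2)(n_c − 1)).

    Single-link clusters (n_c = 2) contribute 0: the normalization is
    undefined there.  D = 1 iff every non-singleton cluster is the full
    link set of a clique.
    """
    if p.M == 0:
        raise ValueError("partition of an empty link set has no density")
    total = 0.0
    for m_c, n_c in zip(p.m, p.n):
        if n_c == 2:
            continue
        total += m_c * (m_c + 1 - n_c) / ((n_c - 2) * (n_c - 1))
    return 2.0 * total / p.M


def density_profile(
    d: LinkDendrogram, heights: np.ndarray | list[float]
) -> list[tuple[float, float]]:
    """Partition density at each cut height (piecewise constant between
    consecutive merge heights)."""
    return [(float(h), cut_dendrogram(d, float(h)).D) for h in heights]


def best_density_cut(
    d: LinkDendrogram, extra_heights: list[float] | None = None
) -> tuple[float, LinkPartition]:
    """Cut at the merge height maximizing D (ties -> larger height)."""
    candidates = sorted({h for _, _, h in d.merges} | {1.0} | set(extra_heights or []))
    best_h, best_p, best_d = 1.0, cut_dendrogram(d, 1.0), -np.inf
    for h in reversed(candidates):
        p = cut_dendrogram(d, h)
        if p.D > best_d:
            best_h, best_p, best_d = h, p, p.D
    return best_h, best_p


def community_connectedness(
    p: LinkPartition, i: int, g: WeightedGraph
) -> float:
    """C_i = (n_i − 1) e_b(i) / (2 e_w(i) d̂) for cluster ``i``.

    Higher values mean more external links per internal link; isolated
    components score 0.
    """
    d_hat = g.avg_degree
    if d_hat <= 0:
        raise ValueError("average degree is zero")
    return (p.n[i] - 1) * p.e_b(i) / (2.0 * p.e_w[i] * d_hat)
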