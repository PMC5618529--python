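"""IPC-MCE: maximal-clique enumeration with neighbourhood extension.

The pipeline removes degree-1 nodes, enumerates maximal cliques of at least
``min_clique`` nodes, extends each clique K with every neighbourhood vertex
v whose interaction probability IP_vK = |E(v,K)| / |K| reaches the threshold
t (all candidates judged against the original clique, so the result does not
depend on iteration order), and finally discards near-duplicate extended
clusters by ω overlap, keeping larger clusters first.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_core import (
    Cluster,
    ClusteringResult,
    Network,
    cluster_sort_key,
    maximal_cliques,
    overlap_omega,
)

__all__ = ["MceParams", "prune_degree_one", "ip_vk", "ipcmce"]


@dataclass
class MceParams:
    """IPC-MCE parameters: extension threshold t in (0, 1], ω de-duplication
    threshold, minimum clique size, and whether degree-1 pruning is iterated
    to the 2-core instead of the default single pass."""

    t: float = 0.5
    overlap_threshold: float = 0.8
    min_clique: int = 3
    iterate_pruning: bool = False

    def __post_init__(self):
        if not 0 < self.t <= 1:
            raise ValueError("t must be in (0, 1]")
        if self.min_clique < 2:
            raise ValueError("min_clique must be >= 2")


def prune_degree_one(net: Network, *, iterate: bool = False) -> Network:
    """Drop nodes with exactly one neighbour (single pass by default).

    With ``iterate=True`` pruning repeats until no degree-1 node remains
    (the 2-core plus isolated survivors).
    """
    keep = {v for v in net.nodes if net.degree(v) != 1}
    sub = net.graph.subgraph(keep)
    pruned = Network(
        ((u, v, d["weight"]) for u, v, d in sub.edges(data=True)), nodes=keep
    )
    if iterate and pruned.number_of_nodes() != net.number_of_nodes():
        again = prune_degree_one(pruned, iterate=True)
        if again.number_of_nodes() != pruned.number_of_nodes():
            return again
    return pruned


def ip_vk(net: Network, v: str, clique: frozenset[str] | set[str]) -> float:
    """Interaction probability of v against a node set K: |E(v,K)| / |K|."""
    k = frozenset(clique)
    if not k:
        raise ValueError("K must be non-empty")
    if v in k:
        raise ValueError(f"{v!r} is already in K")
    net._require_node(v)
    e_vk = sum(1 for x in net.graph[v] if x in k)
    return e_vk / len(k)


def ipcmce(net: Network, params: MceParams | None = None) -> ClusteringResult:
    """IPC-MCE: prune, enumerate maximal cliques, extend, de-duplicate."""
    params = params or MceParams()
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    pruned = prune_degree_one(net, iterate=params.iterate_pruning)
    extended: list[frozenset[str]] = []
    if pruned.number_of_edges():
        for clique in maximal_cliques(pruned, min_size=params.min_clique):
            neighbourhood = set()
            for m in clique:
                neighbourhood.update(x for x in pruned.graph[m] if x not in clique)
            # simultaneous extension against the original clique
            ext = clique | {
                v for v in neighbourhood if ip_vk(pruned, v, clique) >= params.t
            }
            if ext not in extended:
                extended.append(ext)
    extended.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    kept: list[frozenset[str]] = []
    for c in extended:
        if all(overlap_omega(c, k) < params.overlap_threshold for k in kept):
            kept.append(c)
    clusters = [Cluster.from_members(net, c) for c in kept]
    clusters.sort(key=cluster_sort_key("score"))
    return ClusteringResult(
        "IPC-MCE",
        {
            "t": params.t,
            "overlap": params.overlap_threshold,
            "min_clique": params.min_clique,
        },
        clusters,
    )
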