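"""Hierarchical agglomerative module detection: HC-PIN and OH-PIN.

HC-PIN agglomerates singleton clusters along edges ranked by a triangle-
support clustering value, freezing a cluster once it is a λ-module (every
member's weighted internal degree is at least λ times its external degree).
It yields non-overlapping clusters. OH-PIN seeds one candidate cluster per
edge (the edge's endpoints plus their common neighbours, its B_Cluster),
merges highly overlapping candidates, and then assembles the survivors into
λ-modules; its output may overlap.

λ = 0 expresses "no cohesion requirement": module locking is disabled and
HC-PIN agglomerates along every inter-cluster edge, returning the connected
components of size ≥ s.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_core import (
    Cluster,
    ClusteringResult,
    Network,
    cluster_sort_key,
    common_neighbors,
    in_out_degree,
    overlap_min,
    overlap_omega,
)

__all__ = [
    "LambdaParams",
    "OhpinParams",
    "clustering_value",
    "edge_queue",
    "is_lambda_module",
    "b_cluster",
    "hcpin",
    "ohpin",
    "ohpin_candidates",
]


@dataclass
class LambdaParams:
    """HC-PIN parameters: cohesion ratio λ ≥ 0 and minimum output size s ≥ 2."""

    lam: float = 1.0
    s: int = 3

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.s < 2:
            raise ValueError("s must be >= 2")


@dataclass
class OhpinParams:
    """OH-PIN parameters: λ, s, and the B_Cluster merge threshold in (0, 1]."""

    lam: float = 1.0
    s: int = 3
    overlap_threshold: float = 0.5

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.s < 2:
            raise ValueError("s must be >= 2")
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0, 1]")


def clustering_value(net: Network, u: str, v: str) -> float:
    """Triangle-support clustering value of an edge.

    CV(u,v) = (Σ_{x∈N(u)∩N(v)} (w(u,x)+w(x,v))/2 + w(u,v))
              / min(S(u)−w(u,v), S(v)−w(u,v))

    with S the weighted degree. On unit weights this reduces to the classic
    edge-clustering coefficient (z+1)/min(d_u−1, d_v−1) with z the number of
    triangles through the edge. A zero denominator (pendant endpoint) returns
    the raw numerator, ranking such edges by their absolute support.
    """
    if not net.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge")
    w_uv = net.weight(u, v)
    num = w_uv
    for x in common_neighbors(net, u, v):
        num += (net.weight(u, x) + net.weight(x, v)) / 2.0
    den = min(net.degree(u, weighted=True), net.degree(v, weighted=True)) - w_uv
    if den <= 0:
        return num
    return num / den


def edge_queue(net: Network) -> list[tuple[str, str, float]]:
    """All edges as (u, v, cv), non-increasing by clustering value.

    Ties break on higher edge weight, then the lexicographic endpoint pair.
    """
    entries = []
    for u, v, w in net.edges():
        entries.append((u, v, clustering_value(net, u, v), w))
    entries.sort(key=lambda e: (-e[2], -e[3], e[0], e[1]))
    return [(u, v, cv) for u, v, cv, _ in entries]


def is_lambda_module(net: Network, members, lam: float) -> bool:
    """True iff every member's weighted internal degree ≥ λ × its external degree."""
    ms = frozenset(members)
    if not ms:
        raise ValueError("members must be non-empty")
    for v in ms:
        d_in, d_out = in_out_degree(net, v, ms)
        if d_in < lam * d_out:
            return False
    return True


def _locked(net: Network, members: frozenset[str], lam: float) -> bool:
    # λ = 0 disables locking so that agglomeration runs to completion.
    return lam > 0 and is_lambda_module(net, members, lam)


def hcpin(net: Network, params: LambdaParams | None = None) -> ClusteringResult:
    """HC-PIN: non-overlapping λ-module agglomeration.

    Every vertex starts as a singleton cluster; edges are processed in
    non-increasing clustering-value order and merge their endpoint clusters
    unless both are already λ-modules. Clusters of size ≥ s are returned,
    sorted by score descending.
    """
    params = params or LambdaParams()
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    parent: dict[str, str] = {v: v for v in net.nodes}
    members: dict[str, frozenset[str]] = {v: frozenset((v,)) for v in net.nodes}
    locked: dict[str, bool] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v, _cv in edge_queue(net):
        ru, rv = find(u), find(v)
        if ru == rv:
            continue
        if ru not in locked:
            locked[ru] = _locked(net, members[ru], params.lam)
        if rv not in locked:
            locked[rv] = _locked(net, members[rv], params.lam)
        if locked[ru] and locked[rv]:
            continue
        if len(members[ru]) < len(members[rv]):
            ru, rv = rv, ru
        parent[rv] = ru
        members[ru] = members[ru] | members[rv]
        del members[rv]
        locked.pop(rv, None)
        locked[ru] = _locked(net, members[ru], params.lam)

    clusters = [
        Cluster.from_members(net, ms)
        for root, ms in members.items()
        if find(root) == root and len(ms) >= params.s
    ]
    clusters.sort(key=cluster_sort_key("score"))
    return ClusteringResult("HC-PIN", {"lambda": params.lam, "s": params.s}, clusters)


def b_cluster(net: Network, u: str, v: str) -> frozenset[str]:
    """The B_Cluster of an edge: its endpoints plus their common neighbours."""
    if not net.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge")
    return frozenset({u, v} | common_neighbors(net, u, v))


def _canon(s: frozenset[str]) -> tuple[str, ...]:
    return tuple(sorted(s))


def _insert_maximal(cands: list[frozenset[str]], new: frozenset[str]) -> None:
    """Insert keeping the collection subset-free (drop dominated members)."""
    for c in cands:
        if new <= c:
            return
    cands[:] = [c for c in cands if not c < new]
    cands.append(new)


def _inter_edges(net: Network, a: frozenset[str], b: frozenset[str]) -> int:
    """Edges connecting A and B, excluding edges internal to A∩B."""
    both = a & b
    count = 0
    for x, y, _w in net.edges():
        if x in both and y in both:
            continue
        if (x in a and y in b) or (x in b and y in a):
            count += 1
    return count


def ohpin_candidates(net: Network, overlap_threshold: float = 0.5) -> list[frozenset[str]]:
    """OH-PIN steps 1–2: the subset-free B_Cluster collection after merging
    every pair with overlap_min ≥ overlap_threshold to a fixpoint.

    Merge order: higher overlap_min first, then higher overlap_omega, then
    the lexicographic pair of canonical member tuples.
    """
    cands: list[frozenset[str]] = []
    for u, v, _w in net.edges():
        _insert_maximal(cands, b_cluster(net, u, v))

    def pair_key(a: frozenset[str], b: frozenset[str]):
        ca, cb = sorted((_canon(a), _canon(b)))
        return (-overlap_min(a, b), -overlap_omega(a, b), ca, cb)

    while True:
        best = None
        best_key = None
        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                if overlap_min(cands[i], cands[j]) >= overlap_threshold:
                    k = pair_key(cands[i], cands[j])
                    if best_key is None or k < best_key:
                        best_key = k
                        best = (i, j)
        if best is None:
            return cands
        i, j = best
        merged = cands[i] | cands[j]
        rest = [c for k, c in enumerate(cands) if k not in (i, j)]
        cands = []
        for c in rest:
            _insert_maximal(cands, c)
        _insert_maximal(cands, merged)


def ohpin(net: Network, params: OhpinParams | None = None) -> ClusteringResult:
    """OH-PIN: overlapping hierarchical module detection.

    1. Seed one B_Cluster per edge, kept subset-free.
    2. Merge, highest overlap first, any candidate pair with
       overlap_min ≥ overlap_threshold until none remains.
    3. While a candidate fails the λ-module test, merge the connected pair
       (≥ 1 inter-cluster edge, at least one non-module) with the largest
       connectivity Conn(A,B) = |E(A,B)| / min(|A|,|B|).
    4. Output clusters of size ≥ s sorted by score descending; they may overlap.
    """
    params = params or OhpinParams()
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")

    cands = ohpin_candidates(net, params.overlap_threshold)

    # Step 3: assemble into λ-modules (skipped when λ = 0: nothing fails).
    if params.lam > 0:
        while True:
            bad = {
                k for k, c in enumerate(cands) if not is_lambda_module(net, c, params.lam)
            }
            if not bad:
                break
            best = None
            best_key = None
            for i in range(len(cands)):
                for j in range(i + 1, len(cands)):
                    if i not in bad and j not in bad:
                        continue
                    ne = _inter_edges(net, cands[i], cands[j])
                    if ne == 0:
                        continue
                    conn = ne / min(len(cands[i]), len(cands[j]))
                    ca, cb = sorted((_canon(cands[i]), _canon(cands[j])))
                    k = (-conn, ca, cb)
                    if best_key is None or k < best_key:
                        best_key = k
                        best = (i, j)
            if best is None:
                break
            i, j = best
            merged = cands[i] | cands[j]
            rest = [c for k, c in enumerate(cands) if k not in (i, j)]
            cands = []
            for c in rest:
                _insert_maximal(cands, c)
            _insert_maximal(cands, merged)

    clusters = [Cluster.from_members(net, c) for c in cands if len(c) >= params.s]
    clusters.sort(key=cluster_sort_key("score"))
    return ClusteringResult(
        "OH-PIN",
        {"lambda": params.lam, "s": params.s, "overlap": params.overlap_threshold},
        clusters,
    )
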