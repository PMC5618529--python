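"""Graph data model and the topological metrics shared by all clustering algorithms.

Biological networks are modelled as simple undirected graphs whose nodes are
molecule identifiers (proteins, genes, OTUs, ...) and whose edges optionally
carry a positive weight — an interaction confidence, a correlation, or, for
uncertain graphs, an existence probability in (0, 1].

Every complex-detection algorithm in this package consumes the primitives
defined here: induced-subgraph density, common neighbourhoods, weighted
in/out degrees relative to a candidate cluster, bounded-diameter checks,
maximal-clique enumeration, and the two overlap scores used to merge or
deduplicate clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "UncertainNetwork",
    "Cluster",
    "ClusteringResult",
    "density",
    "common_neighbors",
    "in_out_degree",
    "induced_diameter_at_most",
    "maximal_cliques",
    "overlap_omega",
    "overlap_min",
    "cluster_metrics",
]

EdgeSpec = tuple  # (u, v) or (u, v, weight)


class Network:
    """Simple undirected, positively weighted graph.

    Invariants enforced at construction: no self-loops, no duplicate edges,
    every edge weight strictly positive, every endpoint a node. Unweighted
    edges default to weight 1.0. Instances are treated as immutable by the
    rest of the package.
    """

    __slots__ = ("_g",)

    def __init__(self, edges: Iterable[EdgeSpec] = (), nodes: Iterable[str] = ()):
        g = nx.Graph()
        for n in nodes:
            g.add_node(str(n))
        for e in edges:
            if len(e) == 2:
                u, v = e
                w = 1.0
            elif len(e) == 3:
                u, v, w = e
            else:
                raise ValueError(f"edge must be (u, v) or (u, v, weight), got {e!r}")
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop on {u!r} is not allowed")
            if g.has_edge(u, v):
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            w = float(w)
            if not w > 0:
                raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {w}")
            self._check_weight(u, v, w)
            g.add_edge(u, v, weight=w)
        self._g = g

    def _check_weight(self, u: str, v: str, w: float) -> None:  # hook for subclasses
        pass

    # -- basic queries ----------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The backing networkx graph (read-only by convention)."""
        return self._g

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, v: str) -> bool:
        return self._g.has_node(v)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        try:
            return self._g[u][v]["weight"]
        except KeyError:
            raise ValueError(f"({u!r}, {v!r}) is not an edge") from None

    def neighbors(self, v: str) -> set[str]:
        self._require_node(v)
        return set(self._g[v])

    def degree(self, v: str, *, weighted: bool = False) -> float:
        self._require_node(v)
        if weighted:
            return float(self._g.degree(v, weight="weight"))
        return float(self._g.degree(v))

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Edges as (u, v, weight) with u < v, in lexicographic order."""
        for u, v, w in sorted(
            (min(a, b), max(a, b), d["weight"]) for a, b, d in self._g.edges(data=True)
        ):
            yield u, v, w

    def _require_node(self, v: str) -> None:
        if not self._g.has_node(v):
            raise ValueError(f"unknown node {v!r}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<{type(self).__name__} |V|={self.number_of_nodes()} "
            f"|E|={self.number_of_edges()}>"
        )


class UncertainNetwork(Network):
    """A network whose edge weights are existence probabilities in (0, 1]."""

    __slots__ = ()

    def _check_weight(self, u: str, v: str, w: float) -> None:
        if w > 1.0:
            raise ValueError(
                f"edge ({u!r}, {v!r}) has probability {w} > 1 in an uncertain graph"
            )


def _member_set(net: Network, members: Iterable[str]) -> frozenset[str]:
    ms = frozenset(members)
    for v in ms:
        if not net.has_node(v):
            raise ValueError(f"unknown node {v!r}")
    return ms


# -- metrics --------------------------------------------------------------


def density(net: Network, members: Iterable[str]) -> float:
    """Density 2·|E(S)| / (|S|·(|S|−1)) of the induced subgraph; 0 for a singleton."""
    ms = _member_set(net, members)
    if not ms:
        raise ValueError("members must be non-empty")
    k = len(ms)
    if k < 2:
        return 0.0
    e = net.graph.subgraph(ms).number_of_edges()
    return 2.0 * e / (k * (k - 1))


def common_neighbors(net: Network, u: str, v: str) -> set[str]:
    """N(u) ∩ N(v), excluding u and v themselves."""
    if u == v:
        raise ValueError("u and v must differ")
    return (net.neighbors(u) & net.neighbors(v)) - {u, v}


def in_out_degree(
    net: Network, v: str, members: Iterable[str], *, weighted: bool = True
) -> tuple[float, float]:
    """(internal, external) degree of ``v`` relative to ``members``.

    Internal sums edge weights from ``v`` into ``members``∖{v}; external sums
    weights of edges leaving the member set. With ``weighted=False`` edges
    count 1 each.
    """
    ms = _member_set(net, members)
    if v not in ms:
        raise ValueError(f"{v!r} is not in the member set")
    d_in = 0.0
    d_out = 0.0
    for x in net.graph[v]:
        w = net.graph[v][x]["weight"] if weighted else 1.0
        if x in ms:
            d_in += w
        else:
            d_out += w
    return d_in, d_out


def induced_diameter_at_most(net: Network, members: Iterable[str], d: int) -> bool:
    """True iff the induced subgraph is connected with all pairwise distances ≤ d."""
    ms = _member_set(net, members)
    if not ms:
        raise ValueError("members must be non-empty")
    if d < 1:
        raise ValueError("d must be >= 1")
    sub = net.graph.subgraph(ms)
    target = len(ms)
    for src in ms:
        # BFS truncated at depth d
        seen = {src}
        frontier = [src]
        depth = 0
        while frontier and depth < d and len(seen) < target:
            depth += 1
            nxt = []
            for x in frontier:
                for y in sub[x]:
                    if y not in seen:
                        seen.add(y)
                        nxt.append(y)
            frontier = nxt
        if len(seen) < target:
            return False
    return True


def maximal_cliques(net: Network, min_size: int = 2) -> list[frozenset[str]]:
    """All inclusion-maximal cliques with at least ``min_size`` nodes.

    Deterministic order: size descending, then lexicographic member tuple.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if net.number_of_nodes() == 0:
        return []
    out = [frozenset(c) for c in nx.find_cliques(net.graph) if len(c) >= min_size]
    out.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return out


def overlap_omega(a: Iterable[str], b: Iterable[str]) -> float:
    """ω overlap score |A∩B|² / (|A|·|B|)."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("overlap_omega requires non-empty sets")
    inter = len(sa & sb)
    return inter * inter / (len(sa) * len(sb))


def overlap_min(a: Iterable[str], b: Iterable[str]) -> float:
    """Containment-style overlap |A∩B| / min(|A|, |B|)."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("overlap_min requires non-empty sets")
    return len(sa & sb) / min(len(sa), len(sb))


def cluster_metrics(net: Network, members: Iterable[str]) -> tuple[float, float, float]:
    """(density, score, modularity) of a member set.

    score = density × size; modularity = e_in / (e_in + e_out) with e_in the
    number of internal edges and e_out the number of boundary edges (exactly
    one endpoint inside), 0 when there are no incident edges at all.
    """
    ms = _member_set(net, members)
    if not ms:
        raise ValueError("members must be non-empty")
    e_in = 0
    e_out = 0
    for v in ms:
        for x in net.graph[v]:
            if x in ms:
                e_in += 1  # counted from both endpoints
            else:
                e_out += 1
    e_in //= 2
    dens = density(net, ms)
    score = dens * len(ms)
    modularity = e_in / (e_in + e_out) if (e_in + e_out) else 0.0
    return dens, score, modularity


# -- result containers ----------------------------------------------------


@dataclass(frozen=True)
class Cluster:
    """A detected module: a node set with its cached quality metrics."""

    members: frozenset[str]
    size: int
    density: float
    score: float
    modularity: float

    @classmethod
    def from_members(cls, net: Network, members: Iterable[str]) -> "Cluster":
        ms = frozenset(members)
        dens, score, modularity = cluster_metrics(net, ms)
        return cls(ms, len(ms), dens, score, modularity)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


def cluster_sort_key(key: str):
    """Sort key for clusters: chosen metric desc, then size desc, then members."""
    if key not in ("score", "size", "modularity", "density"):
        raise ValueError(f"unknown sort key {key!r}")

    def _key(c: Cluster):
        return (-float(getattr(c, key)), -c.size, c.sorted_members())

    return _key


@dataclass
class ClusteringResult:
    """Ordered output of one algorithm run: name, parameters, clusters."""

    algorithm: str
    parameters: dict = field(default_factory=dict)
    clusters: list[Cluster] = field(default_factory=list)

    def sorted_by(self, key: str) -> "ClusteringResult":
        return ClusteringResult(
            self.algorithm,
            dict(self.parameters),
            sorted(self.clusters, key=cluster_sort_key(key)),
        )

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)
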