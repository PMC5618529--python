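"""Seed-and-grow complex detection: IPCA, ClusterONE, and DCU.

IPCA grows a dense, small-diameter cluster around the vertex with the
highest triangle-based weight; ClusterONE greedily optimises a cohesiveness
objective from high-degree seeds and then merges and filters the locally
optimal groups; DCU works on an uncertain graph (edge weights are existence
probabilities) with a core-attachment strategy: grow a high-cohesion /
low-coupling core, attach the core's neighbourhood, prune loosely attached
proteins, and de-duplicate by overlap.

All three are deterministic: ties break on the documented keys, ending with
lexicographic node order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph_core import (
    Cluster,
    ClusteringResult,
    Network,
    cluster_sort_key,
    common_neighbors,
    density,
    in_out_degree,
    induced_diameter_at_most,
    overlap_omega,
)

__all__ = [
    "IpcaParams",
    "ClusterOneParams",
    "DcuParams",
    "ipca_vertex_weights",
    "ipca",
    "cohesiveness",
    "grow_cohesive_group",
    "clusterone_groups",
    "clusterone",
    "expected_density",
    "dcu_complexes",
    "dcu",
]

_EPS = 1e-12  # strict-improvement margin for greedy float comparisons


@dataclass
class IpcaParams:
    """IPCA parameters: interaction-probability threshold t_in, diameter bound
    d (shortest-path bound), and minimum emitted cluster size."""

    t_in: float = 0.5
    d: int = 2
    min_size: int = 3

    def __post_init__(self):
        if not 0 < self.t_in <= 1:
            raise ValueError("t_in must be in (0, 1]")
        if self.d < 1:
            raise ValueError("d must be >= 1")


@dataclass
class ClusterOneParams:
    """ClusterONE parameters: size penalty, ω merge threshold, density
    threshold ∂ for the output filter, and minimum size."""

    penalty: float = 2.0
    overlap_threshold: float = 0.8
    density_threshold: float = 0.8
    min_size: int = 3

    def __post_init__(self):
        if self.penalty < 0:
            raise ValueError("penalty must be >= 0")


@dataclass
class DcuParams:
    """DCU parameters: ω overlap threshold for de-duplication and minimum size."""

    overlap_threshold: float = 0.8
    min_size: int = 3


# -- IPCA -----------------------------------------------------------------


def ipca_vertex_weights(net: Network) -> dict[str, float]:
    """Vertex weights: each edge weighs its common-neighbour count (triangle
    support); a vertex sums the weights of its incident edges."""
    vw = {v: 0.0 for v in net.nodes}
    for u, v, _w in net.edges():
        ew = float(len(common_neighbors(net, u, v)))
        vw[u] += ew
        vw[v] += ew
    return vw


def _edges_to(net: Network, v: str, members: frozenset[str]) -> int:
    return sum(1 for x in net.graph[v] if x in members)


def _triangle_weight_to(net: Network, v: str, members: frozenset[str]) -> float:
    return sum(
        float(len(common_neighbors(net, v, x))) for x in net.graph[v] if x in members
    )


def ipca(net: Network, params: IpcaParams | None = None) -> ClusteringResult:
    """IPCA: grow dense small-diameter clusters from high-weight seeds.

    Seeds are the highest-weight vertices not yet covered by a cluster.
    Growth scans the cluster's neighbourhood in priority order (more edges
    into the cluster, higher triangle-weighted connectivity, higher vertex
    weight, lexicographic) and admits a vertex v when
    IN_vK = |E(v,K)| / |K| ≥ t_in and the extended cluster keeps induced
    diameter ≤ d. Growth may re-enter covered vertices, so clusters can
    overlap. Clusters of size ≥ min_size are emitted, sorted by score.
    """
    params = params or IpcaParams()
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    vw = ipca_vertex_weights(net)
    covered: set[str] = set()
    clusters: list[Cluster] = []
    while True:
        uncovered = sorted(net.nodes - covered, key=lambda v: (-vw[v], v))
        if not uncovered:
            break
        seed = uncovered[0]
        k = frozenset((seed,))
        while True:
            frontier = set()
            for m in k:
                frontier.update(x for x in net.graph[m] if x not in k)
            added = None
            for v in sorted(
                frontier,
                key=lambda v: (
                    -_edges_to(net, v, k),
                    -_triangle_weight_to(net, v, k),
                    -vw[v],
                    v,
                ),
            ):
                if _edges_to(net, v, k) / len(k) >= params.t_in and induced_diameter_at_most(
                    net, k | {v}, params.d
                ):
                    added = v
                    break
            if added is None:
                break
            k = k | {added}
        covered.update(k)
        if len(k) >= params.min_size:
            clusters.append(Cluster.from_members(net, k))
    clusters.sort(key=cluster_sort_key("score"))
    return ClusteringResult(
        "IPCA", {"tin": params.t_in, "sp": params.d, "min_size": params.min_size}, clusters
    )


# -- ClusterONE -----------------------------------------------------------


def cohesiveness(net: Network, members, penalty: float = 2.0) -> float:
    """f(S) = w_in / (w_in + w_bound + penalty·|S|): internal weight against
    boundary weight plus a per-member penalty for unobserved interactions."""
    ms = frozenset(members)
    if not ms:
        raise ValueError("members must be non-empty")
    w_in = 0.0
    w_bound = 0.0
    for v in ms:
        d_in, d_out = in_out_degree(net, v, ms)
        w_in += d_in
        w_bound += d_out
    w_in /= 2.0
    denom = w_in + w_bound + penalty * len(ms)
    return w_in / denom if denom else 0.0


def grow_cohesive_group(net: Network, seed: str, penalty: float = 2.0) -> frozenset[str]:
    """Greedy local search from a seed: repeatedly apply the boundary-vertex
    addition or member removal that most increases cohesiveness; stop at a
    local optimum. Deterministic: additions beat removals on ties, then
    lexicographic vertex order."""
    s = {seed}
    f = cohesiveness(net, s, penalty)
    while True:
        best_gain = _EPS
        best_move: tuple[int, str] | None = None  # (0=add, 1=remove, vertex)
        boundary = set()
        for m in s:
            boundary.update(x for x in net.graph[m] if x not in s)
        for v in sorted(boundary):
            g = cohesiveness(net, s | {v}, penalty) - f
            if g > best_gain:
                best_gain = g
                best_move = (0, v)
        if len(s) > 1:
            for v in sorted(s):
                g = cohesiveness(net, s - {v}, penalty) - f
                if g > best_gain:
                    best_gain = g
                    best_move = (1, v)
        if best_move is None:
            return frozenset(s)
        kind, v = best_move
        if kind == 0:
            s.add(v)
        else:
            s.remove(v)
        f += best_gain


def clusterone_groups(net: Network, penalty: float = 2.0) -> list[frozenset[str]]:
    """Growth stage: locally optimal cohesive groups, one per seed.

    Seeds are the uncovered vertices of highest weighted degree; every grown
    group marks its members covered, and growth may re-enter covered
    vertices, producing overlapping groups.
    """
    covered: set[str] = set()
    groups: list[frozenset[str]] = []
    while True:
        uncovered = sorted(
            net.nodes - covered, key=lambda v: (-net.degree(v, weighted=True), v)
        )
        if not uncovered:
            return groups
        group = grow_cohesive_group(net, uncovered[0], penalty)
        covered.add(uncovered[0])  # the seed may have been removed during search
        covered.update(group)
        if group not in groups:
            groups.append(group)


def _merge_by_omega(
    groups: list[frozenset[str]], threshold: float
) -> list[frozenset[str]]:
    """Merge pairs with ω ≥ threshold, highest ω first, to a fixpoint."""
    groups = list(dict.fromkeys(groups))
    while True:
        best = None
        best_key = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                w = overlap_omega(groups[i], groups[j])
                if w >= threshold:
                    ca, cb = sorted((tuple(sorted(groups[i])), tuple(sorted(groups[j]))))
                    key = (-w, ca, cb)
                    if best_key is None or key < best_key:
                        best_key = key
                        best = (i, j)
        if best is None:
            return groups
        i, j = best
        merged = groups[i] | groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        if merged not in groups:
            groups.append(merged)


def clusterone(net: Network, params: ClusterOneParams | None = None) -> ClusteringResult:
    """ClusterONE: cohesiveness growth, ω merging, size/density filtering.

    Groups smaller than min_size or with density below ∂ are discarded;
    survivors are sorted by cohesiveness descending.
    """
    params = params or ClusterOneParams()
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    groups = clusterone_groups(net, params.penalty)
    groups = _merge_by_omega(groups, params.overlap_threshold)
    kept = [
        g
        for g in groups
        if len(g) >= params.min_size and density(net, g) >= params.density_threshold
    ]
    kept.sort(key=lambda g: (-cohesiveness(net, g, params.penalty), -len(g), tuple(sorted(g))))
    clusters = [Cluster.from_members(net, g) for g in kept]
    return ClusteringResult(
        "ClusterONE",
        {
            "penalty": params.penalty,
            "overlap": params.overlap_threshold,
            "density": params.density_threshold,
            "min_size": params.min_size,
        },
        clusters,
    )


# -- DCU ------------------------------------------------------------------


def _check_probabilities(net: Network) -> None:
    for u, v, w in net.edges():
        if w > 1.0:
            raise ValueError(
                f"edge ({u!r}, {v!r}) has weight {w} > 1; DCU requires probabilities"
            )


def _expected_degree(net: Network, v: str, within: frozenset[str] | None = None) -> float:
    total = 0.0
    for x in net.graph[v]:
        if within is None or x in within:
            total += net.graph[v][x]["weight"]
    return total


def _core_score(net: Network, s: frozenset[str]) -> float:
    """CS(S) = P_in / (P_in + P_out): probability-weighted cohesion vs coupling."""
    p_in = 0.0
    p_out = 0.0
    for v in s:
        d_in, d_out = in_out_degree(net, v, s)
        p_in += d_in
        p_out += d_out
    p_in /= 2.0
    return p_in / (p_in + p_out) if (p_in + p_out) else 0.0


def expected_density(net: Network, members) -> float:
    """Expected density of an uncertain subgraph: Σ p(e) over internal edges
    divided by the number of possible pairs."""
    ms = frozenset(members)
    if len(ms) < 2:
        return 0.0
    p_sum = sum(
        d["weight"] for u, v, d in net.graph.subgraph(ms).edges(data=True)
    )
    return p_sum / (len(ms) * (len(ms) - 1) / 2.0)


def dcu_complexes(
    net: Network, params: DcuParams | None = None
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """DCU pipeline up to the final kept complexes; returns (members, core) pairs.

    Cores grow greedily from uncovered seeds of highest expected degree,
    maximising CS(S); attachments are the core's neighbours, iteratively
    pruned while any non-core protein's internal expected degree is below
    its external expected degree; finally complexes are ranked by expected
    density and de-duplicated at ω ≥ overlap_threshold.
    """
    params = params or DcuParams()
    _check_probabilities(net)
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    covered: set[str] = set()
    raw: list[tuple[frozenset[str], frozenset[str]]] = []
    while True:
        uncovered = sorted(
            net.nodes - covered, key=lambda v: (-_expected_degree(net, v), v)
        )
        if not uncovered:
            break
        core = frozenset((uncovered[0],))
        cs = _core_score(net, core)
        while True:
            frontier = set()
            for m in core:
                frontier.update(x for x in net.graph[m] if x not in core)
            best_v = None
            best_cs = cs
            for v in sorted(frontier):
                c2 = _core_score(net, core | {v})
                if c2 > best_cs + _EPS:
                    best_cs = c2
                    best_v = v
            if best_v is None:
                break
            core = core | {best_v}
            cs = best_cs
        covered.update(core)
        candidate = set(core)
        for m in core:
            candidate.update(net.graph[m])
        candidate = frozenset(candidate)
        # attachment pruning: drop loosely attached non-core proteins
        while True:
            violators = [
                v
                for v in sorted(candidate - core)
                if _expected_degree(net, v, candidate) < _expected_degree(net, v) - _expected_degree(net, v, candidate)
            ]
            if not violators:
                break
            candidate = candidate - set(violators)
        raw.append((candidate, core))

    candidates = [rc for rc in raw if len(rc[0]) >= params.min_size]
    candidates.sort(
        key=lambda rc: (-expected_density(net, rc[0]), -len(rc[0]), tuple(sorted(rc[0])))
    )
    kept: list[tuple[frozenset[str], frozenset[str]]] = []
    for members, core in candidates:
        if all(overlap_omega(members, k) < params.overlap_threshold for k, _ in kept):
            kept.append((members, core))
    return kept


def dcu(net: Network, params: DcuParams | None = None) -> ClusteringResult:
    """DCU: core-attachment complex detection on an uncertain graph."""
    params = params or DcuParams()
    kept = dcu_complexes(net, params)
    clusters = [Cluster.from_members(net, members) for members, _core in kept]
    return ClusteringResult(
        "DCU",
        {"overlap": params.overlap_threshold, "min_size": params.min_size},
        clusters,
    )
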