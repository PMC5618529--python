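"""Shared test utilities: random graph generation and independent oracles.

The oracles here are deliberately naive (exhaustive enumeration, explicit
edge scans, exact rational arithmetic) and share no code with the package
implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from netclust import Network, UncertainNetwork


def random_network(rng, n, p, *, weighted=False, low=0.05, high=1.0, uncertain=False):
    """Erdős–Rényi G(n, p) with string node IDs; optional uniform weights."""
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.uniform(low, high)) if weighted else 1.0
                edges.append((nodes[i], nodes[j], w))
    cls = UncertainNetwork if uncertain else Network
    return cls(edges, nodes=nodes)


def brute_density(net, members):
    ms = sorted(members)
    if len(ms) < 2:
        return 0.0
    edges = sum(
        1
        for i in range(len(ms))
        for j in range(i + 1, len(ms))
        if net.has_edge(ms[i], ms[j])
    )
    return 2.0 * edges / (len(ms) * (len(ms) - 1))


def brute_in_out(net, v, members, weighted=True):
    d_in = d_out = 0.0
    for a, b, w in net.edges():
        if v not in (a, b):
            continue
        other = b if a == v else a
        val = w if weighted else 1.0
        if other in members:
            d_in += val
        else:
            d_out += val
    return d_in, d_out


def brute_maximal_cliques(net, min_size):
    """Exhaustive subset enumeration; only for |V| <= ~14."""
    nodes = sorted(net.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v, _w in net.edges():
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    cliques = []
    for mask in range(1, 1 << n):
        m = mask
        ok = True
        while m:
            i = (m & -m).bit_length() - 1
            if (adj[i] & mask) != (mask & ~(1 << i)):
                ok = False
                break
            m &= m - 1
        if ok:
            cliques.append(mask)
    out = []
    for c in cliques:
        if bin(c).count("1") < min_size:
            continue
        if any(c != d and (c & d) == c for d in cliques):
            continue
        out.append(frozenset(nodes[i] for i in range(n) if (c >> i) & 1))
    return sorted(out, key=lambda s: (-len(s), tuple(sorted(s))))


def brute_clustering_value(net, u, v):
    """Direct neighbour-set loop, independent of the implementation."""
    nu = {x for x in net.nodes if net.has_edge(u, x)}
    nv = {x for x in net.nodes if net.has_edge(v, x)}
    num = net.weight(u, v)
    for x in (nu & nv) - {u, v}:
        num += (net.weight(u, x) + net.weight(x, v)) / 2.0
    su = sum(net.weight(u, x) for x in nu)
    sv = sum(net.weight(v, x) for x in nv)
    den = min(su, sv) - net.weight(u, v)
    return num if den <= 0 else num / den


def brute_cohesiveness(net, members, penalty):
    w_in = w_bound = 0.0
    for a, b, w in net.edges():
        inside = (a in members) + (b in members)
        if inside == 2:
            w_in += w
        elif inside == 1:
            w_bound += w
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom else 0.0


def exact_hypergeom_tail(k, n, K, N):
    """P(X >= k), X ~ Hypergeometric(N, K, n), exact rational arithmetic."""
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(total, comb(N, n))


def exact_binom_tail(k, n, K, N):
    """P(X >= k), X ~ Binomial(n, K/N), exact rational arithmetic."""
    q = Fraction(K, N)
    return sum(comb(n, i) * q**i * (1 - q) ** (n - i) for i in range(k, n + 1))


def textbook_bh(p_values):
    """Benjamini–Hochberg step-up with monotonicity, straight from the book."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted
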