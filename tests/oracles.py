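"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) they check:
shortest-path metrics come from a hand-written Floyd–Warshall and an
explicit simple-path enumeration; the hypergeometric tail from exact
integer combinatorics.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def hypergeom_upper_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational, by summing the pmf."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def floyd_warshall(nodes: list, edges: set) -> dict:
    """All-pairs shortest-path lengths; unreachable pairs absent."""
    INF = float("inf")
    dist = {(u, v): (0 if u == v else INF) for u in nodes for v in nodes}
    for u, v in edges:
        dist[(u, v)] = dist[(v, u)] = 1
    for w in nodes:
        for u in nodes:
            for v in nodes:
                via = dist[(u, w)] + dist[(w, v)]
                if via < dist[(u, v)]:
                    dist[(u, v)] = via
    return {pair: d for pair, d in dist.items() if d < INF}


def closeness_exact(nodes: list, edges: set) -> dict:
    """(m-1)/sum(d) within each connected component, 0 for isolates."""
    dist = floyd_warshall(nodes, edges)
    out = {}
    for v in nodes:
        reachable = [u for u in nodes if u != v and (v, u) in dist]
        total = sum(dist[(v, u)] for u in reachable)
        out[v] = len(reachable) / total if total > 0 else 0.0
    return out


def _all_simple_paths(adj: dict, u, v) -> list:
    paths, stack = [], [(u, [u])]
    while stack:
        node, path = stack.pop()
        if node == v:
            paths.append(path)
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))
    return paths


def betweenness_exact(nodes: list, edges: set) -> dict:
    """Endpoint-excluded betweenness over unordered pairs, scaled by
    2/((n-1)(n-2)), by enumerating every simple path."""
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            on = sum(1 for p in geodesics if v in p)
            score[v] += on / len(geodesics)
    n = len(nodes)
    if n < 3:
        return {v: 0.0 for v in nodes}
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: s * scale for v, s in score.items()}
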