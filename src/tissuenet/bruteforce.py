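"""Exhaustive reference implementations of the structural characteristics.

Deliberately naive, enumeration-based versions of every metric, feasible only
for small graphs (n up to ~12).  They exist to validate the production
implementations in :mod:`tissuenet.metrics` by a second, independent route:
nothing here shares code with the production path (no BFS sigma counting, no
Brandes accumulation) — geodesics are enumerated as explicit simple paths.

All functions take an adjacency mapping ``vertex -> set of neighbors``
(symmetric, no self-loops).
"""
from __future__ import annotations

import math
from itertools import combinations
from typing import Mapping, Sequence


Adjacency = Mapping[str, frozenset]


def simple_paths_of_length(adj: Adjacency, s: str, t: str, length: int) -> list[tuple[str, ...]]:
    """Every simple path from s to t using exactly ``length`` edges."""
    paths: list[tuple[str, ...]] = []

    def walk(v: str, path: list[str], seen: set[str]) -> None:
        if len(path) - 1 == length:
            if v == t:
                paths.append(tuple(path))
            return
        for u in sorted(adj[v]):
            if u not in seen:
                seen.add(u)
                path.append(u)
                walk(u, path, seen)
                path.pop()
                seen.remove(u)

    walk(s, [s], {s})
    return paths


def geodesics(adj: Adjacency, s: str, t: str) -> list[tuple[str, ...]]:
    """All minimal-length simple paths from s to t ([] if unreachable).

    Iterative deepening: enumerate paths of length 1, 2, ... until some exist;
    those are exactly the geodesics.  Unreachable pairs are detected first by
    union-find so the deepening never runs across components.
    """
    if _component_labels(adj)[s] != _component_labels(adj)[t]:
        return []
    for length in range(1, len(adj)):
        paths = simple_paths_of_length(adj, s, t, length)
        if paths:
            return paths
    return []


def _component_labels(adj: Adjacency) -> dict[str, str]:
    """Union-find component label of every vertex."""
    parent = {v: v for v in adj}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for v in adj:
        for u in adj[v]:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    return {v: find(v) for v in adj}


def clustering(adj: Adjacency, all_nodes: bool = False) -> float:
    """Mean local clustering by direct enumeration of neighbor pairs."""
    locals_: list[float] = []
    n_vertices = len(adj)
    for v in adj:
        ns = sorted(adj[v])
        k = len(ns)
        if k < 2:
            continue
        closed = sum(1 for a, b in combinations(ns, 2) if b in adj[a])
        locals_.append(closed / (k * (k - 1) / 2))
    if all_nodes:
        return sum(locals_) / n_vertices if n_vertices else 0.0
    return sum(locals_) / len(locals_) if locals_ else 0.0


def components(adj: Adjacency) -> int:
    """Connected components by union-find."""
    return len(set(_component_labels(adj).values()))


def degree_sequence(adj: Adjacency) -> list[int]:
    return sorted(len(adj[v]) for v in adj)


def centralization(adj: Adjacency) -> float:
    """Degree centralization recomputed from the sorted degree sequence."""
    degs = degree_sequence(adj)
    n = len(degs)
    if n < 3:
        return 0.0
    dens = sum(degs) / (n * (n - 1))
    return (n / (n - 2)) * (degs[-1] / (n - 1) - dens)


def count_shortest_paths(adj: Adjacency, pairs_only: bool = False) -> int:
    """Sum of geodesic counts over ordered pairs, by explicit enumeration."""
    total = 0
    for s in adj:
        for t in adj:
            if s == t:
                continue
            g = geodesics(adj, s, t)
            if g:
                total += 1 if pairs_only else len(g)
    return total


def avg_neighbors(adj: Adjacency) -> float:
    degs = degree_sequence(adj)
    return sum(degs) / len(degs) if degs else 0.0


def density(adj: Adjacency) -> float:
    n = len(adj)
    if n < 2:
        return 0.0
    return sum(degree_sequence(adj)) / (n * (n - 1))


def heterogeneity(adj: Adjacency) -> float:
    degs = degree_sequence(adj)
    if not degs:
        return 0.0
    mean = sum(degs) / len(degs)
    if mean == 0:
        return 0.0
    var = sum((d - mean) ** 2 for d in degs) / len(degs)
    return math.sqrt(var) / mean


def betweenness(adj: Adjacency, normalized: bool = True) -> dict[str, float]:
    """Betweenness by enumerating every geodesic and counting pass-throughs."""
    score = {v: 0.0 for v in adj}
    vertices = sorted(adj)
    for i, s in enumerate(vertices):
        for t in vertices[i + 1 :]:
            g = geodesics(adj, s, t)
            if not g:
                continue
            for path in g:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(g)
    n = len(adj)
    if normalized and n > 2:
        norm = (n - 1) * (n - 2) / 2
        score = {v: x / norm for v, x in score.items()}
    return score


def random_adjacency(rng, n: int, p: float) -> dict[str, frozenset]:
    """A random G(n, p) adjacency for oracle comparisons."""
    vertices = [f"v{i:02d}" for i in range(n)]
    adj: dict[str, set] = {v: set() for v in vertices}
    for a, b in combinations(vertices, 2):
        if rng.random() < p:
            adj[a].add(b)
            adj[b].add(a)
    return {v: frozenset(ns) for v, ns in adj.items()}
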