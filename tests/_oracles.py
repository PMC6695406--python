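"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive enumeration, exact
rational arithmetic, O(n^3) loops) and shares no code path with the
package.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb

import numpy as np


def brute_betweenness(nodes, edges):
    """Normalized betweenness by exhaustive shortest-path enumeration.

    BFS per source for distances, then DFS enumeration of every shortest
    path for every ordered pair; interior nodes of each path are credited
    1/(number of shortest paths).  Normalization divides by (n-1)(n-2)/2.
    """
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def bfs_dist(src):
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        return dist

    def all_shortest_paths(s, t, dist):
        # enumerate by walking backwards from t along dist-decreasing edges
        paths = []

        def back(v, tail):
            if v == s:
                paths.append([s] + tail)
                return
            for w in adj[v]:
                if dist.get(w, -1) == dist[v] - 1:
                    back(w, [v] + tail)

        back(t, [])
        return paths

    credit = {v: Fraction(0) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist = bfs_dist(s)
        if t not in dist:
            continue
        paths = all_shortest_paths(s, t, dist)
        share = Fraction(1, len(paths))
        for path in paths:
            for interior in path[1:-1]:
                credit[interior] += share
    n = len(nodes)
    if n < 3:
        return {v: 0.0 for v in nodes}
    norm = Fraction((n - 1) * (n - 2), 2)
    return {v: float(credit[v] / norm) for v in nodes}


def hypergeom_upper_tail(x, K, E, N):
    """Exact P(X >= x) for X ~ Hypergeom(N, K, E), as a Fraction."""
    total = comb(N, E)
    tail = sum(comb(K, i) * comb(N - K, E - i) for i in range(x, min(K, E) + 1))
    return Fraction(tail, total)


def average_linkage_heights(dist):
    """Naive O(n^3) average-linkage agglomeration; returns merge heights.

    ``dist`` is a symmetric (n, n) distance matrix.  At each step the two
    clusters with minimal average inter-cluster distance merge; returns the
    sorted list of merge heights.
    """
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean(
                [dist[i, j] for i in clusters[a] for j in clusters[b]]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [
            c for k, c in enumerate(clusters) if k not in (a, b)
        ] + [merged]
    return sorted(heights)


def pearson(x, y):
    """Direct covariance/variance-formula Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    return float((xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum()))
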