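"""Independent brute-force oracles for small graphs.

Deliberately naive implementations (triple loops, exhaustive path
enumeration) used only to check the production metric code on tiny
instances; they share no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

TOL = 1e-12


def floyd_warshall_oracle(lengths: np.ndarray) -> np.ndarray:
    """Textbook O(n^3) Floyd-Warshall on a dense length matrix."""
    n = lengths.shape[0]
    d = lengths.astype(float).copy()
    for i in range(n):
        d[i, i] = 0.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _all_simple_paths(adj: dict[int, list[int]], s: int, t: int) -> list[list[int]]:
    paths = []

    def dfs(node: int, visited: list[int]) -> None:
        if node == t:
            paths.append(visited.copy())
            return
        for nb in adj[node]:
            if nb not in visited:
                visited.append(nb)
                dfs(nb, visited)
                visited.pop()

    dfs(s, [s])
    return paths


def betweenness_oracle(weights: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive enumeration of all simple paths.

    For each unordered pair, every simple path is enumerated, shortest
    ones identified within a tolerance, and each interior node of each
    shortest path credited 1/(number of shortest paths).
    """
    n = weights.shape[0]
    adj = {i: [j for j in range(n) if weights[i, j] > 0] for i in range(n)}
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_simple_paths(adj, s, t)
        if not paths:
            continue
        plens = [
            sum(1.0 / weights[a, b] for a, b in zip(p[:-1], p[1:])) for p in paths
        ]
        dmin = min(plens)
        shortest = [p for p, L in zip(paths, plens) if L <= dmin + TOL]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def onnela_clustering_oracle(weights: np.ndarray) -> np.ndarray:
    """Direct triple-loop evaluation of the Onnela weighted clustering formula."""
    n = weights.shape[0]
    wmax = weights.max()
    if wmax == 0:
        return np.zeros(n)
    what = weights / wmax
    c = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if weights[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                total += (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
        c[i] = total / (k * (k - 1))
    return c


def random_weighted_matrix(
    rng: np.random.Generator,
    n: int,
    density: float = 0.6,
    integer: bool = False,
) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                v = float(rng.integers(1, 10)) if integer else float(rng.uniform(0.5, 3.0))
                w[i, j] = w[j, i] = v
    return w
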