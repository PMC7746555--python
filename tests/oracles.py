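"""Independent brute-force reference implementations for small graphs.

Everything here is written from first principles (enumeration, Floyd-
Warshall, exhaustive partition search) and deliberately shares no code
with the package; it is only usable for tiny graphs.
"""
from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_nodal(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if a[v, u]]
        if len(nb) < 2:
            continue
        links = sum(1 for x, y in itertools.combinations(nb, 2) if a[x, y])
        out[v] = links / (len(nb) * (len(nb) - 1) / 2)
    return out


def characteristic_path_length(a: np.ndarray) -> float:
    d = floyd_warshall(a)
    vals = [
        d[i, j]
        for i, j in itertools.combinations(range(a.shape[0]), 2)
        if np.isfinite(d[i, j]) and d[i, j] > 0
    ]
    return float(np.mean(vals))


def global_efficiency(a: np.ndarray) -> float:
    d = floyd_warshall(a)
    vals = [
        1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
        for i, j in itertools.combinations(range(a.shape[0]), 2)
    ]
    return float(np.mean(vals)) if vals else 0.0


def local_efficiency_nodal(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if a[v, u]]
        if len(nb) < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        out[v] = global_efficiency(sub)
    return out


def transitivity(a: np.ndarray) -> float:
    n = a.shape[0]
    triangles = sum(
        1
        for i, j, k in itertools.combinations(range(n), 3)
        if a[i, j] and a[j, k] and a[i, k]
    )
    triples = 0
    for v in range(n):
        k = int(a[v].sum())
        triples += k * (k - 1) // 2
    return 3.0 * triangles / triples if triples else 0.0


def _all_shortest_paths(a: np.ndarray, s: int, t: int, d: np.ndarray):
    """Every shortest s-t path, as node lists, by recursive descent."""
    if not np.isfinite(d[s, t]):
        return []
    if s == t:
        return [[s]]
    paths = []
    for u in range(a.shape[0]):
        if a[s, u] and d[u, t] == d[s, t] - 1:
            for tail in _all_shortest_paths(a, u, t, d):
                paths.append([s] + tail)
    return paths


def betweenness(a: np.ndarray) -> np.ndarray:
    """Fractional-credit betweenness; each unordered pair counted once."""
    n = a.shape[0]
    d = floyd_warshall(a)
    out = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(a, s, t, d)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def _set_partitions(n: int):
    """All partitions of range(n) via restricted-growth strings."""
    codes = [0] * n

    def rec(i, maxcode):
        if i == n:
            yield list(codes)
            return
        for c in range(maxcode + 2):
            codes[i] = c
            yield from rec(i + 1, max(maxcode, c))

    yield from rec(0, -1)


def modularity_of(a: np.ndarray, membership) -> float:
    m = a.sum() / 2
    q = 0.0
    for c in set(membership):
        nodes = [i for i, x in enumerate(membership) if x == c]
        l_c = a[np.ix_(nodes, nodes)].sum() / 2
        d_c = a[nodes].sum()
        q += l_c / m - (d_c / (2 * m)) ** 2
    return q


def best_modularity(a: np.ndarray) -> tuple[float, list]:
    """Exhaustive search over all node partitions (n <= 8 or so)."""
    best, best_p = -np.inf, None
    for p in _set_partitions(a.shape[0]):
        q = modularity_of(a, p)
        if q > best:
            best, best_p = q, p
    return best, best_p


def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def random_graph(n: int, p: float, rng) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            a[i, j] = a[j, i] = 1
    return a
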