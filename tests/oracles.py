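"""Independent brute-force oracles for graph quantities.

Deliberately naive: exhaustive enumeration only, no shared code with the
package's implementations.
"""

from collections import deque
from itertools import combinations

import numpy as np


def degree_oracle(a: np.ndarray) -> np.ndarray:
    return np.array([sum(a[i]) for i in range(len(a))], dtype=float)


def clustering_oracle(a: np.ndarray) -> np.ndarray:
    """Exhaustive enumeration of connected neighbour pairs per node."""
    d = len(a)
    out = np.zeros(d)
    for i in range(d):
        nbrs = [j for j in range(d) if a[i][j]]
        k = len(nbrs)
        if k < 2:
            continue
        closed = sum(1 for u, v in combinations(nbrs, 2) if a[u][v])
        out[i] = closed / (k * (k - 1) / 2)
    return out


def _all_shortest_paths(a: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Every shortest s-t path, by BFS layering then path enumeration."""
    d = len(a)
    dist = [None] * d
    dist[s] = 0
    q = deque([s])
    while q:
        u = q.popleft()
        for v in range(d):
            if a[u][v] and dist[v] is None:
                dist[v] = dist[u] + 1
                q.append(v)
    if dist[t] is None:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(path)
            return
        for v in range(d):
            if a[u][v] and dist[v] == dist[u] + 1:
                extend(path + [v])

    extend([s])
    return paths


def betweenness_oracle(a: np.ndarray) -> np.ndarray:
    """Sum over unordered pairs of the fraction of shortest paths via i."""
    d = len(a)
    out = np.zeros(d)
    for s, t in combinations(range(d), 2):
        paths = _all_shortest_paths(a, s, t)
        if not paths:
            continue
        for i in range(d):
            if i in (s, t):
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            out[i] += through / len(paths)
    return out


def _set_partitions(items):
    """All set partitions of a list (exhaustive, recursive)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1 :]
        yield [[first]] + smaller


def max_modularity_oracle(a: np.ndarray) -> float:
    """Exhaustive maximum of Q over every partition (feasible for d <= 8)."""
    d = len(a)
    deg = a.sum(axis=1)
    two_m = deg.sum()
    best = -np.inf
    for part in _set_partitions(list(range(d))):
        q = 0.0
        for block in part:
            idx = np.array(block)
            e_c = a[np.ix_(idx, idx)].sum() / 2.0
            d_c = deg[idx].sum()
            q += 2.0 * e_c / two_m - (d_c / two_m) ** 2
        best = max(best, q)
    return best
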