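"""Independent brute-force oracles used to validate the graph quantifiers.

Everything here is deliberately naive — exhaustive path enumeration,
union-find, direct formula evaluation — and shares no code with the
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def all_simple_paths(w: np.ndarray, s: int, t: int):
    """Yield every simple path s -> t in the weighted adjacency ``w``."""
    n = w.shape[0]

    def extend(path):
        last = path[-1]
        if last == t:
            yield list(path)
            return
        for nxt in range(n):
            if w[last, nxt] != 0 and nxt not in path:
                yield from extend(path + [nxt])

    yield from extend([s])


def path_length(w: np.ndarray, path) -> float:
    return sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))


def brute_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest 1/weight path lengths by simple-path enumeration."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for s, t in itertools.combinations(range(n), 2):
        best = np.inf
        for path in all_simple_paths(w, s, t):
            best = min(best, path_length(w, path))
        d[s, t] = d[t, s] = best
    return d


def brute_betweenness(w: np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness, endpoints excluded.

    For every unordered pair (s, t), enumerate all simple paths, keep those
    achieving the minimum 1/weight length (to a 1e-12 relative tolerance),
    and credit each interior node with its fraction of shortest paths.
    """
    n = w.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = list(all_simple_paths(w, s, t))
        if not paths:
            continue
        lengths = [path_length(w, p) for p in paths]
        best = min(lengths)
        shortest = [p for p, l in zip(paths, lengths) if l <= best * (1 + 1e-12)]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def brute_onnela_clustering(w: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by direct triple loops."""
    n = w.shape[0]
    peak = w.max()
    c = np.zeros(n)
    if peak == 0:
        return c
    what = w / peak
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] != 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            total += (what[i, j] * what[i, h] * what[j, h]) ** (1.0 / 3.0)
        c[i] = 2.0 * total / (k * (k - 1))
    return c


def brute_largest_component(w: np.ndarray) -> int:
    """Largest connected component size via union-find."""
    n = w.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(*np.nonzero(w)):
        parent[find(int(i))] = find(int(j))
    sizes: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values()) if sizes else 0


def brute_collective_influence(w: np.ndarray, ell: int) -> np.ndarray:
    """CI_ell from per-node breadth-first search on the binary topology."""
    adj = [set(np.nonzero(w[i])[0].tolist()) for i in range(w.shape[0])]
    n = w.shape[0]
    degree = np.array([len(a) for a in adj])
    ci = np.zeros(n)
    for i in range(n):
        frontier, seen = {i}, {i}
        for _ in range(ell):
            frontier = {v for u in frontier for v in adj[u]} - seen
            seen |= frontier
        ci[i] = (degree[i] - 1) * sum(degree[j] - 1 for j in frontier)
    return ci


def exact_rank_sum_p(a, b) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


def random_weighted_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric random graph with distinct uniform weights in (0, 1]."""
    w = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
    return w
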