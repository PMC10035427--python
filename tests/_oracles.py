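"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit loops, path enumeration,
power iteration — and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Pearson correlation by direct summation


def pearson_direct(ts: np.ndarray) -> np.ndarray:
    """Double-loop covariance/sd correlation matrix, zero diagonal."""
    n, m = ts.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            si, sj = ts[i], ts[j]
            di = si - sum(si) / m
            dj = sj - sum(sj) / m
            num = sum(a * b for a, b in zip(di, dj))
            den = math.sqrt(sum(a * a for a in di)) * math.sqrt(sum(b * b for b in dj))
            out[i, j] = num / den
    return out


# ---------------------------------------------------------------------------
# graph statistics on a binary undirected graph given as a 0/1 matrix


def _neighbors(a, v):
    return [u for u in range(len(a)) if a[v][u]]


def _all_simple_paths(a, s, t):
    n = len(a)
    stack = [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            yield path
            continue
        for u in range(n):
            if a[v][u] and u not in path:
                stack.append((u, path + [u]))


def shortest_path_census(a, s, t):
    """(distance, count of shortest paths, the shortest paths themselves)."""
    paths = list(_all_simple_paths(a, s, t))
    if not paths:
        return math.inf, 0, []
    dmin = min(len(p) - 1 for p in paths)
    shortest = [p for p in paths if len(p) - 1 == dmin]
    return dmin, len(shortest), shortest


def betweenness_brute(a) -> np.ndarray:
    """Normalized betweenness via explicit enumeration of shortest paths."""
    n = len(a)
    out = np.zeros(n)
    for v in range(n):
        total = 0.0
        for s, t in itertools.combinations([u for u in range(n) if u != v], 2):
            d, sigma, paths = shortest_path_census(a, s, t)
            if sigma == 0:
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            total += through / sigma
        norm = (n - 1) * (n - 2) / 2
        out[v] = total / norm if norm > 0 else 0.0
    return out


def harmonic_closeness_brute(a) -> np.ndarray:
    """Harmonic closeness scaled by 1/(n-1); unreachable nodes contribute 0."""
    n = len(a)
    out = np.zeros(n)
    for v in range(n):
        s = 0.0
        for u in range(n):
            if u == v:
                continue
            d, _, _ = shortest_path_census(a, v, u)
            if math.isfinite(d) and d > 0:
                s += 1.0 / d
        out[v] = s / (n - 1)
    return out


def clustering_brute(a) -> np.ndarray:
    """Watts-Strogatz clustering by triangle counting."""
    n = len(a)
    out = np.zeros(n)
    for v in range(n):
        nbrs = _neighbors(a, v)
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(1 for i, j in itertools.combinations(nbrs, 2) if a[i][j])
        out[v] = 2.0 * tri / (k * (k - 1))
    return out


def degree_brute(a) -> np.ndarray:
    n = len(a)
    return np.array([sum(a[v]) / (n - 1) for v in range(n)], dtype=float)


def eigenvector_brute(w, iters: int = 50_000, tol: float = 1e-14) -> np.ndarray:
    """Power iteration on the (weighted) adjacency, L2-normalized.

    Iterates on W + nI (same eigenvectors, strictly dominant Perron value)
    so bipartite graphs, whose extreme eigenvalues tie in magnitude, still
    converge.
    """
    w = np.asarray(w, dtype=float)
    n = len(w)
    if not w.any():
        return np.zeros(n)
    shifted = w + n * w.max() * np.eye(n)
    v = np.ones(n) / math.sqrt(n)
    for _ in range(iters):
        nxt = shifted @ v
        nrm = np.linalg.norm(nxt)
        if nrm == 0:
            return np.zeros(n)
        nxt = nxt / nrm
        if np.linalg.norm(nxt - v) < tol:
            v = nxt
            break
        v = nxt
    v = np.abs(v)
    return v / np.linalg.norm(v)


def local_efficiency_brute(a) -> np.ndarray:
    """Efficiency of each node's neighbor subgraph; unreachable pairs add 0."""
    n = len(a)
    out = np.zeros(n)
    for v in range(n):
        nbrs = _neighbors(a, v)
        k = len(nbrs)
        if k < 2:
            continue
        sub = [[a[i][j] for j in nbrs] for i in nbrs]
        s = 0.0
        for i, j in itertools.combinations(range(k), 2):
            d, _, _ = shortest_path_census(sub, i, j)
            if math.isfinite(d) and d > 0:
                s += 1.0 / d
        out[v] = s / (k * (k - 1) / 2)
    return out


def onnela_clustering_brute(w) -> np.ndarray:
    """Onnela weighted clustering: geometric-mean triangle intensities."""
    w = np.asarray(w, dtype=float)
    n = len(w)
    wmax = w.max()
    wh = w / wmax if wmax > 0 else w
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if w[v][u] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for i, j in itertools.combinations(nbrs, 2):
            s += (wh[v][i] * wh[v][j] * wh[i][j]) ** (1.0 / 3.0)
        out[v] = 2.0 * s / (k * (k - 1))
    return out


def zhang_clustering_brute(w) -> np.ndarray:
    """Zhang-Horvath weighted clustering with max-rescaled weights."""
    w = np.asarray(w, dtype=float)
    n = len(w)
    wmax = w.max()
    wh = w / wmax if wmax > 0 else w
    out = np.zeros(n)
    for v in range(n):
        num = 0.0
        for j in range(n):
            for k in range(n):
                if j != v and k != v and j != k:
                    num += wh[v][j] * wh[j][k] * wh[k][v]
        den = sum(wh[v]) ** 2 - sum(x * x for x in wh[v])
        if den > 0:
            out[v] = num / den
    return out


# ---------------------------------------------------------------------------
# misc


def auc_all_pairs(labels, scores) -> float:
    """Fraction of correctly ordered positive/negative pairs, ties 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    if not pos or not neg:
        return 0.5
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def random_connected_graph(rng, n_max: int = 6) -> np.ndarray:
    """Random connected binary graph with 3..n_max nodes (rejection sampled)."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        p = float(rng.uniform(0.3, 0.9))
        a = (rng.random((n, n)) < p).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        # connectivity check by BFS
        seen = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for u in range(n):
                if a[v][u] and u not in seen:
                    seen.add(u)
                    frontier.append(u)
        if len(seen) == n:
            return a
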