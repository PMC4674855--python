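"""Independent brute-force oracles used to validate the implementation.

Deliberately naive and algorithmically unrelated to the code paths they
check: betweenness comes from distance/path-count matrices built by
repeated adjacency-matrix multiplication (not Brandes), clustering from
the diagonal of A^3, BH q-values from an explicit step-up loop, and
Wang S-values from exhaustive ancestor-path enumeration without
memoization or pruning.
"""

from __future__ import annotations

import numpy as np


def matrix_shortest_path_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance and shortest-path-count matrices via powers of the adjacency matrix.

    A walk of minimal length between two nodes is necessarily a simple
    shortest path, so sigma[s, t] = (A^d)[s, t] with d the first power
    where the entry becomes positive.
    """
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(sigma, 1.0)
    power = np.eye(n)
    adj = adj.astype(float)
    for d in range(1, n):
        power = power @ adj
        newly = (dist == np.inf) & (power > 0)
        np.fill_diagonal(newly, False)
        dist[newly] = d
        sigma[newly] = power[newly]
    return dist, sigma


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness (endpoints excluded) over unordered pairs."""
    n = adj.shape[0]
    dist, sigma = matrix_shortest_path_counts(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def brute_clustering(adj: np.ndarray) -> np.ndarray:
    """Local clustering coefficient by triangle counting: diag(A^3) / (k(k-1))."""
    deg = adj.sum(axis=1)
    tri2 = np.diag(adj @ adj @ adj)  # 2 * triangles per node
    out = np.zeros(adj.shape[0])
    mask = deg >= 2
    out[mask] = tri2[mask] / (deg[mask] * (deg[mask] - 1))
    return out


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values by the explicit step-up recursion."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def wang_s_values_by_paths(term, dag, factors) -> dict[str, float]:
    """S-values by exhaustive enumeration of every child-to-ancestor path."""
    best: dict[str, float] = {term: 1.0}

    def dfs(node: str, weight: float) -> None:
        for parent, rel in dag.parents(node):
            w = weight * factors.get(rel, 0.0)
            if w > best.get(parent, 0.0):
                best[parent] = w
            dfs(parent, w)

    dfs(term, 1.0)
    return best


def wang_term_similarity_by_paths(t1, t2, dag, factors) -> float:
    sv1 = wang_s_values_by_paths(t1, dag, factors)
    sv2 = wang_s_values_by_paths(t2, dag, factors)
    shared = set(sv1) & set(sv2)
    denom = sum(sv1.values()) + sum(sv2.values())
    if not shared or denom == 0:
        return 0.0
    return sum(sv1[a] + sv2[a] for a in shared) / denom
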