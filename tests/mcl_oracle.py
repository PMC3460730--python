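"""Dense reference implementation of Markov Clustering, for oracle tests only.

Written independently of the package's sparse implementation: plain numpy
dense arrays, explicit loops, and cluster read-off via scipy's
connected-components on the attractor overlap graph.  Semantics match the
documented contract (self-loops = max incident weight, column-stochastic
iteration of expansion / Hadamard inflation / pruning / renormalization,
attractor-based partition with largest-value assignment).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def mcl_reference(
    W: np.ndarray,
    inflation: float,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> list[set[int]]:
    """Cluster a symmetric non-negative dense weight matrix; returns a partition."""
    W = np.array(W, dtype=float)
    n = W.shape[0]
    np.fill_diagonal(W, 0.0)
    loops = W.max(axis=1)
    loops[loops == 0] = 1.0
    M = W + np.diag(loops)
    M = M / M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        prev = M.copy()
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        # prune, but keep each column's maximum entry
        for j in range(n):
            col = M[:, j]
            keep = col >= prune_threshold
            if not keep.any():
                keep = col == col.max()
            M[:, j] = np.where(keep, col, 0.0)
        M = M / M.sum(axis=0, keepdims=True)
        if np.abs(M - prev).max() < tol:
            break

    attractors = [i for i in range(n) if M[i, i] > 0]
    # overlap graph: attractors sharing any reached column belong together
    adj = np.zeros((len(attractors), len(attractors)))
    for ai, a in enumerate(attractors):
        for bi, b in enumerate(attractors):
            if ai < bi and np.any((M[a] > 0) & (M[b] > 0)):
                adj[ai, bi] = adj[bi, ai] = 1
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    clusters: list[set[int]] = [set() for _ in range(n_comp)]
    assigned = np.full(n, -1)
    best = np.full(n, -1.0)
    for ai, a in enumerate(attractors):
        for j in range(n):
            v = M[a, j]
            if v > 0 and (v > best[j] or (v == best[j] and comp[ai] < assigned[j])):
                best[j] = v
                assigned[j] = comp[ai]
    for j in range(n):
        if assigned[j] < 0:
            clusters.append({j})
        else:
            clusters[assigned[j]].add(j)
    return [c for c in clusters if c]
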