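"""Deterministic Markov clustering (MCL) on a weighted adjacency matrix.

Used both for protein clustering (viral-cluster network, ortholog groups)
and for genome-level viral clusters.  The procedure: add self-loops equal to
the maximum incident edge weight (so isolated nodes are well-defined),
column-normalize, then iterate expansion (matrix square) and inflation
(element-wise power, re-normalize) until the matrix changes by less than a
tolerance or an iteration cap is reached.  Clusters are read off the rows of
attractor nodes.  There is no randomness anywhere.
"""

from __future__ import annotations

import numpy as np


def markov_cluster(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list[list[int]]:
    """Cluster node indices of a symmetric non-negative adjacency matrix.

    Returns disjoint clusters covering all nodes, ordered by smallest member.
    """
    A = np.asarray(adjacency, dtype=float).copy()
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if (A < 0).any():
        raise ValueError("adjacency weights must be non-negative")
    n = A.shape[0]
    if n == 0:
        return []
    incident_max = A.max(axis=0)
    loops = np.where(incident_max > 0, incident_max, 1.0)
    np.fill_diagonal(A, np.maximum(np.diag(A), loops))
    M = A / A.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        M2 = M @ M
        M2 = np.power(M2, inflation)
        colsum = M2.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M2 /= colsum
        if np.abs(M2 - M).max() < tol:
            M = M2
            break
        M = M2
    M[M < 1e-9] = 0.0
    # attractors: nodes with nonzero diagonal mass; their rows define clusters
    clusters: list[set[int]] = []
    assigned = np.full(n, -1, dtype=int)
    for i in range(n):
        if M[i, i] <= 0:
            continue
        members = set(np.nonzero(M[i] > 0)[0].tolist()) | {i}
        merged = False
        for ci, c in enumerate(clusters):
            if c & members:
                c |= members
                merged = True
                break
        if not merged:
            clusters.append(members)
    # repeated merging until stable (overlapping attractor systems)
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i] & clusters[j]:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    for ci, c in enumerate(clusters):
        for m in c:
            assigned[m] = ci
    for i in range(n):  # nodes not claimed by any attractor become singletons
        if assigned[i] < 0:
            clusters.append({i})
            assigned[i] = len(clusters) - 1
    out = [sorted(c) for c in clusters]
    out.sort(key=lambda c: c[0])
    return out
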