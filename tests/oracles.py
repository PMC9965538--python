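"""Independent reference implementations used only as test oracles.

These deliberately use different algorithms/code paths from the package:
quadratic-space Smith-Waterman for protein alignment scores, exhaustive
combinatorial enumeration for the hypergeometric tail, and direct path-length
computation on randomly grown additive trees for neighbor joining.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from numba import njit

_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(_AA_ORDER)}


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense array in ``_AA_ORDER`` order, with X scoring 0."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(_AA_ORDER), len(_AA_ORDER)))
    for i, a in enumerate(_AA_ORDER):
        for j, b in enumerate(_AA_ORDER):
            out[i, j] = mat[a, b]
    xi = _AA_INDEX["X"]
    out[xi, :] = 0.0
    out[:, xi] = 0.0
    return out


@njit(cache=True)
def _sw_kernel(a, b, mat, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e9)
    F = np.full((n + 1, m + 1), -1e9)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, h, E[i, j], F[i, j])
            if H[i, j] > best:
                best = H[i, j]
    return best


def smith_waterman_score(
    a: str, b: str, matrix: np.ndarray | None = None,
    gap_open: float = 11.0, gap_extend: float = 1.0,
) -> float:
    """Optimal local alignment score (affine gaps; gap of length L costs
    ``gap_open + (L-1) * gap_extend``)."""
    if matrix is None:
        matrix = blosum62_matrix()
    av = np.array([_AA_INDEX[c] for c in a], dtype=np.int64)
    bv = np.array([_AA_INDEX[c] for c in b], dtype=np.int64)
    return float(_sw_kernel(av, bv, matrix, gap_open, gap_extend))


def hypergeom_tail_enum(k: int, n_a: int, n_b: int, universe: int) -> float:
    """P(X >= k) for a hypergeometric draw, by exhaustive enumeration."""
    total = comb(universe, n_b)
    num = sum(
        comb(n_a, x) * comb(universe - n_a, n_b - x)
        for x in range(k, min(n_a, n_b) + 1)
        if n_b - x <= universe - n_a
    )
    return num / total


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Grow a random binary tree; return (distance matrix, set of non-trivial
    bipartitions as frozensets of leaf labels).

    Distances are exact path lengths, so the matrix is additive by
    construction.
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    # each active node: (dict leaf -> distance to this node's root, leafset)
    nodes = [({lab: 0.0}, frozenset([lab])) for lab in labels]
    bipartitions: list[frozenset] = []
    all_leaves = frozenset(labels)
    dist: dict[tuple[str, str], float] = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (da, sa), (db, sb) = nodes[i], nodes[j]
        la = float(rng.uniform(0.05, 0.5))
        lb = float(rng.uniform(0.05, 0.5))
        for x in da:
            for y in db:
                dist[(x, y)] = dist[(y, x)] = da[x] + la + db[y] + lb
        merged = {x: d + la for x, d in da.items()}
        merged.update({y: d + lb for y, d in db.items()})
        new_set = sa | sb
        if 2 <= len(new_set) <= n_leaves - 2:
            bipartitions.append(new_set)
        del nodes[j], nodes[i]
        nodes.append((merged, new_set))
    mat = np.zeros((n_leaves, n_leaves))
    for a, b in combinations(range(n_leaves), 2):
        mat[a, b] = mat[b, a] = dist[(labels[a], labels[b])]
    mat /= mat.max() * 1.05  # rescaling preserves additivity and topology
    canon = {
        min(frozenset(s), all_leaves - s, key=lambda t: (len(t), tuple(sorted(t))))
        for s in bipartitions
    }
    return labels, mat, canon


def mean_pairwise_identity_bruteforce(members, align_fn) -> float:
    """All-pairs mean identity over members from distinct genomes."""
    vals = []
    for (ga, _, sa), (gb, _, sb) in combinations(members, 2):
        if ga == gb:
            continue
        vals.append(align_fn(sa, sb))
    return float(np.mean(vals)) if vals else 1.0
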