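"""Genome-BLAST Distance Phylogeny (GBDP) with pseudo-bootstrap and
fraction-of-links clustering.

Pairwise genome distances are derived from merged HSP statistics: with
``H`` = covered positions, ``I`` = identical positions per genome and ``L``
genome lengths,

* ``d0 = 1 - (HA + HB) / (LA + LB)``  (coverage distance; default),
* ``d4 = 1 - (IA + IB) / (HA + HB)``  (identity within aligned regions),
* ``d6 = 1 - (IA + IB) / (LA + LB)``  (identity over whole genomes),

so ``(1 - d6) = (1 - d4)(1 - d0)`` holds algebraically.  Trees are built by
neighbor joining (negative branch lengths clamped to zero); branch support
comes from pseudo-bootstrap replicates that resample every pair's HSP set
with replacement.  Taxon boundaries are estimated by agglomerative
fraction-of-links clustering (OPTSIL-style): two clusters fuse while the
fraction of their inter-cluster distance links at or below the threshold is
at least ``F``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj

from phagetax.align import HSP, AlignParams, find_hsps_nt, merge_hsps
from phagetax.seqio import GenomeRecord
from phagetax.similarity import Partition

FORMULAS = ("d0", "d4", "d6")


@dataclass
class GbdpParams:
    formula: str = "d0"
    replicates: int = 100
    F: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.formula not in FORMULAS:
            raise ValueError(f"formula must be one of {FORMULAS}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.F <= 1:
            raise ValueError("F must be in (0, 1]")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


def gbdp_distance(
    A: GenomeRecord, B: GenomeRecord, hsps: Sequence[HSP], formula: str = "d0"
) -> float:
    """One GBDP distance from the HSP set of a genome pair."""
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {FORMULAS}")
    la, lb = A.length, B.length
    if not hsps:
        return 1.0
    ha, ia = merge_hsps(hsps, "query", la)
    hb, ib = merge_hsps(hsps, "subject", lb)
    if formula == "d0":
        d = 1.0 - (ha + hb) / (la + lb)
    elif formula == "d4":
        d = 1.0 - (ia + ib) / (ha + hb) if (ha + hb) else 1.0
    else:
        d = 1.0 - (ia + ib) / (la + lb)
    return float(min(max(d, 0.0), 1.0))


def pairwise_hsps(
    genomes: Sequence[GenomeRecord], align_params: AlignParams | None = None
) -> dict[tuple[int, int], list[HSP]]:
    """HSP sets for every unordered genome pair (query = lower index)."""
    align_params = align_params or AlignParams()
    store: dict[tuple[int, int], list[HSP]] = {}
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            store[(i, j)] = find_hsps_nt(genomes[i], genomes[j], align_params)
    return store


def distance_matrix_from_hsps(
    genomes: Sequence[GenomeRecord],
    store: dict[tuple[int, int], list[HSP]],
    formula: str = "d0",
) -> DistanceMatrix:
    n = len(genomes)
    vals = np.zeros((n, n))
    for (i, j), hsps in store.items():
        d = gbdp_distance(genomes[i], genomes[j], hsps, formula)
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids=[g.id for g in genomes], values=vals)


def gbdp_distance_matrix(
    genomes: Sequence[GenomeRecord],
    formula: str = "d0",
    align_params: AlignParams | None = None,
) -> DistanceMatrix:
    return distance_matrix_from_hsps(genomes, pairwise_hsps(genomes, align_params), formula)


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (negative branch lengths clamped to zero)."""
    if len(D.ids) < 3:
        raise ValueError("need >= 3 taxa for a tree")
    dm = _SkbioDM(D.values, ids=D.ids)
    return nj(dm)


def _bipartitions(tree: TreeNode, all_tips: frozenset[str]) -> set[frozenset[str]]:
    """Canonical non-trivial bipartitions (smaller side, ties by sorted names)."""
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out.add(canon)
    return out


def bootstrap_supports(
    genomes: Sequence[GenomeRecord],
    params: GbdpParams | None = None,
    align_params: AlignParams | None = None,
    store: Optional[dict[tuple[int, int], list[HSP]]] = None,
) -> TreeNode:
    """Point-estimate NJ tree with pseudo-bootstrap supports (% of replicates
    containing each internal bipartition) as internal node names."""
    params = params or GbdpParams()
    if store is None:
        store = pairwise_hsps(genomes, align_params)
    point_dm = distance_matrix_from_hsps(genomes, store, params.formula)
    tree = nj_tree(point_dm)
    all_tips = frozenset(g.id for g in genomes)
    rng = np.random.default_rng(params.seed)
    counts: dict[frozenset[str], int] = {}
    n = len(genomes)
    for _ in range(params.replicates):
        vals = np.zeros((n, n))
        for (i, j), hsps in store.items():
            if hsps:
                pick = rng.integers(0, len(hsps), size=len(hsps))
                sample = [hsps[k] for k in pick]
            else:
                sample = []
            d = gbdp_distance(genomes[i], genomes[j], sample, params.formula)
            vals[i, j] = vals[j, i] = d
        rep_tree = nj_tree(DistanceMatrix(ids=[g.id for g in genomes], values=vals))
        for bp in _bipartitions(rep_tree, all_tips):
            counts[bp] = counts.get(bp, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min(side, all_tips - side, key=lambda s: (len(s), tuple(sorted(s))))
        support = 100.0 * counts.get(canon, 0) / params.replicates
        node.name = f"{support:.0f}"
    return tree


def optsil_cluster(D: DistanceMatrix, distance_threshold: float, F: float = 0.5) -> Partition:
    """Agglomerative fraction-of-links clustering.

    Repeatedly merge the cluster pair whose fraction of inter-cluster
    distances <= ``distance_threshold`` is maximal and >= ``F``; ties are
    broken by smaller maximum, then smaller mean, inter-cluster distance,
    then lexicographically by the smallest member id.  Stops when no pair
    qualifies.  The max-distance tie-break makes the F=1 limit coincide
    exactly with complete-linkage clustering cut at the threshold.
    """
    if not 0 < F <= 1:
        raise ValueError("F must be in (0, 1]")
    ids = list(D.ids)
    vals = D.values
    clusters: list[list[int]] = [[i] for i in range(len(ids))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dists = [vals[i, j] for i in clusters[a] for j in clusters[b]]
                frac = sum(1 for d in dists if d <= distance_threshold) / len(dists)
                if frac < F:
                    continue
                mean_d = float(np.mean(dists))
                max_d = float(np.max(dists))
                lex = min(min(ids[i] for i in clusters[a]), min(ids[j] for j in clusters[b]))
                key = (-frac, max_d, mean_d, lex)
                if best is None or key < best[0]:
                    best = (key, a, b)
        if best is None:
            break
        _, a, b = best
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
    assignment: dict[str, int] = {}
    order = sorted(range(len(clusters)), key=lambda c: min(clusters[c]))
    for rank, c in enumerate(order):
        for i in clusters[c]:
            assignment[ids[i]] = rank
    return Partition(assignment={gid: assignment[gid] for gid in ids})
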