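"""Intergenomic nucleotide similarity and ICTV threshold taxonomy.

The similarity statistic is the VIRIDIC-style identity-over-total-length
percentage: ``100 * (idA + idB) / (LA + LB)``, where ``idX`` is the number of
identical positions of all merged HSPs projected on genome ``X``.  Species and
genus partitions come from single-linkage clustering of the similarity graph
at the ICTV demarcation thresholds (>= 95% species, >= 70% genus), with
species edges also counted as genus edges so the species partition always
refines the genus partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from phagetax.align import AlignParams, find_hsps_nt, merge_hsps
from phagetax.seqio import GenomeRecord


@dataclass
class TaxonThresholds:
    species: float = 95.0
    genus: float = 70.0

    def __post_init__(self) -> None:
        if not self.species > self.genus:
            raise ValueError("species threshold must exceed genus threshold")


@dataclass
class Partition:
    """Cluster assignment of genome ids; cluster indices are ordered by the
    first-seen genome of each cluster."""

    assignment: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def clusters(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for gid, c in self.assignment.items():
            out.setdefault(c, []).append(gid)
        return [out[c] for c in sorted(out)]

    def refines(self, coarser: "Partition") -> bool:
        """True if every cluster of ``self`` is contained in one cluster of
        ``coarser``."""
        for members in self.clusters():
            targets = {coarser.assignment[m] for m in members}
            if len(targets) != 1:
                return False
        return True


@dataclass
class SimilarityMatrix:
    """Symmetric percentage matrix with 100 on the diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("diagonal must be exactly 100")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("values must lie in [0, 100]")

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])


def intergenomic_similarity(
    A: GenomeRecord, B: GenomeRecord, params: AlignParams | None = None
) -> float:
    """Whole-genome similarity percentage of two genomes (symmetric)."""
    if A.id == B.id and A.seq == B.seq:
        return 100.0
    params = params or AlignParams()
    hsps = find_hsps_nt(A, B, params)
    if not hsps:
        return 0.0
    _, id_a = merge_hsps(hsps, "query", A.length)
    _, id_b = merge_hsps(hsps, "subject", B.length)
    sim = 100.0 * (id_a + id_b) / (A.length + B.length)
    return float(min(sim, 100.0))


def similarity_matrix(
    genomes: Sequence[GenomeRecord], params: AlignParams | None = None
) -> SimilarityMatrix:
    """All-pairs similarity matrix in input order."""
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    n = len(genomes)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s = intergenomic_similarity(genomes[i], genomes[j], params)
            vals[i, j] = vals[j, i] = s
    return SimilarityMatrix(ids=ids, values=vals)


def _components_partition(ids: Sequence[str], edges) -> Partition:
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from(edges)
    comp_of: dict[str, set] = {}
    for comp in nx.connected_components(g):
        for node in comp:
            comp_of[node] = comp
    assignment: dict[str, int] = {}
    next_idx = 0
    for gid in ids:  # cluster indices ordered by first-seen genome
        if gid in assignment:
            continue
        for member in sorted(comp_of[gid], key=lambda x: list(ids).index(x)):
            assignment[member] = next_idx
        next_idx += 1
    return Partition(assignment={gid: assignment[gid] for gid in ids})


def cluster_by_threshold(matrix: SimilarityMatrix, threshold: float) -> Partition:
    """Single-linkage clustering: connected components of the graph with
    edges where similarity >= threshold."""
    ids = matrix.ids
    n = len(ids)
    edges = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if matrix.values[i, j] >= threshold
    ]
    return _components_partition(ids, edges)


def assign_taxa(
    matrix: SimilarityMatrix, thresholds: TaxonThresholds | None = None
) -> tuple[Partition, Partition]:
    """Species and genus partitions; species edges also count as genus edges,
    so the species partition refines the genus partition by construction."""
    thresholds = thresholds or TaxonThresholds()
    species = cluster_by_threshold(matrix, thresholds.species)
    ids = matrix.ids
    n = len(ids)
    edges = [
        (ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
        if matrix.values[i, j] >= thresholds.genus
        or species.assignment[ids[i]] == species.assignment[ids[j]]
    ]
    genera = _components_partition(ids, edges)
    return species, genera
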