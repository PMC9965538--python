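"""Reticulate protein-sharing network and viral clusters (VCs).

Proteins from all genomes are clustered into protein clusters (PCs) by
Markov clustering of a local-alignment similarity graph.  Genome pairs are
then connected with a weight of -log10 of the upper-tail hypergeometric
probability of sharing at least the observed number of PCs, and the weighted
genome network is Markov-clustered into viral clusters and, at a higher
inflation, into sub-VCs nested within them — the protein-content analogue of
genus-level grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import hypergeom

from phagetax.align import AlignParams, align_proteins
from phagetax.mcl import markov_cluster
from phagetax.similarity import Partition

MAX_EDGE_WEIGHT = 300.0  # cap for -log10(p) when p underflows


@dataclass
class ProteinClusterSet:
    clusters: list[set[str]]
    membership: dict[str, int]
    genome_of: dict[str, str]

    @property
    def universe_size(self) -> int:
        return len(self.clusters)

    def genome_pcs(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for pid, ci in self.membership.items():
            out.setdefault(self.genome_of[pid], set()).add(ci)
        return out


@dataclass
class GenomeNetwork:
    nodes: list[str]
    edges: list[tuple[str, str, float]]
    min_weight: float = 1.0

    def __post_init__(self) -> None:
        for a, b, w in self.edges:
            if a == b:
                raise ValueError("self-edges are not allowed")
            if w < 0:
                raise ValueError("edge weights must be >= 0")


def _kmers(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_protein_clusters(
    proteomes: Mapping[str, Mapping[str, str]],
    params: AlignParams | None = None,
    min_identity: float = 0.35,
    min_coverage: float = 0.5,
    inflation: float = 2.0,
) -> ProteinClusterSet:
    """Cluster all proteins into PCs.

    ``proteomes`` maps genome id -> {protein id -> aa sequence}; protein ids
    must be globally unique.  Edges require local-alignment identity >=
    ``min_identity`` with coverage >= ``min_coverage`` of the shorter protein.
    """
    params = params or AlignParams()
    if len(proteomes) < 2:
        raise ValueError("need proteomes from >= 2 genomes")
    genome_of: dict[str, str] = {}
    seqs: dict[str, str] = {}
    for gid, prots in proteomes.items():
        if not prots:
            raise ValueError(f"genome {gid!r} has an empty proteome")
        for pid, seq in prots.items():
            if pid in seqs:
                raise ValueError(f"duplicate protein id {pid!r}")
            genome_of[pid] = gid
            seqs[pid] = seq
    pids = sorted(seqs)
    idx = {p: i for i, p in enumerate(pids)}
    n = len(pids)
    kmer_sets = {p: _kmers(seqs[p]) for p in pids}
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pids[i], pids[j]
            if not (kmer_sets[a] & kmer_sets[b]):
                continue
            aln = align_proteins(seqs[a], seqs[b], params)
            if aln.length == 0:
                continue
            shorter_cov = max(aln.a_cov, aln.b_cov) if len(seqs[a]) == len(seqs[b]) else (
                aln.a_cov if len(seqs[a]) < len(seqs[b]) else aln.b_cov
            )
            if aln.identity >= min_identity and shorter_cov >= min_coverage:
                adj[i, j] = adj[j, i] = aln.identity
    groups = markov_cluster(adj, inflation=inflation)
    clusters = [set(pids[i] for i in g) for g in groups]
    membership = {pid: ci for ci, c in enumerate(clusters) for pid in c}
    return ProteinClusterSet(clusters=clusters, membership=membership, genome_of=genome_of)


def _log10_sf(k: int, n_a: int, n_b: int, universe: int) -> float:
    """log10 of the upper-tail hypergeometric probability P(X >= k)."""
    if k <= 0:
        return 0.0
    return float(hypergeom.logsf(k - 1, universe, n_a, n_b) / np.log(10.0))


def shared_pc_significance(k_shared: int, n_a: int, n_b: int, universe: int) -> float:
    """Upper-tail hypergeometric probability of sharing >= ``k_shared``
    protein clusters, drawing ``n_b`` from a universe containing ``n_a``
    successes.  Computed in log space for stability."""
    if not (0 <= k_shared <= min(n_a, n_b) <= universe and max(n_a, n_b) <= universe):
        raise ValueError(
            f"need 0 <= k ({k_shared}) <= min(n_A, n_B) ({min(n_a, n_b)}) "
            f"<= universe ({universe})"
        )
    return float(np.exp(np.log(10.0) * _log10_sf(k_shared, n_a, n_b, universe)))


def build_genome_network(pcs: ProteinClusterSet, min_weight: float = 1.0) -> GenomeNetwork:
    """Hypergeometric-weighted genome network from shared protein clusters."""
    genome_pcs = pcs.genome_pcs()
    nodes = sorted(genome_pcs)
    universe = pcs.universe_size
    edges: list[tuple[str, str, float]] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i], nodes[j]
            k = len(genome_pcs[a] & genome_pcs[b])
            w = min(-_log10_sf(k, len(genome_pcs[a]), len(genome_pcs[b]), universe), MAX_EDGE_WEIGHT)
            if w >= min_weight:
                edges.append((a, b, w))
    return GenomeNetwork(nodes=nodes, edges=edges, min_weight=min_weight)


def _mcl_partition(nodes: list[str], edges, inflation: float) -> Partition:
    idx = {n: i for i, n in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for a, b, w in edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = w
    groups = markov_cluster(adj, inflation=inflation)
    assignment: dict[str, int] = {}
    order: dict[int, int] = {}
    group_of = {}
    for gi, g in enumerate(groups):
        for m in g:
            group_of[m] = gi
    next_idx = 0
    for i, node in enumerate(nodes):
        g = group_of[i]
        if g not in order:
            order[g] = next_idx
            next_idx += 1
        assignment[node] = order[g]
    return Partition(assignment=assignment)


def cluster_viral(
    network: GenomeNetwork, inflation: float = 2.0, sub_inflation: float = 4.0
) -> tuple[Partition, Partition]:
    """Two-pass Markov clustering: VCs at ``inflation``, then sub-VCs at the
    higher ``sub_inflation`` within each VC (so sub-VCs refine VCs)."""
    vcs = _mcl_partition(network.nodes, network.edges, inflation)
    sub_assignment: dict[str, int] = {}
    next_idx = 0
    for members in vcs.clusters():
        member_set = set(members)
        sub_edges = [(a, b, w) for a, b, w in network.edges if a in member_set and b in member_set]
        sub = _mcl_partition(members, sub_edges, sub_inflation)
        for cluster in sub.clusters():
            for m in cluster:
                sub_assignment[m] = next_idx
            next_idx += 1
    sub_vcs = Partition(assignment={n: sub_assignment[n] for n in network.nodes})
    return vcs, sub_vcs
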