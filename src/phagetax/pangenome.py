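"""Ortholog-group clustering and core-proteome extraction.

Proteins from all genomes are clustered into ortholog groups by Markov
clustering of a local-alignment graph at a permissive identity threshold
(30% by default — low enough to hold fast-evolving phage structural proteins
together).  The core proteome is the set of groups with at least one member
in every genome; per-genome accessory percentages and conservation-ranked
marker groups are derived from the same groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np

from phagetax.align import AlignParams, align_proteins
from phagetax.mcl import markov_cluster
from phagetax.network import _kmers


@dataclass
class OrthologGroup:
    group_id: str
    members: list[tuple[str, str, str]]  # (genome id, protein id, sequence)
    mean_pairwise_identity: float
    mean_pairwise_similarity: float
    has_paralogs: bool = False

    @property
    def n_genomes_present(self) -> int:
        return len({g for g, _, _ in self.members})


@dataclass
class CoreProteomeReport:
    core_groups: list[OrthologGroup]
    per_genome: dict[str, dict]  # proteome_size, core, accessory, accessory_pct
    ranked_markers: list[OrthologGroup] = field(default_factory=list)

    @property
    def core_count(self) -> int:
        return len(self.core_groups)


def _group_stats(members: list[tuple[str, str, str]], params: AlignParams) -> tuple[float, float]:
    """Mean pairwise identity and positive-score (similarity) fraction over
    unordered member pairs from distinct genomes."""
    idents, sims = [], []
    for (ga, _, sa), (gb, _, sb) in combinations(members, 2):
        if ga == gb:
            continue
        aln = align_proteins(sa, sb, params)
        idents.append(aln.identity)
        sims.append(aln.similarity)
    if not idents:
        return 1.0, 1.0
    return float(np.mean(idents)), float(np.mean(sims))


def cluster_orthologs(
    proteomes: Mapping[str, Mapping[str, str]],
    min_identity: float = 0.30,
    min_coverage: float = 0.5,
    inflation: float = 1.5,
    params: AlignParams | None = None,
) -> list[OrthologGroup]:
    """All-vs-all ortholog clustering across >= 2 genomes.

    Edges require local identity >= ``min_identity`` and coverage >=
    ``min_coverage`` of the shorter protein.  Paralogs (two members from one
    genome) are permitted but flagged.
    """
    params = params or AlignParams()
    if len(proteomes) < 2:
        raise ValueError("need >= 2 genomes")
    entries: list[tuple[str, str, str]] = []
    for gid, prots in proteomes.items():
        for pid, seq in prots.items():
            entries.append((gid, pid, seq))
    entries.sort(key=lambda t: (t[0], t[1]))
    n = len(entries)
    kmer_sets = [_kmers(s) for _, _, s in entries]
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if not (kmer_sets[i] & kmer_sets[j]):
                continue
            sa, sb = entries[i][2], entries[j][2]
            aln = align_proteins(sa, sb, params)
            if aln.length == 0:
                continue
            shorter_cov = aln.a_cov if len(sa) <= len(sb) else aln.b_cov
            if aln.identity >= min_identity and shorter_cov >= min_coverage:
                adj[i, j] = adj[j, i] = aln.identity
    groups_idx = markov_cluster(adj, inflation=inflation)
    groups: list[OrthologGroup] = []
    for gi, idxs in enumerate(groups_idx):
        members = [entries[i] for i in idxs]
        genomes = [g for g, _, _ in members]
        ident, sim = _group_stats(members, params)
        groups.append(
            OrthologGroup(
                group_id=f"og_{gi + 1}",
                members=members,
                mean_pairwise_identity=ident,
                mean_pairwise_similarity=sim,
                has_paralogs=len(genomes) != len(set(genomes)),
            )
        )
    return groups


def core_proteome(groups: list[OrthologGroup], genome_ids: list[str]) -> CoreProteomeReport:
    """Core groups (present in every genome) and per-genome accessory stats."""
    gid_set = set(genome_ids)
    core = [g for g in groups if {m[0] for m in g.members} >= gid_set]
    core_ids = {g.group_id for g in core}
    per_genome: dict[str, dict] = {}
    for gid in genome_ids:
        total = sum(sum(1 for m in g.members if m[0] == gid) for g in groups)
        in_core = sum(
            sum(1 for m in g.members if m[0] == gid) for g in groups if g.group_id in core_ids
        )
        accessory = total - in_core
        per_genome[gid] = {
            "proteome_size": total,
            "core": in_core,
            "accessory": accessory,
            "accessory_pct": 100.0 * accessory / total if total else 0.0,
        }
    ranked = rank_markers(core, top_n=len(core)) if core else []
    return CoreProteomeReport(core_groups=core, per_genome=per_genome, ranked_markers=ranked)


def rank_markers(core_groups: list[OrthologGroup], top_n: int = 5) -> list[OrthologGroup]:
    """Core groups ranked by mean pairwise identity (most conserved first)."""
    if not core_groups:
        raise ValueError("core proteome is empty")
    ranked = sorted(core_groups, key=lambda g: (-g.mean_pairwise_identity, g.group_id))
    return ranked[:top_n]


def presence_absence_matrix(groups: list[OrthologGroup], genome_ids: list[str]):
    """Gene presence/absence counts (rows = groups, columns = genomes)."""
    mat = np.zeros((len(groups), len(genome_ids)), dtype=int)
    for i, g in enumerate(groups):
        for gid, _, _ in g.members:
            mat[i, genome_ids.index(gid)] += 1
    return [g.group_id for g in groups], mat
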