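"""Synthetic phage genomes, evolved genome clusters, and nanopore-like reads.

The generator emulates the salient statistics of Kuravirus-like podophage
genomes: ~78 kb length at ~42% GC, short (~193 bp) direct terminal repeats
(DTRs), ~120 forward-strand genes laid out in late/middle/early functional
blocks, one capsid-like gene carrying a slippery heptamer (pattern
N1N1N1N2N2N2N3) that drives a -1 programmed ribosomal frameshift into a long
extended isoform, and codon usage optionally planted from a codon-bias
profile.  Genome clusters are planted by evolving a common root so that
intra- and inter-cluster divergences straddle the 95%/70% species/genus
similarity thresholds.  Reads are windows of the packaged linear molecule
(which carries the DTR at both ends), with iid substitution/indel errors and
ligation Y-adapters at the read termini.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from phagetax.codons import AA_TO_CODONS, CODON_TO_AA, SENSE_CODONS, STOP_CODONS, CodonUsageTable
from phagetax.seqio import CdsFeature, GenomeRecord, ReadRecord, revcomp

# Ligation-sequencing Y-adapter sequences (top/bottom strands).
ADAPTER_TOP = "GGCGTCTGCTTGGGTGTTTAACCTTTTTTTTTTAATGTACTTCGTTCAGTTACGTATTGCT"
ADAPTER_BOTTOM = "GCAATACGTAACTGAACGAAGT"

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeSpec:
    """Parameters of a single synthetic phage genome."""

    length: int = 78000
    gc: float = 0.421
    dtr_len: int = 193
    n_genes: int = 120
    slippage_gene: bool = True
    slippage_extension_aa: int = 210
    trna_codon: Optional[str] = "AGA"
    codon_bias_profile: Optional[CodonUsageTable] = None
    id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.dtr_len and self.dtr_len >= self.length / 10:
            raise ValueError("dtr_len must be < length/10")


@dataclass
class ClusterSpec:
    """Planted-partition parameters for a set of related genomes."""

    n_clusters: int = 4
    genomes_per_cluster: list[int] = field(default_factory=lambda: [3, 3, 3, 3])
    intra_divergence: float = 0.10
    inter_divergence: float = 0.45
    indel_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genomes_per_cluster) != self.n_clusters:
            raise ValueError("genomes_per_cluster must have n_clusters entries")
        if any(g < 1 for g in self.genomes_per_cluster):
            raise ValueError("all cluster sizes must be >= 1")
        if not self.intra_divergence < self.inter_divergence:
            raise ValueError("intra_divergence must be < inter_divergence")


@dataclass
class ReadSimParams:
    """Nanopore-like read simulation parameters (iid error model)."""

    n_reads: int = 20
    sub_rate: float = 0.005
    ins_rate: float = 0.002
    del_rate: float = 0.002
    frac_full_length: float = 0.3
    add_adapters: bool = True
    adapter_top: str = ADAPTER_TOP
    adapter_bottom: str = ADAPTER_BOTTOM
    circular_permutation: bool = False
    min_partial_len: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 0.2:
                raise ValueError(f"{name} must be in [0, 0.2]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


@dataclass
class SlipperySiteTruth:
    """Planted frameshift cassette coordinates (1-based genomic)."""

    cds_label: str
    heptamer: str
    heptamer_start: int
    cds_start: int
    natural_stop_end: int
    extended_stop_end: int
    natural_length_aa: int
    extended_length_aa: int


def _heptamer_hits(s: str) -> list[int]:
    """0-based start positions of N1N1N1N2N2N2N3 pattern matches in ``s``."""
    hits = []
    for i in range(len(s) - 6):
        if s[i] == s[i + 1] == s[i + 2] and s[i + 3] == s[i + 4] == s[i + 5]:
            hits.append(i)
    return hits


def _base_probs(gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    g = gc / 2
    return np.array([at, g, g, at])  # A, C, G, T order of _BASES? (A,C,G,T)


def _codon_distribution(gc: float) -> tuple[list[str], np.ndarray]:
    """Sense-codon distribution from iid bases at the target GC."""
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    codons = list(SENSE_CODONS)
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
    return codons, w / w.sum()


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=probs)]) if n > 0 else ""


def _quota_codons(rng: np.random.Generator, m: int, codons: list[str], freqs: np.ndarray) -> list[str]:
    """Deterministic largest-remainder allocation of ``m`` codons to the
    profile frequencies, then a seeded shuffle.  Plants the profile exactly up
    to rounding so codon-usage recovery is not at the mercy of multinomial
    noise."""
    raw = freqs * m
    base = np.floor(raw).astype(int)
    rem = m - base.sum()
    if rem > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:rem]] += 1
    out: list[str] = []
    for c, k in zip(codons, base):
        out.extend([c] * int(k))
    rng.shuffle(out)
    return out


def _profile_freqs(profile: CodonUsageTable) -> tuple[list[str], np.ndarray]:
    codons = list(SENSE_CODONS)
    counts = np.array([profile.counts.get(c, 0) for c in codons], dtype=float)
    if counts.sum() == 0:
        raise ValueError("codon bias profile has no sense-codon counts")
    return codons, counts / counts.sum()


_SLIP_TAIL_PRE = "CATCTG"       # two safe codons before the heptamer cassette
_SLIP_CASSETTE = "GCGGGAAAG"    # ...G | GGA | AAG — heptamer GGGAAAG in frame
_SLIP_LINKER = "GCAGCCGCTGCA"   # 4 codons; -1 frame across them is stop-free
_STOP = "TAA"


def synthesize_phage_genome(
    spec: GenomeSpec,
) -> tuple[GenomeRecord, list[CdsFeature], Optional[SlipperySiteTruth]]:
    """Generate a genome with planted DTRs, gene blocks and (optionally) a
    -1-frameshift cassette.  Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    if spec.codon_bias_profile is not None:
        codons, freqs = _profile_freqs(spec.codon_bias_profile)
    else:
        codons, freqs = _codon_distribution(spec.gc)

    unit_len = spec.length - spec.dtr_len
    span = unit_len - spec.dtr_len - 40
    ext_len = 2 + 3 * spec.slippage_extension_aa + 3 if spec.slippage_gene else 0
    overhead = 26  # mean spacer + upstream stop + start + stop per gene
    body_budget = 0.8 * span - spec.n_genes * overhead - ext_len
    avg_m = body_budget / (3 * spec.n_genes) if spec.n_genes else 0
    if spec.n_genes and avg_m < 40:
        raise ValueError(
            f"infeasible packing: {spec.n_genes} genes do not fit in {spec.length} bp"
        )

    m_sizes = (
        rng.integers(int(0.6 * avg_m), int(1.4 * avg_m) + 1, size=spec.n_genes)
        if spec.n_genes
        else np.array([], dtype=int)
    )
    slip_idx = min(7, spec.n_genes - 1) if (spec.slippage_gene and spec.n_genes) else -1
    if slip_idx >= 0:
        m_sizes[slip_idx] = max(int(m_sizes[slip_idx]), 120)

    n_late = spec.n_genes // 3
    n_middle = spec.n_genes // 3
    modules = (
        ["late"] * n_late
        + ["middle"] * n_middle
        + ["early"] * (spec.n_genes - n_late - n_middle)
    )
    products = {
        "late": "virion morphogenesis/lysis protein",
        "middle": "DNA replication protein",
        "early": "early hypothetical protein",
    }

    pieces: list[str] = []
    pos = 0  # 0-based cursor within the unit

    def emit(s: str) -> None:
        nonlocal pos
        pieces.append(s)
        pos += len(s)

    emit(_random_bases(rng, spec.dtr_len + 20, spec.gc))  # DTR + margin

    features: list[CdsFeature] = []
    truth: Optional[SlipperySiteTruth] = None

    for i in range(spec.n_genes):
        emit(_random_bases(rng, int(rng.integers(5, 31)), spec.gc))
        emit(_STOP)  # in-frame stop directly upstream of the start codon
        gene_start0 = pos
        m = int(m_sizes[i])
        if i == slip_idx:
            body = _quota_codons(rng, m, codons, freqs)
            gene = "ATG" + "".join(body) + _SLIP_TAIL_PRE + _SLIP_CASSETTE + _SLIP_LINKER + _STOP
            # scrub accidental heptamers so the cassette's is the only one in
            # the scan window near the stop
            for _ in range(100):
                window = gene[-45:]
                hits = _heptamer_hits(window)
                if len(hits) == 1 and window[hits[0] : hits[0] + 7] == "GGGAAAG":
                    break
                body[-5:] = _quota_codons(rng, 5, codons, freqs)
                gene = "ATG" + "".join(body) + _SLIP_TAIL_PRE + _SLIP_CASSETTE + _SLIP_LINKER + _STOP
            emit(gene)
            hept_start0 = gene_start0 + 3 + 3 * m + len(_SLIP_TAIL_PRE) + 2
            stop_end0 = pos - 1
            # extension region: -1-frame codon stream, stop-free, then TAA
            ext_codons = [codons[j] for j in rng.choice(len(codons), size=spec.slippage_extension_aa, p=freqs)]
            ext = _random_bases(rng, 2, spec.gc) + "".join(ext_codons) + _STOP
            emit(ext)
            extended_stop_end0 = pos - 1
            features.append(
                CdsFeature(
                    genome_id=spec.id,
                    start=gene_start0 + 1,
                    end=stop_end0 + 1,
                    strand="+",
                    label=f"gp{i + 1}",
                    product="major capsid protein (frameshift cassette)",
                )
            )
            natural_aa = (stop_end0 - gene_start0 + 1) // 3 - 1
            extended_aa = (extended_stop_end0 + 1 - (gene_start0 + 1) + 2) // 3 - 1
            truth = SlipperySiteTruth(
                cds_label=f"gp{i + 1}",
                heptamer="GGGAAAG",
                heptamer_start=hept_start0 + 1,
                cds_start=gene_start0 + 1,
                natural_stop_end=stop_end0 + 1,
                extended_stop_end=extended_stop_end0 + 1,
                natural_length_aa=natural_aa,
                extended_length_aa=extended_aa,
            )
        else:
            body = _quota_codons(rng, m, codons, freqs)
            gene = "ATG" + "".join(body) + _STOP
            for _ in range(100):
                if not _heptamer_hits(gene[-43:]):
                    break
                body[-15:] = _quota_codons(rng, min(15, len(body)), codons, freqs)
                gene = "ATG" + "".join(body) + _STOP
            emit(gene)
            features.append(
                CdsFeature(
                    genome_id=spec.id,
                    start=gene_start0 + 1,
                    end=pos,
                    strand="+",
                    label=f"gp{i + 1}",
                    product=products[modules[i]],
                )
            )
        if pos > unit_len - 40:
            raise ValueError("infeasible packing: genes overflow the genome unit")

    emit(_random_bases(rng, unit_len - pos, spec.gc))
    body_seq = "".join(pieces)
    assert len(body_seq) == unit_len
    genome_seq = body_seq + body_seq[: spec.dtr_len]
    record = GenomeRecord(id=spec.id, seq=genome_seq, features=features or None)
    return record, features, truth


def evolve_genome(
    ancestor: GenomeRecord | str,
    divergence: float,
    indel_rate: float = 0.05,
    seed: int = 0,
    id: Optional[str] = None,
) -> GenomeRecord:
    """Mutate a genome: iid substitutions at the given per-site divergence,
    plus indel events (geometric lengths, mean 3 bp) making up ``indel_rate``
    of all mutation events."""
    if not 0 <= divergence <= 0.6:
        raise ValueError("divergence must be in [0, 0.6] (alignment signal assumption)")
    seq = ancestor.seq if hasattr(ancestor, "seq") else ancestor
    anc_id = ancestor.id if hasattr(ancestor, "id") else "ancestor"
    rng = np.random.default_rng(seed)
    gc = (seq.count("G") + seq.count("C")) / max(len(seq), 1)

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    code = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    enc = code[arr]
    L = enc.shape[0]

    sub_mask = (rng.random(L) < divergence) & (enc < 4)
    idx = np.nonzero(sub_mask)[0]
    shift = rng.integers(1, 4, size=idx.size)
    enc[idx] = (enc[idx] + shift) % 4
    bases = np.frombuffer(b"ACGTN", dtype=np.uint8)
    mutated = bases[enc].tobytes().decode("ascii")

    ind_rate = divergence * indel_rate / (1 - indel_rate) if indel_rate < 1 else 0.0
    if ind_rate > 0:
        events = np.nonzero(rng.random(L) < ind_rate)[0]
    else:
        events = np.array([], dtype=int)
    out: list[str] = []
    prev = 0
    for epos in events:
        if epos < prev:
            continue
        out.append(mutated[prev:epos])
        elen = int(rng.geometric(1 / 3))
        if rng.random() < 0.5:  # insertion
            out.append(_random_bases(rng, elen, gc))
            prev = epos
        else:  # deletion
            prev = epos + elen
    out.append(mutated[prev:])
    new_seq = "".join(out)
    return GenomeRecord(id=id or f"{anc_id}_mut{seed}", seq=new_seq)


def simulate_clustered_genomes(
    spec: ClusterSpec, genome_spec: Optional[GenomeSpec] = None
) -> tuple[list[GenomeRecord], dict[str, int]]:
    """Planted-partition genome set: a synthesized root, cluster ancestors at
    ``inter_divergence`` from the root, members at ``intra_divergence`` from
    their ancestor.  Returns (records, truth labels)."""
    genome_spec = genome_spec or GenomeSpec()
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(1 + spec.n_clusters + sum(spec.genomes_per_cluster))]
    root, _, _ = synthesize_phage_genome(
        GenomeSpec(**{**genome_spec.__dict__, "seed": seeds[0], "id": "root"})
    )
    records: list[GenomeRecord] = []
    labels: dict[str, int] = {}
    k = 1
    member_seed = 1 + spec.n_clusters
    for ci in range(spec.n_clusters):
        ancestor = (
            evolve_genome(root, spec.inter_divergence, spec.indel_rate, seed=seeds[k], id=f"anc{ci}")
            if spec.inter_divergence > 0
            else root
        )
        k += 1
        for gi in range(spec.genomes_per_cluster[ci]):
            gid = f"c{ci}_g{gi}"
            rec = (
                evolve_genome(ancestor, spec.intra_divergence, spec.indel_rate, seed=seeds[member_seed], id=gid)
                if spec.intra_divergence > 0
                else GenomeRecord(id=gid, seq=ancestor.seq)
            )
            member_seed += 1
            records.append(rec)
            labels[gid] = ci
    return records, labels


def _inject_errors(seq: str, params: ReadSimParams, rng: np.random.Generator, gc: float) -> str:
    out: list[str] = []
    other = {b: "ACGT".replace(b, "") for b in "ACGT"}
    L = len(seq)
    subs = rng.random(L) < params.sub_rate
    inss = rng.random(L) < params.ins_rate
    dels = rng.random(L) < params.del_rate
    for i, b in enumerate(seq):
        if inss[i]:
            out.append(_random_bases(rng, 1, gc))
        if dels[i]:
            continue
        if subs[i] and b in other:
            out.append(other[b][int(rng.integers(0, 3))])
        else:
            out.append(b)
    return "".join(out)


def simulate_reads(genome: GenomeRecord | str, params: ReadSimParams) -> list[ReadRecord]:
    """Simulate long reads from the packaged linear molecule.

    Full-length reads traverse the whole molecule (both DTR copies); partial
    reads are internal windows.  With ``circular_permutation`` reads are
    rotated windows of a two-unit concatemer (headful-style packaging, no
    fixed termini).  ~50% of reads are reverse-complemented; Y-adapters are
    appended at both ends when ``add_adapters``.
    """
    seq = genome.seq if hasattr(genome, "seq") else genome
    n = len(seq)
    rng = np.random.default_rng(params.seed)
    gc = (seq.count("G") + seq.count("C")) / max(n, 1)
    reads: list[ReadRecord] = []
    concat = seq + seq
    for i in range(params.n_reads):
        full = rng.random() < params.frac_full_length
        if params.circular_permutation:
            start = int(rng.integers(0, n))
            length = n if full else int(rng.integers(min(params.min_partial_len, n // 2), n))
            frag = concat[start : start + length]
        elif full:
            frag = seq
        else:
            length = int(rng.integers(min(params.min_partial_len, n // 2), n))
            start = int(rng.integers(0, n - length + 1))
            frag = seq[start : start + length]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        if params.add_adapters:
            frag = params.adapter_top + frag + revcomp(params.adapter_bottom)
        if params.sub_rate or params.ins_rate or params.del_rate:
            frag = _inject_errors(frag, params, rng, gc)
        reads.append(ReadRecord(id=f"read_{i}", seq=frag, quals=[30] * len(frag)))
    return reads


def synthesize_frameshift_construct(
    cds_start: int = 7253,
    cds_end: int = 8314,
    heptamer_start: int = 8293,
    minus1_stop_end: int = 9930,
    total_length: int = 10500,
    gc: float = 0.421,
    seed: int = 0,
) -> tuple[GenomeRecord, CdsFeature]:
    """Minimal synthetic genome carrying one -1-frameshift cassette at exact
    1-based coordinates: a forward CDS at ``cds_start..cds_end`` with a
    GGGAAAG heptamer at ``heptamer_start`` (its last base on a codon
    boundary) and the first -1-frame stop ending at ``minus1_stop_end``.

    Used to reproduce printed isoform coordinates without a full genome.
    """
    hept_end = heptamer_start + 6
    if (hept_end - cds_start + 1) % 3:
        raise ValueError("heptamer end must fall on a codon boundary of the CDS")
    if (cds_end - cds_start + 1) % 3:
        raise ValueError("CDS length must be divisible by 3")
    if not cds_start <= heptamer_start <= cds_end - 6:
        raise ValueError("heptamer must lie inside the CDS")
    slip = hept_end  # 1-based position of the re-read base
    if (minus1_stop_end - slip - 2) % 3:
        raise ValueError("-1-frame stop end incompatible with the slip position")
    if minus1_stop_end + 10 > total_length:
        raise ValueError("total_length too short for the cassette")

    rng = np.random.default_rng(seed)
    codon_list, codon_freqs = _codon_distribution(gc)
    seq = list(_random_bases(rng, total_length, gc))

    def put(pos1: int, s: str) -> None:
        seq[pos1 - 1 : pos1 - 1 + len(s)] = list(s)

    # gene body: sense codons up to the codon preceding the heptamer region
    n_body = (heptamer_start - 1 - cds_start + 1 - 2) // 3  # codons before the X?G codon
    body = [codon_list[j] for j in rng.choice(len(codon_list), size=n_body - 1, p=codon_freqs)]
    put(cds_start, "ATG" + "".join(body))
    # heptamer split as [X?G][GGA][AAG]: the partial codon ends with G
    put(heptamer_start - 2, "CTG")
    put(heptamer_start + 1, "GGAAAG")
    # gene tail after the heptamer: GCA repeats (stop-free in both 0 and -1
    # frames) then the natural stop
    tail_codons = (cds_end - 3 - hept_end) // 3
    put(hept_end + 1, "GCA" * tail_codons)
    put(cds_end - 2, _STOP)
    # -1 frame after the CDS: pad to the next -1 codon boundary, then sense
    # codons, then the planted -1 stop
    first_free_m1 = slip + 3 * ((cds_end - slip) // 3 + 1)  # first -1 codon fully past cds_end
    put(cds_end + 1, "C" * (first_free_m1 - cds_end - 1))
    n_ext = (minus1_stop_end - 2 - first_free_m1) // 3
    ext = [codon_list[j] for j in rng.choice(len(codon_list), size=n_ext, p=codon_freqs)]
    put(first_free_m1, "".join(ext))
    put(minus1_stop_end - 2, _STOP)

    genome = GenomeRecord(id="frameshift_construct", seq="".join(seq))
    cds = CdsFeature(
        genome_id=genome.id, start=cds_start, end=cds_end, strand="+",
        label="mcp", product="major capsid protein",
    )
    # the cassette must be internally consistent: no 0-frame internal stop, no
    # -1-frame stop before the planted one
    for i in range(cds_start - 1, cds_end - 3, 3):
        if "".join(seq[i : i + 3]) in STOP_CODONS:
            raise AssertionError("internal 0-frame stop in constructed CDS")
    for p in range(slip - 1, minus1_stop_end - 3, 3):
        if "".join(seq[p : p + 3]) in STOP_CODONS:
            raise AssertionError("premature -1-frame stop in construct")
    return genome, cds


def mutate_protein(seq: str, divergence: float, seed: int = 0) -> str:
    """Substitute amino acids iid at the given rate (test/planting helper)."""
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for ch in seq:
        if rng.random() < divergence:
            choices = aas.replace(ch, "") if ch in aas else aas
            out.append(choices[int(rng.integers(0, len(choices)))])
        else:
            out.append(ch)
    return "".join(out)
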