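"""Genome-feature analyses: adapter screening, direct-terminal-repeat (DTR)
detection, ORF calling, -1 programmed ribosomal frameshift prediction, and
codon-usage bias against a host.

The frameshift model: a slippery heptamer (pattern N1N1N1 N2N2N2 N3, e.g.
GGGAAAG) near the natural stop lets the ribosome slip back one nucleotide at
the last in-frame codon boundary inside the heptamer, re-reading that base
and continuing in the -1 frame until the next stop — producing an extended
protein isoform.  When the -1 frame stops almost immediately the extension
is biologically invisible (reported as ``premature_stop``).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from phagetax.align import AlignParams, find_hsps_nt
from phagetax.codons import CODON_TO_AA, STOP_CODONS, CodonUsageTable
from phagetax.seqio import CdsFeature, GenomeRecord, ReadRecord, revcomp
from phagetax.simulate import ADAPTER_BOTTOM, ADAPTER_TOP

DEFAULT_ADAPTERS = (
    ADAPTER_TOP,
    ADAPTER_BOTTOM,
    revcomp(ADAPTER_TOP),
    revcomp(ADAPTER_BOTTOM),
)


# ---------------------------------------------------------------------------
# Adapter screening


def trim_adapters(
    read: ReadRecord,
    adapters: Sequence[str] = DEFAULT_ADAPTERS,
    window: int = 150,
    min_identity: float = 0.75,
) -> ReadRecord:
    """Trim adapter matches from the terminal windows of a read.

    Only the first/last ``window`` nt are scanned; the read interior is never
    modified.  A terminal match at >= ``min_identity`` truncates the read
    through the match (prefix) or from the match on (suffix).  Idempotent.
    """
    if not adapters:
        raise ValueError("adapters must be non-empty")
    seq = read.seq
    cut_start = 0
    cut_end = len(seq)
    head = seq[: min(window, len(seq))]
    for ad in adapters:
        k = int(len(ad) * (1 - min_identity))
        r = edlib.align(ad, head, mode="HW", task="locations", k=k)
        if r["editDistance"] >= 0:
            end = max(loc[1] for loc in r["locations"]) + 1
            cut_start = max(cut_start, end)
    # suffix scan starts after the prefix cut so a single terminal adapter is
    # not trimmed twice on reads shorter than two windows
    tail_off = max(cut_start, len(seq) - window)
    tail = seq[tail_off:]
    for ad in adapters:
        k = int(len(ad) * (1 - min_identity))
        r = edlib.align(ad, tail, mode="HW", task="locations", k=k)
        if r["editDistance"] >= 0:
            start = tail_off + min(loc[0] for loc in r["locations"])
            cut_end = min(cut_end, start)
    if cut_start >= cut_end:
        return ReadRecord(id=read.id, seq="", quals=[] if read.quals is not None else None)
    return ReadRecord(
        id=read.id,
        seq=seq[cut_start:cut_end],
        quals=read.quals[cut_start:cut_end] if read.quals is not None else None,
    )


# ---------------------------------------------------------------------------
# Termini / DTR detection


@dataclass
class TerminiReport:
    dtr_length: int
    dtr_sequence: str
    n_supporting_reads: int
    per_read_lengths: list[int] = field(default_factory=list)
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "dtr_length": self.dtr_length,
            "dtr_sequence": self.dtr_sequence,
            "n_supporting_reads": self.n_supporting_reads,
            "per_read_lengths": self.per_read_lengths,
            "warning": self.warning,
        }


def _orient_read(seq: str, fwd_kmers: set[str], k: int = 15, stride: int = 97) -> str:
    fwd = sum(1 for i in range(0, len(seq) - k, stride) if seq[i : i + k] in fwd_kmers)
    rc = revcomp(seq)
    rev = sum(1 for i in range(0, len(rc) - k, stride) if rc[i : i + k] in fwd_kmers)
    return seq if fwd >= rev else rc


def _read_repeat_length(
    seq: str,
    assembly: str,
    anchor_len: int,
    max_dtr: int,
    min_identity: float,
) -> int:
    """Terminal-repeat length supported by one oriented full-length read.

    The assembly's first ``anchor_len`` bases (the DTR start) are located in
    the read's terminal window; the remaining read tail is then aligned
    semi-globally onto the assembly prefix, whose end position is the repeat
    length.  Alignment against the error-free assembly keeps the estimate
    robust to read indels.
    """
    anchor = assembly[:anchor_len]
    search = seq[-(max_dtr + 300) :]
    k = int(anchor_len * (1 - min_identity))
    r = edlib.align(anchor, search, mode="HW", task="locations", k=k)
    if r["editDistance"] < 0:
        return 0
    t = len(seq) - len(search) + min(loc[0] for loc in r["locations"])
    tail = seq[t:]
    if len(tail) < anchor_len:
        return 0
    ref = assembly[: max_dtr + 200]
    r2 = edlib.align(tail, ref, mode="SHW", task="locations")
    if r2["editDistance"] < 0:
        return 0
    end = r2["locations"][0][1] + 1
    if end > max_dtr:
        return 0
    if 1 - r2["editDistance"] / max(len(tail), 1) < min_identity:
        return 0
    return end


def detect_termini_from_reads(
    reads: Sequence[ReadRecord],
    assembly: GenomeRecord,
    min_read_len: Optional[int] = None,
    anchor_len: int = 50,
    min_identity: float = 0.9,
    max_dtr: int = 1000,
    min_supporting: int = 2,
    adapters: Sequence[str] = DEFAULT_ADAPTERS,
) -> TerminiReport:
    """Detect the DTR length from full-length long reads.

    Reads are adapter-trimmed, filtered to ``min_read_len`` (default: 99% of
    the assembly length, mirroring read filters set slightly below the genome
    size so that genome-spanning reads with a net deletion excess still
    qualify), oriented against the assembly, and each is asked for a terminal
    repeat (>= ``anchor_len`` window re-occurring at >= ``min_identity`` near
    the read end).  The report carries the modal per-read repeat length and a
    per-column majority-vote consensus.
    """
    if min_read_len is None:
        min_read_len = round(0.99 * assembly.length)
    k = 15
    fwd_kmers = {assembly.seq[i : i + k] for i in range(assembly.length - k)}
    lengths: list[int] = []
    repeat_seqs: list[str] = []
    n_qualifying = 0
    for read in reads:
        trimmed = trim_adapters(read, adapters)
        if len(trimmed.seq) < min_read_len:
            continue
        n_qualifying += 1
        seq = _orient_read(trimmed.seq, fwd_kmers)
        L = _read_repeat_length(seq, assembly.seq, anchor_len, max_dtr, min_identity)
        if L > 0:
            lengths.append(L)
            repeat_seqs.append(seq[-L:])
    if n_qualifying == 0:
        return TerminiReport(0, "", 0, [], warning="no reads passed the length filter")
    if len(lengths) < min_supporting:
        return TerminiReport(0, "", len(lengths), lengths,
                             warning="insufficient supporting reads")
    modal = Counter(lengths).most_common(1)[0][0]
    votes = [s[:modal].ljust(modal, "N") for s in repeat_seqs]
    consensus = "".join(
        Counter(col).most_common(1)[0][0] for col in zip(*votes)
    )
    return TerminiReport(
        dtr_length=modal,
        dtr_sequence=consensus,
        n_supporting_reads=len(lengths),
        per_read_lengths=lengths,
    )


def detect_dtr_in_assembly(
    assembly: GenomeRecord,
    max_dtr: int = 1000,
    min_identity: float = 0.95,
    min_dtr: int = 25,
) -> TerminiReport:
    """Assembly-level DTR: the prefix/suffix overlap length maximizing
    ``matches - penalty * edits`` (penalty ``1/(1-min_identity)``), subject to
    the identity floor.  Returns length 0 when nothing qualifies."""
    seq = assembly.seq
    n = len(seq)
    hi = min(max_dtr, n // 2)
    penalty = 1.0 / (1.0 - min_identity)
    best_len, best_score = 0, 0.0
    for L in range(min_dtr, hi + 1):
        k = int(L * (1 - min_identity)) + 1
        r = edlib.align(seq[:L], seq[n - L :], mode="NW", k=k)
        d = r["editDistance"]
        if d < 0 or 1 - d / L < min_identity:
            continue
        score = L - penalty * d
        if score > best_score:
            best_score, best_len = score, L
    return TerminiReport(
        dtr_length=best_len,
        dtr_sequence=seq[:best_len],
        n_supporting_reads=0,
        per_read_lengths=[],
        warning=None if best_len else "no terminal repeat detected",
    )


def find_dtr_by_similarity(
    dtr_seq: str,
    genome: GenomeRecord,
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
    terminus_window: int = 2000,
) -> list[tuple[int, int, float]]:
    """Search a known DTR sequence against a genome's termini.

    Returns (start, end, identity) genomic hits at >= ``min_identity`` over
    >= ``min_coverage`` of the query.
    """
    if not 50 <= len(dtr_seq) <= 1000:
        raise ValueError("DTR query must be 50-1000 bp")
    n = genome.length
    w = min(terminus_window, n)
    params = AlignParams(word_size=8, min_hsp_score=20)
    hits: list[tuple[int, int, float]] = []
    for offset, window in ((0, genome.seq[:w]), (n - w, genome.seq[n - w :])):
        for h in find_hsps_nt(dtr_seq, window, params):
            if h.identity >= min_identity and h.length >= min_coverage * len(dtr_seq):
                s, e = sorted((h.s_start, h.s_end))
                hit = (offset + s, offset + e, round(h.identity, 4))
                if hit not in hits:
                    hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# ORF calling


def find_orfs(
    genome: GenomeRecord,
    min_aa: int = 30,
    starts: frozenset[str] = frozenset({"ATG", "GTG", "TTG"}),
) -> list[CdsFeature]:
    """Deterministic maximal-ORF caller on both strands.

    An ORF runs from the first in-frame start codon after the previous
    in-frame stop to the next stop (inclusive); minimum length ``min_aa``
    coding codons.  Overlapping same-frame ORFs are maximal by construction.
    """
    out: list[CdsFeature] = []
    n = genome.length
    if n == 0:
        return out
    counter = 0
    for strand, seq in (("+", genome.seq), ("-", revcomp(genome.seq))):
        for off in range(3):
            pending: Optional[int] = None
            for i in range(off, n - 2, 3):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS:
                    if pending is not None:
                        aa_len = (i - pending) // 3
                        if aa_len >= min_aa:
                            counter += 1
                            if strand == "+":
                                start, end = pending + 1, i + 3
                            else:
                                start, end = n - (i + 3) + 1, n - pending
                            out.append(
                                CdsFeature(
                                    genome_id=genome.id,
                                    start=start,
                                    end=end,
                                    strand=strand,
                                    label=f"orf_{counter}",
                                )
                            )
                    pending = None
                elif pending is None and codon in starts:
                    pending = i
    out.sort(key=lambda f: (f.start, f.end, f.strand))
    return out


# ---------------------------------------------------------------------------
# Slippery sites and -1 frameshift isoforms


@dataclass
class SlipperySite:
    """A heptamer matching N1N1N1 N2N2N2 N3 near a CDS stop.

    ``position`` is the 1-based genomic coordinate (plus-strand reference) of
    the heptamer's first coding base; ``offset_to_stop`` is measured along the
    coding strand from heptamer start to the last base of the stop codon.
    """

    position: int
    heptamer: str
    cds_label: str
    offset_to_stop: int

    def __post_init__(self) -> None:
        h = self.heptamer
        if len(h) != 7 or not (h[0] == h[1] == h[2] and h[3] == h[4] == h[5]):
            raise ValueError(f"{h!r} does not match the N1N1N1N2N2N2N3 pattern")


@dataclass
class SlippageReport:
    natural_length_aa: int
    extended_length_aa: int
    extended_end: int
    premature_stop: bool
    site: Optional[SlipperySite] = None

    def to_dict(self) -> dict:
        return {
            "natural_length_aa": self.natural_length_aa,
            "extended_length_aa": self.extended_length_aa,
            "extended_end": self.extended_end,
            "premature_stop": self.premature_stop,
            "heptamer": self.site.heptamer if self.site else None,
            "heptamer_position": self.site.position if self.site else None,
        }


def _coding_context(genome: GenomeRecord, cds: CdsFeature) -> tuple[str, int]:
    """Coding-strand sequence from the CDS start to the end of the genome (in
    coding orientation) and the 0-based offset of the CDS start within it."""
    if cds.strand == "+":
        return genome.seq[cds.start - 1 :], 0
    return revcomp(genome.seq[: cds.end]), 0


def find_slippery_sites(
    genome: GenomeRecord, cds: CdsFeature, window: int = 30
) -> list[SlipperySite]:
    """All pattern heptamers whose start lies within ``window`` nt upstream
    of the CDS stop (precisely: start in [stop_end - window - 6, stop_end])."""
    cseq, _ = _coding_context(genome, cds)
    cds_len = len(cds)
    stop_end_rel = cds_len  # 1-based along coding strand, from cds start
    lo = max(1, stop_end_rel - window - 6)
    hi = min(stop_end_rel, cds_len - 6, len(cseq) - 6)  # heptamer fully inside the CDS
    sites: list[SlipperySite] = []
    for rel in range(lo, hi + 1):  # 1-based start of heptamer along coding strand
        h = cseq[rel - 1 : rel + 6]
        if len(h) == 7 and h[0] == h[1] == h[2] and h[3] == h[4] == h[5]:
            if cds.strand == "+":
                pos = cds.start + rel - 1
            else:
                pos = cds.end - rel + 1
            sites.append(
                SlipperySite(
                    position=pos,
                    heptamer=h,
                    cds_label=cds.label,
                    offset_to_stop=stop_end_rel - rel,
                )
            )
    return sites


def predict_extended_isoform(
    genome: GenomeRecord, cds: CdsFeature, site: SlipperySite
) -> SlippageReport:
    """Predict the -1 frameshift extended isoform for a slippery site.

    The ribosome translates 0-frame codons through the codon ending at the
    heptamer's last base (which must coincide with a codon boundary), then
    resumes one nucleotide back — re-reading that base — in the -1 frame
    until the next stop.
    """
    cseq, _ = _coding_context(genome, cds)
    cds_len = len(cds)
    if cds.strand == "+":
        hept_rel = site.position - cds.start + 1  # 1-based along coding strand
    else:
        hept_rel = cds.end - site.position + 1
    slip_rel = hept_rel + 6  # last base of the heptamer
    if slip_rel % 3 != 0:
        raise ValueError(
            "heptamer end does not coincide with a 0-frame codon boundary"
        )
    natural_aa = cds_len // 3 - 1
    # -1 frame codons start at the re-read base (slip_rel, 1-based)
    pos = slip_rel - 1  # 0-based index of the re-read base in cseq
    extended_end_rel = None
    while pos + 3 <= len(cseq):
        codon = cseq[pos : pos + 3]
        if codon in STOP_CODONS:
            extended_end_rel = pos + 3  # 1-based end along coding strand
            break
        pos += 3
    if extended_end_rel is None:
        raise ValueError("runaway frame: no -1-frame stop before genome end")
    extended_aa = (extended_end_rel + 2) // 3 - 1
    if cds.strand == "+":
        extended_end = cds.start + extended_end_rel - 1
    else:
        extended_end = cds.end - extended_end_rel + 1
    return SlippageReport(
        natural_length_aa=natural_aa,
        extended_length_aa=extended_aa,
        extended_end=extended_end,
        premature_stop=(extended_aa - natural_aa) <= 20,
        site=site,
    )


# ---------------------------------------------------------------------------
# Codon usage and bias


def codon_usage(cds_sequences: Sequence[str]) -> CodonUsageTable:
    """Codon counts over CDS sequences, excluding each terminal stop.

    Sequences must be in-frame; internal stops raise an error naming the CDS.
    """
    counts: Counter[str] = Counter()
    for idx, seq in enumerate(cds_sequences):
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError(f"CDS #{idx + 1} length {len(seq)} not divisible by 3")
        ncod = len(seq) // 3
        for ci in range(ncod):
            codon = seq[3 * ci : 3 * ci + 3]
            if codon in STOP_CODONS:
                if ci != ncod - 1:
                    raise ValueError(f"internal stop codon in CDS #{idx + 1} at codon {ci + 1}")
                break
            if codon in CODON_TO_AA:
                counts[codon] += 1
    return CodonUsageTable(counts=dict(counts))


@dataclass
class CodonBiasEntry:
    codon: str
    aa: str
    phage_share: float
    host_share: float
    fold_change: float
    direction: str
    unstable: bool = False


def codon_bias(
    phage: CodonUsageTable,
    host: CodonUsageTable,
    min_fold: float = 2.0,
    pseudocount: float = 0.5,
) -> list[CodonBiasEntry]:
    """Codons whose synonymous share differs >= ``min_fold`` between phage
    and host, sorted by |log2 fold change| descending.

    When either raw count is zero the family shares are recomputed with the
    pseudocount and the entry is flagged unstable.
    """
    p_shares = phage.shares()
    h_shares = host.shares()
    p_pseudo = phage.shares(pseudocount)
    h_pseudo = host.shares(pseudocount)
    out: list[CodonBiasEntry] = []
    for codon, aa in CODON_TO_AA.items():
        pc = phage.counts.get(codon, 0)
        hc = host.counts.get(codon, 0)
        unstable = pc == 0 or hc == 0
        ps = p_pseudo[codon] if unstable else p_shares[codon]
        hs = h_pseudo[codon] if unstable else h_shares[codon]
        if hs == 0 or ps == 0:
            continue
        fold = ps / hs
        if fold >= min_fold or fold <= 1 / min_fold:
            out.append(
                CodonBiasEntry(
                    codon=codon,
                    aa=aa,
                    phage_share=ps,
                    host_share=hs,
                    fold_change=fold,
                    direction="up" if fold >= 1 else "down",
                    unstable=unstable,
                )
            )
    out.sort(key=lambda e: (-abs(math.log2(e.fold_change)), e.codon))
    return out
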