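"""Local alignment substrate for the taxonomy pipeline.

Nucleotide genome pairs are compared with a seed-and-extend HSP engine
(exact word seeds on both strands, ungapped x-drop extension along each
seeded diagonal, then greedy chaining of co-linear segments across small
indels with affine gap costs).  Protein pairs are scored with an optimal
local alignment under BLOSUM62 and affine gaps.  Overlapping HSPs are
aggregated into per-genome covered/identical position counts, the raw
material of both the intergenomic-similarity statistic and the GBDP
distance formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from numba import njit

from phagetax.seqio import GenomeRecord, revcomp

_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i


@dataclass
class AlignParams:
    """Scoring parameters for the nucleotide HSP engine and protein aligner.

    Nucleotide defaults (word 11, +1/-2, affine 5/2) approximate megablast-like
    sensitivity for sequences at >= 70% identity, which is the regime the
    genus-demarcation threshold lives in.
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = 2  # penalty (positive)
    gap_open: int = 5
    gap_extend: int = 2
    x_drop: int = 20
    min_hsp_score: int = 30
    protein_matrix: str = "BLOSUM62"
    protein_gap_open: int = 11
    protein_gap_extend: int = 1
    aa_word_size: int = 4
    max_seed_hits_per_word: int = 64
    chain_max_gap: int = 60
    chain_band: int = 30

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        for name in ("mismatch", "gap_open", "gap_extend", "x_drop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive penalty")


@dataclass
class HSP:
    """A high-scoring segment pair (1-based inclusive coordinates).

    For minus-strand HSPs ``s_start > s_end`` (BLAST convention): the subject
    coordinates refer to the original subject strand.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    length: int
    identities: int
    score: int

    @property
    def identity(self) -> float:
        return self.identities / self.length if self.length else 0.0


@njit(cache=True)
def _xdrop_segments(m, match, mismatch, x_drop, min_keep, starts, ends, scores, idents):
    """One-pass maximal-segment scan with x-drop termination on a 0/1 match
    vector along one diagonal.  Returns the number of segments emitted."""
    n = m.shape[0]
    k = 0
    cur = 0
    cur_id = 0
    best = 0
    best_id = 0
    best_end = -1
    start = 0
    for i in range(n):
        if m[i]:
            cur += match
            cur_id += 1
        else:
            cur -= mismatch
        if cur > best:
            best = cur
            best_id = cur_id
            best_end = i
        if cur <= 0 or best - cur >= x_drop:
            if best >= min_keep:
                starts[k] = start
                ends[k] = best_end
                scores[k] = best
                idents[k] = best_id
                k += 1
            cur = 0
            cur_id = 0
            best = 0
            best_id = 0
            best_end = -1
            start = i + 1
    if best >= min_keep:
        starts[k] = start
        ends[k] = best_end
        scores[k] = best
        idents[k] = best_id
        k += 1
    return k


def _encode(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int):
    """Integer codes of all k-mers; windows containing N are marked invalid."""
    n = enc.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + np.minimum(enc[j : n - k + 1 + j], 3).astype(np.int64)
    bad = (enc >= 4).astype(np.int32)
    cbad = np.concatenate(([0], np.cumsum(bad)))
    valid = (cbad[k:] - cbad[:-k]) == 0
    return codes, valid


def _seed_hits(q_enc: np.ndarray, s_enc: np.ndarray, params: AlignParams):
    """(query_pos, subject_pos) pairs of exact word matches, 0-based."""
    k = params.word_size
    q_codes, q_valid = _kmer_codes(q_enc, k)
    s_codes, s_valid = _kmer_codes(s_enc, k)
    if q_codes.size == 0 or s_codes.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    s_pos = np.nonzero(s_valid)[0]
    s_sorted_codes = s_codes[s_pos]
    order = np.argsort(s_sorted_codes, kind="stable")
    s_sorted_codes = s_sorted_codes[order]
    s_pos = s_pos[order]
    q_pos = np.nonzero(q_valid)[0]
    qc = q_codes[q_pos]
    lo = np.searchsorted(s_sorted_codes, qc, side="left")
    hi = np.searchsorted(s_sorted_codes, qc, side="right")
    counts = np.minimum(hi - lo, params.max_seed_hits_per_word)
    total = int(counts.sum())
    out_q = np.empty(total, dtype=np.int64)
    out_s = np.empty(total, dtype=np.int64)
    ptr = 0
    nz = np.nonzero(counts)[0]
    for i in nz:
        c = counts[i]
        out_q[ptr : ptr + c] = q_pos[i]
        out_s[ptr : ptr + c] = s_pos[lo[i] : lo[i] + c]
        ptr += c
    return out_q, out_s


def _segments_on_strand(q_enc, s_enc, params: AlignParams, min_keep: int):
    """Ungapped x-drop segments on all seeded diagonals.

    Returns a list of (q_start0, q_end0, s_start0, s_end0, score, identities).
    """
    hq, hs = _seed_hits(q_enc, s_enc, params)
    if hq.size == 0:
        return []
    diags = np.unique(hs - hq)
    nq, ns = q_enc.shape[0], s_enc.shape[0]
    out = []
    max_seg = None
    for d in diags:
        q0 = max(0, -d)
        q1 = min(nq, ns - d)
        if q1 - q0 < params.word_size:
            continue
        qs = q_enc[q0:q1]
        ss = s_enc[q0 + d : q1 + d]
        m = ((qs == ss) & (qs < 4)).astype(np.uint8)
        cap = (q1 - q0) // max(min_keep, 1) + 2
        starts = np.empty(cap, dtype=np.int64)
        ends = np.empty(cap, dtype=np.int64)
        scores = np.empty(cap, dtype=np.int64)
        idents = np.empty(cap, dtype=np.int64)
        nseg = _xdrop_segments(
            m, params.match, params.mismatch, params.x_drop, min_keep,
            starts, ends, scores, idents,
        )
        for j in range(nseg):
            a, b = q0 + int(starts[j]), q0 + int(ends[j])
            out.append((a, b, a + int(d), b + int(d), int(scores[j]), int(idents[j])))
    return out


def _chain_segments(segs, params: AlignParams):
    """Greedy co-linear chaining of ungapped segments across small indels.

    Chained entries are (q_start0, q_end0, s_start0, s_end0, score,
    identities, length) where length counts aligned (segment) columns only.
    """
    if not segs:
        return []
    segs = sorted(segs, key=lambda t: (t[0], t[2]))
    chains = []  # mutable [qs, qe, ss, se, score, id, length]
    for qs, qe, ss, se, sc, ident in segs:
        seg_len = qe - qs + 1
        best_i = -1
        best_gain = 0
        for i, ch in enumerate(chains):
            qgap = qs - ch[1] - 1
            sgap = ss - ch[3] - 1
            if qgap < 0 or sgap < 0:
                continue
            if qgap > params.chain_max_gap or sgap > params.chain_max_gap:
                continue
            shift = abs(qgap - sgap)
            if shift > params.chain_band:
                continue
            penalty = params.gap_open + params.gap_extend * shift if (qgap or sgap) else 0
            gain = sc - penalty
            if gain > best_gain or (gain == best_gain and best_i == -1 and gain > 0):
                best_gain = gain
                best_i = i
        if best_i >= 0 and best_gain > 0:
            ch = chains[best_i]
            qgap = qs - ch[1] - 1
            sgap = ss - ch[3] - 1
            shift = abs(qgap - sgap)
            penalty = params.gap_open + params.gap_extend * shift if (qgap or sgap) else 0
            ch[1], ch[3] = qe, se
            ch[4] += sc - penalty
            ch[5] += ident
            ch[6] += seg_len
        else:
            chains.append([qs, qe, ss, se, sc, ident, seg_len])
    return [tuple(c) for c in chains]


def find_hsps_nt(query, subject, params: AlignParams | None = None) -> list[HSP]:
    """All HSPs between two nucleotide sequences, both strands.

    ``query``/``subject`` may be :class:`GenomeRecord` or plain strings.
    Output is sorted by (score desc, q_start, s_start) and fully deterministic.
    """
    params = params or AlignParams()
    qseq = query.seq if hasattr(query, "seq") else query
    sseq = subject.seq if hasattr(subject, "seq") else subject
    if not qseq or not sseq:
        raise ValueError("empty sequence")
    q_enc = _encode(qseq)
    min_keep = max(12, params.word_size)
    hsps: list[HSP] = []
    for strand in "+-":
        s_oriented = sseq if strand == "+" else revcomp(sseq)
        s_enc = _encode(s_oriented)
        segs = _segments_on_strand(q_enc, s_enc, params, min_keep)
        chained = _chain_segments(segs, params)
        ns = len(sseq)
        for qs, qe, ss, se, sc, ident, length in chained:
            if sc < params.min_hsp_score:
                continue
            if strand == "+":
                s_start, s_end = ss + 1, se + 1
            else:
                s_start, s_end = ns - ss, ns - se
            hsps.append(
                HSP(
                    q_start=qs + 1,
                    q_end=qe + 1,
                    s_start=s_start,
                    s_end=s_end,
                    strand=strand,
                    length=length,
                    identities=ident,
                    score=sc,
                )
            )
    hsps.sort(key=lambda h: (-h.score, h.q_start, min(h.s_start, h.s_end)))
    return hsps


# ---------------------------------------------------------------------------
# Protein alignment


@lru_cache(maxsize=8)
def _protein_aligner(matrix_name: str, gap_open: int, gap_extend: int):
    from Bio import Align
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(matrix_name)
    if "X" in mat.alphabet:
        mat = mat.copy()
        xi = mat.alphabet.index("X")
        mat[xi, :] = 0.0
        mat[:, xi] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(gap_open)
    aligner.extend_gap_score = -(gap_extend)
    return aligner


@dataclass
class ProteinAlignment:
    score: float
    length: int
    identities: int
    a_cov: float
    b_cov: float
    positives: int = 0

    @property
    def identity(self) -> float:
        return self.identities / self.length if self.length else 0.0

    @property
    def similarity(self) -> float:
        """Fraction of alignment columns with a positive substitution score."""
        return self.positives / self.length if self.length else 0.0


def align_proteins(a: str, b: str, params: AlignParams | None = None) -> ProteinAlignment:
    """Optimal local alignment of two protein sequences.

    Identity is identical columns over alignment length (aligned columns plus
    internal gap columns); coverage is the aligned span over each full protein
    length.  ``X`` scores zero against everything.
    """
    params = params or AlignParams()
    if not a or not b:
        raise ValueError("empty protein sequence")
    aligner = _protein_aligner(
        params.protein_matrix, params.protein_gap_open, params.protein_gap_extend
    )
    alns = aligner.align(a, b)
    aln = alns[0]
    if aln.score <= 0:
        return ProteinAlignment(0.0, 0, 0, 0.0, 0.0)
    c = aln.counts()
    length = (
        c.identities
        + c.mismatches
        + c.internal_insertions
        + c.internal_deletions
    )
    mat = aligner.substitution_matrix
    positives = 0
    for (a0, a1), (b0, b1) in zip(*(rng.tolist() for rng in aln.aligned)):
        for x, y in zip(a[a0:a1], b[b0:b1]):
            if mat[x, y] > 0:
                positives += 1
    a_rng = aln.aligned[0]
    b_rng = aln.aligned[1]
    a_span = int(a_rng[-1][1] - a_rng[0][0])
    b_span = int(abs(b_rng[-1][1] - b_rng[0][0]))
    return ProteinAlignment(
        score=float(aln.score),
        length=int(length),
        identities=int(c.identities),
        a_cov=a_span / len(a),
        b_cov=b_span / len(b),
        positives=positives,
    )


# ---------------------------------------------------------------------------
# HSP aggregation


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def merge_hsps(hsps: Sequence[HSP], axis: str, seq_length: int) -> tuple[int, int]:
    """Resolve overlapping HSPs on one genome axis.

    HSPs are taken in (score desc, q_start, s_start) order; each is trimmed to
    the positions not yet covered by higher-scoring HSPs, and its identity
    count is apportioned proportionally to the retained fraction of its
    footprint (rounded half-up).  Returns (covered_positions,
    identical_positions).
    """
    if axis not in ("query", "subject"):
        raise ValueError("axis must be 'query' or 'subject'")
    covered = np.zeros(seq_length, dtype=bool)
    identical = 0
    ordered = sorted(hsps, key=lambda h: (-h.score, h.q_start, min(h.s_start, h.s_end)))
    for h in ordered:
        if axis == "query":
            a, b = h.q_start, h.q_end
        else:
            a, b = sorted((h.s_start, h.s_end))
        if a < 1 or b > seq_length:
            raise ValueError(
                f"HSP {axis} coordinates {a}..{b} outside [1, {seq_length}]"
            )
        span = b - a + 1
        window = covered[a - 1 : b]
        new = span - int(window.sum())
        if new == 0:
            continue
        identical += _round_half_up(h.identities * new / span)
        window[:] = True
    return int(covered.sum()), identical


def write_hsps_tsv(hsps: Sequence[HSP], qid: str, sid: str, path) -> None:
    """BLAST outfmt-6-like tabular HSP dump."""
    with open(path, "w") as fh:
        fh.write("qid\tsid\tqstart\tqend\tsstart\tsend\tstrand\tlength\tidentities\tscore\n")
        for h in hsps:
            fh.write(
                f"{qid}\t{sid}\t{h.q_start}\t{h.q_end}\t{h.s_start}\t{h.s_end}\t"
                f"{h.strand}\t{h.length}\t{h.identities}\t{h.score}\n"
            )
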