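"""Sequence records and file formats shared by every pipeline stage.

Conventions used throughout the package:

* coordinates are 1-based inclusive (GFF3 convention) everywhere in the API;
* nucleotide sequences are uppercase over ``{A, C, G, T, N}``; ``U`` is mapped
  to ``T`` on input;
* ``N`` counts as a mismatch in alignments and is excluded from both the
  numerator and denominator of GC content;
* FASTA output wraps at 70 columns and ids are truncated at the first
  whitespace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

NT_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ``ACGTN`` string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction; ``N`` bases are excluded from numerator and denominator."""
    n = seq.count("N")
    denom = len(seq) - n
    if denom == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / denom


@dataclass
class CdsFeature:
    """A protein-coding feature on a genome (1-based inclusive coordinates)."""

    genome_id: str
    start: int
    end: int
    strand: str
    label: str
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid CDS coordinates {self.start}..{self.end} for {self.label!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def extract(self, genome_seq: str) -> str:
        """Coding-strand nucleotide sequence of the feature."""
        sub = genome_seq[self.start - 1 : self.end]
        return sub if self.strand == "+" else revcomp(sub)


@dataclass
class GenomeRecord:
    """A (phage) genome assembly with derived length/GC and optional features."""

    id: str
    seq: str
    features: Optional[list[CdsFeature]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        bad = set(self.seq) - NT_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_content(self.seq)


@dataclass
class ReadRecord:
    """A sequencing read with optional Phred quality scores."""

    id: str
    seq: str
    quals: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quals)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _clean_nt(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise FormatError(
            f"record {record_id!r} contains illegal characters: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path, alphabet: str = "nt") -> list[GenomeRecord]:
    """Read a nucleotide FASTA file into :class:`GenomeRecord` objects.

    ``alphabet='aa'`` returns records without nucleotide validation (used for
    proteome FASTA input); the records then carry the raw uppercase sequence.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id  # Biopython already truncates at first whitespace
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        if alphabet == "nt":
            seq = _clean_nt(str(rec.seq), rid)
            records.append(GenomeRecord(id=rid, seq=seq))
        else:
            g = GenomeRecord.__new__(GenomeRecord)
            g.id = rid
            g.seq = str(rec.seq).upper()
            g.features = None
            records.append(g)
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid = rec.id.split()[0]
            fh.write(f">{rid}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a Phred+33 FASTQ file."""
    path = Path(path)
    reads: list[ReadRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            seq = _clean_nt(str(rec.seq), rec.id)
            reads.append(
                ReadRecord(id=rec.id, seq=seq, quals=list(rec.letter_annotations["phred_quality"]))
            )
    except ValueError as exc:  # Biopython raises ValueError on truncated/mismatched records
        raise FormatError(f"malformed FASTQ record #{len(reads) + 1} in {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.quals if r.quals is not None else [30] * len(r.seq)
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# GFF3 (CDS rows only — full GFF feature hierarchies are out of scope)

_GFF_COLS = 9


def read_gff3(path: str | Path, genome_lengths: Optional[dict[str, int]] = None) -> list[CdsFeature]:
    """Read CDS features from a GFF3 file.

    If ``genome_lengths`` is given, coordinates are checked against genome
    bounds.
    """
    path = Path(path)
    feats: list[CdsFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end < start ({start_i}..{end_i})")
            if genome_lengths is not None:
                glen = genome_lengths.get(seqid)
                if glen is not None and end_i > glen:
                    raise FormatError(
                        f"{path}:{lineno}: CDS end {end_i} beyond genome length {glen}"
                    )
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            label = attr_map.get("ID") or attr_map.get("Name") or f"cds_{lineno}"
            feats.append(
                CdsFeature(
                    genome_id=seqid,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    label=label,
                    product=attr_map.get("product"),
                )
            )
    return feats


def write_gff3(features: Sequence[CdsFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.label}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                "\t".join(
                    [f.genome_id, "phagetax", "CDS", str(f.start), str(f.end), ".", f.strand, "0", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Trees and matrices


def write_newick(tree, path: str | Path) -> None:
    """Serialize a scikit-bio ``TreeNode``; bootstrap supports become internal
    node labels. Every leaf must be named."""
    for tip in tree.tips():
        if not tip.name:
            raise ValueError("tree has an unlabeled leaf")
    tree.write(str(path), format="newick")


def write_matrix_tsv(ids: Sequence[str], values, path: str | Path, symmetric: bool = True, decimals: int = 1) -> None:
    """Write a labelled square matrix as TSV with identical row/column order."""
    import numpy as np

    values = np.asarray(values, dtype=float)
    n = len(ids)
    if values.shape != (n, n):
        raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
    if symmetric and not np.allclose(values, values.T, atol=1e-6):
        raise ValueError("matrix declared symmetric but is not")
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(ids) + "\n")
        for i, rid in enumerate(ids):
            row = "\t".join(f"{v:.{decimals}f}" for v in values[i])
            fh.write(f"{rid}\t{row}\n")


def read_matrix_tsv(path: str | Path):
    """Read a matrix written by :func:`write_matrix_tsv`; returns (ids, array)."""
    import numpy as np

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(x) for x in parts[1:]])
    return header, np.array(rows)
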