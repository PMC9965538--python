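"""Standard genetic code tables and codon-usage bookkeeping.

The synonymous *share* of a codon — its frequency among all codons encoding
the same amino acid — is the unit in which phage-vs-host codon bias is
expressed (e.g., an AGA share of 0.202 among the arginine codons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable as _CT

_std = _CT.unambiguous_dna_by_id[1]

CODON_TO_AA: dict[str, str] = dict(_std.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_std.stop_codons)

AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))


@dataclass
class CodonUsageTable:
    """Codon counts with per-amino-acid-family synonymous shares.

    Stop codons are excluded from families (and from :meth:`shares`).
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS) - STOP_CODONS
        if bad:
            raise ValueError(f"unknown codons: {sorted(bad)}")

    @property
    def total(self) -> int:
        return sum(v for c, v in self.counts.items() if c in CODON_TO_AA)

    def aa_count(self, aa: str) -> int:
        return sum(self.counts.get(c, 0) for c in AA_TO_CODONS[aa])

    def shares(self, pseudocount: float = 0.0) -> dict[str, float]:
        """Synonymous share per codon; families with zero total get uniform
        shares when a pseudocount is supplied, else zeros."""
        out: dict[str, float] = {}
        for aa, codons in AA_TO_CODONS.items():
            tot = sum(self.counts.get(c, 0) + pseudocount for c in codons)
            for c in codons:
                out[c] = (self.counts.get(c, 0) + pseudocount) / tot if tot > 0 else 0.0
        return out

    def aa_frequencies(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {aa: 0.0 for aa in AA_TO_CODONS}
        return {aa: self.aa_count(aa) / tot for aa in AA_TO_CODONS}


def translate(cds_seq: str) -> str:
    """Translate an in-frame CDS (terminal stop, if present, is dropped)."""
    if len(cds_seq) % 3:
        raise ValueError("CDS length not divisible by 3")
    aas = []
    for i in range(0, len(cds_seq), 3):
        codon = cds_seq[i : i + 3]
        if codon in STOP_CODONS:
            if i != len(cds_seq) - 3:
                raise ValueError(f"internal stop codon at nt {i + 1}")
            break
        aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)
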