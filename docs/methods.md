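# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `phagetax`, in the spirit of a methods supplement.

## Local alignment engine

Genome pairs are compared by seed-and-extend: exact 11-mer word matches on
both strands seed ungapped extensions along each matching diagonal, scored
+1/−2 (match/mismatch) with x-drop 20 termination; a one-pass maximal-segment
scan per diagonal makes this O(diagonal length) in vectorized/numba code.
Co-linear segments separated by small gaps (≤60 nt on either sequence,
diagonal shift ≤30) are then chained greedily with affine gap costs (open 5,
extend 2 per diagonal-shift base), which plays the role of a banded gapped
extension: short indels no longer fragment an alignment into pieces below the
reporting threshold (HSP score ≥30). Word size 11 gives megablast-like
sensitivity in the ≥70% identity regime that the genus threshold lives in;
pairs below roughly 60% identity produce essentially no seeds, which is the
desired behaviour for an intergenomic-similarity statistic (unalignable
genome pairs score ~0, not some alignment-forced residual). Chained HSPs
report `length` as the number of aligned (segment) columns; their footprint
on a genome spans the gap interiors, so coverage is an upper bound within one
chain gap (≤60 nt) per indel cluster. Tie-breaking everywhere is
(score desc, q_start, s_start), so output is deterministic.

`N` never matches anything; `X` scores 0 against every residue. Protein
pairs use an optimal local alignment under BLOSUM62 with affine gaps 11/1
(Biopython's `PairwiseAligner` is the workhorse); identity is identical
columns over alignment columns (including internal gaps), coverage is the
aligned span over each protein's full length, and "similarity" is the
fraction of aligned columns with a positive substitution score. The test
suite checks the engine's scores against an independent quadratic-space
Smith–Waterman oracle.

### Merging overlapping HSPs

Per genome axis, HSPs are taken best-first and trimmed to positions not yet
covered; the identity count of a trimmed HSP is apportioned proportionally to
the retained fraction of its footprint, rounded half-up. The error of this
apportionment relative to re-aligning the trimmed window is at most a few
positions per trimmed HSP, and it is deterministic and cheap.

## Intergenomic similarity and taxa

The similarity of genomes A and B is `100·(id_A + id_B)/(L_A + L_B)`, where
`id_X` is the merged identical-position count projected on genome X — an
identity-over-total-length statistic, so it jointly penalizes divergence and
incomplete coverage. Matrix entries are kept at full precision internally
and rounded to one decimal only in TSV output. Species (≥95%) and genus
(≥70%) partitions are connected components of the thresholded similarity
graph (single linkage); species edges are also counted as genus edges so the
species partition refines the genus partition for *any* matrix, not just
metric ones. Whether a complete-linkage rule would serve better near the
threshold is deliberately left open; single linkage matches the reading of
"≥ threshold ⇒ same taxon" as an edge rule and is order-independent.

## Protein-sharing network

All proteins are clustered into protein clusters (PCs) by Markov clustering
(inflation 2.0) of a graph with edges at ≥35% identity and ≥50% coverage of
the shorter protein. A genome pair sharing `k` PCs out of `n_A`, `n_B`
(universe = total PC count) gets edge weight `−log10 P(X ≥ k)` under the
hypergeometric distribution, computed via the log survival function for
stability and capped at 300. Viral clusters come from Markov clustering of
the weighted genome network at inflation 2.0; a second pass at inflation 4.0
within each VC yields sub-VCs, which therefore always refine VCs. The
Markov process is fully deterministic: self-loops equal to the maximum
incident weight, column normalization, expansion/inflation iterated to a
1e-6 fixed point or 100 iterations. Note that the hypergeometric weight is
only informative when the universe is substantially larger than the
proteomes being compared; in a two-genome universe the tail probability is 1
by construction and the network is empty.

## GBDP distances, trees, and fraction-of-links clustering

With `H_X` covered and `I_X` identical positions per genome and `L_X`
lengths: `d0 = 1 − (H_A+H_B)/(L_A+L_B)` (default, coverage-driven),
`d4 = 1 − (I_A+I_B)/(H_A+H_B)`, `d6 = 1 − (I_A+I_B)/(L_A+L_B)`; genome pairs
with no HSPs take distance 1 in every formula. The algebraic identity
`(1−d6) = (1−d4)(1−d0)` is asserted to 1e-12 in the tests. Trees are built
by neighbor joining (scikit-bio, negative branch lengths clamped to zero)
rather than minimum-evolution with SPR: NJ is deterministic, recovers the
same topology on additive matrices, and the exact published tree topology is
not something this package tries to reproduce. Pseudo-bootstrap supports
resample each pair's HSP set with replacement (same count), recompute the
distance matrix and a replicate tree, and report the percentage of
replicates containing each internal bipartition of the point-estimate tree.
The resampling unit (HSPs per pair) is the natural GBDP convention; with one
replicate, supports are trivially 0 or 100.

OPTSIL-style clustering merges, at each step, the cluster pair maximizing
the fraction of inter-cluster distances at or below the threshold, provided
that fraction is ≥F; ties break on smaller maximum inter-cluster distance,
then smaller mean, then lexicographically. The max-distance tie-break makes
the F=1 limit coincide exactly with complete-linkage clustering cut at the
threshold, and the F→0 limit is single-linkage components; both limits are
verified against independent oracles. Distance thresholds for
species/genus/family ranks are not baked in — they are explicit parameters
(the pipeline default is 0.5 for d0, which separates near-total-coverage
within-genus pairs from no-coverage between-genus pairs).

## Termini and the frameshift model

**Adapter screening.** Only the first/last 150 nt of a read are scanned for
the ligation Y-adapter top/bottom sequences (and reverse complements) at
≥75% identity; a terminal match truncates through it. The suffix scan
starts after the prefix cut so the operation is idempotent and a single
terminal adapter is never double-counted on short reads.

**DTR from reads.** Reads are adapter-trimmed and filtered to ≥99% of the
assembly length (a filter slightly below the genome size keeps
genome-spanning reads whose iid errors leave a small net deletion excess —
mirroring read-length filters set a few hundred bp under the assembly size).
Each qualifying read is oriented by shared 15-mers, the assembly's first
50 bp are located near the read end (≥90% identity), and the read's terminal
copy is aligned semi-globally onto the assembly prefix; the alignment's end
position *is* that read's repeat length. Measuring the end against the
error-free assembly rather than read-vs-read makes the estimate robust to
read indels (read-internal estimates jitter by ±1–2 bp per indel). The
reported DTR length is the mode over supporting reads (≥2 required — a
single read is not evidence), and the consensus sequence is a per-column
majority vote. On error-free reads the recovery is exact for any planted
repeat length in [50, 1000].

**DTR from an assembly.** Among prefix/suffix overlap lengths L in
[25, 1000], the detector maximizes `L − 20·edits(L)` subject to ≥95%
identity, where `edits(L)` is the global edit distance between the first and
last L bases. Maximizing matches-minus-penalized-edits rather than taking
the first L passing the identity floor matters: lengths a few bp beyond the
true repeat still pass a 95% floor (2 extra edits in ~195 columns), but
they lose the penalized score, so the argmax lands on the exact boundary.

**Slippery sites and the −1 frameshift.** A slippery site is a heptamer
matching N1N1N1N2N2N2N3 (e.g. GGGAAAG) lying fully inside a CDS with its
start within 30 nt + 6 of the stop's last base. The minimal pattern is used
deliberately — additional constraints (purine content, codon context) are
plausible but not required to explain the observed sites. The isoform
model: the ribosome translates 0-frame codons through the codon ending at
the heptamer's last base (which must coincide with a codon boundary — a
precondition, not a scan filter), then resumes one nucleotide back,
re-reading that base in the −1 frame until the next stop. Hence the
extended span plus one re-read nucleotide is always divisible by 3, and
`extended_aa = (extended_end − cds_start + 2)/3 − 1`. Extensions of ≤20
residues are flagged `premature_stop`: they are indistinguishable from the
natural product on a gel, which is the biologically meaningful readout.

## Codon usage and bias

Codon usage is reported as synonymous shares — each codon's frequency within
its amino-acid family (stop codons excluded) — because tRNA complementation
arguments are about choices *within* a family, not global codon frequency.
Bias entries are share ratios phage/host; when either raw count is zero the
family's shares are recomputed with a 0.5 pseudocount and the entry is
flagged unstable. Entries at ≥2-fold (either direction) are reported,
sorted by |log2 fold|. All six arginine codons (and every other family
member) are always reported, including zero-count codons.

## Pangenome

Ortholog groups are Markov clusters (inflation 1.5) of the protein graph at
≥30% identity and ≥50% coverage of the shorter sequence — all-vs-all, with a
shared-5-mer prefilter; at ≤40 genomes × ~125 proteins this is tractable
without CD-HIT-style pre-clustering, and the core size is governed mainly by
the identity threshold. The coverage requirement (not part of the classical
recipe) prevents single-domain matches from chaining unrelated multidomain
proteins. Paralogs are allowed within a group but flagged. The core is the
set of groups with ≥1 member in every genome; accessory % per genome is
`100·(1 − core members/proteome size)`. Marker ranking uses mean pairwise
identity over members from distinct genomes, with the BLOSUM62
positive-score column fraction reported as "similarity".

## Synthetic data

The generator emulates what the analyses assume, with defaults set to the
study conditions: 78 kb genomes at GC 0.421, a 193 bp DTR (the genome is a
unit plus a repeated copy of its first 193 bp), 120 non-overlapping
forward-strand genes in late/middle/early blocks, one capsid-like gene
carrying a GGGAAAG cassette whose −1 frame stays open for ≥200 extra codons,
and an in-frame TAA planted directly upstream of every start codon so the
deterministic ORF caller can recover gene boundaries exactly. Accidental
pattern heptamers in the scan window near every other gene's stop are
scrubbed, so exactly one CDS carries a slippery site. Gene codons are drawn
from a codon profile by largest-remainder quota plus a seeded shuffle — the
profile is planted exactly up to rounding, so codon-usage recovery tests
measure the analysis, not multinomial noise. Without a profile, codons
follow the iid base distribution at the target GC (realized GC is within
±0.01 for genomes ≥20 kb; excluding stop codons shifts GC up by ~0.002,
well inside that band).

Cluster sets evolve a synthesized root: cluster ancestors at the
inter-cluster divergence (default 0.45 substitutions/site) from the root,
members at the intra-cluster divergence (default 0.10) from their ancestor,
so within-cluster pairs sit at ~73–75% intergenomic similarity (above the
70% genus threshold) and between-cluster pairs share no alignable signal —
the planted partition straddles the demarcation exactly as intended.
Substitutions are iid at the stated rate; indel events are 5% of mutation
events with geometric lengths (mean 3 bp). Divergence above 0.6 is refused
because the seed-and-extend engine has no signal there.

Reads are windows of the packaged linear molecule. Full-length reads
traverse the whole molecule, so they carry the DTR at both ends — the
physical situation for a T7-like packaging strategy, where every virion
contains the same linear genome. A `circular_permutation` flag instead
draws rotated windows from a two-unit concatemer (headful-style packaging),
which is the DTR-free negative control. Errors are iid per base
(substitution 0.005, insertion 0.002, deletion 0.002 by default); ~50% of
reads are reverse-complemented; Y-adapters flank each read. The error
model deliberately omits homopolymer-conditioned errors, quality-score
structure, and chimeras — it stresses the consensus logic of the termini
detector, not a basecaller. Passing tests on these data show the analyses
recover planted truth under iid noise and clean cluster separation; they do
not certify behaviour on real nanopore error profiles, recombinant genomes,
or taxa that sit *on* the 70% threshold.

## Problem sizes and determinism

Tests run the cluster-recovery analysis at 40 kb × 12 genomes × 20 seeds and
termini recovery at 78 kb × 20 reads × 10 seeds; these sizes give the
statistics room to concentrate while keeping the full suite in a few
minutes on one core. Every stochastic component is a pure function of an
explicit integer seed; Markov clustering, NJ, merging and chaining are
deterministic with pinned tie-breaks, and rerunning the pipeline with the
same seed reproduces its outputs byte-for-byte (newick up to rotation).

## Known limitations

- The ORF caller is rule-based (first in-frame start after the previous
  stop, ATG/GTG/TTG); it has no coding-potential model, so CDS counts on
  real genomes are approximate and real annotations can be supplied via
  GFF3 instead.
- The similarity statistic's dialect (identity over total length, merged
  greedily) is pinned here for reproducibility; other tools' aggregation
  details differ in near-threshold cases.
- VC/sub-VC and similarity-threshold genera need not agree — both are
  reported, neither is arbitrated.
- E-values, translated searches, and multiple alignment are out of scope;
  the network weight is a significance transform, not an E-value.
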