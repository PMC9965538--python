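import numpy as np
import pytest

from phagetax.codons import CodonUsageTable
from phagetax.features import (
    codon_bias,
    codon_usage,
    detect_dtr_in_assembly,
    detect_termini_from_reads,
    find_dtr_by_similarity,
    find_orfs,
    find_slippery_sites,
    predict_extended_isoform,
    trim_adapters,
)
from phagetax.seqio import CdsFeature, GenomeRecord, ReadRecord, revcomp
from phagetax.simulate import (
    ADAPTER_BOTTOM,
    ADAPTER_TOP,
    GenomeSpec,
    ReadSimParams,
    simulate_reads,
    synthesize_frameshift_construct,
    synthesize_phage_genome,
)

from tests.conftest import random_dna


class TestTrimAdapters:
    def test_exact_prefix_removed(self):
        r = ReadRecord(id="r", seq=ADAPTER_TOP + "G")
        assert trim_adapters(r).seq == "G"

    def test_two_substitutions_still_trimmed(self):
        ad = list(ADAPTER_TOP)
        ad[5] = "A" if ad[5] != "A" else "C"
        ad[30] = "G" if ad[30] != "G" else "T"
        r = ReadRecord(id="r", seq="".join(ad) + "C" * 400)
        assert trim_adapters(r).seq == "C" * 400

    def test_interior_adapter_untouched(self):
        r = ReadRecord(id="r", seq="A" * 200 + ADAPTER_TOP + "A" * 200)
        assert trim_adapters(r).seq == r.seq

    def test_idempotent(self, rng):
        r = ReadRecord(id="r", seq=ADAPTER_TOP + random_dna(rng, 1000) + revcomp(ADAPTER_BOTTOM))
        once = trim_adapters(r)
        assert trim_adapters(once).seq == once.seq

    def test_quals_follow_sequence(self):
        r = ReadRecord(id="r", seq=ADAPTER_TOP + "GGGG", quals=[20] * (len(ADAPTER_TOP) + 4))
        t = trim_adapters(r)
        assert len(t.quals) == len(t.seq) == 4


class TestTerminiFromReads:
    @pytest.mark.parametrize("dtr_len", [50, 193, 400])
    def test_error_free_reads_exact(self, dtr_len):
        g, _, _ = synthesize_phage_genome(GenomeSpec(length=30000, n_genes=30, dtr_len=dtr_len, seed=2))
        reads = simulate_reads(
            g, ReadSimParams(n_reads=6, sub_rate=0, ins_rate=0, del_rate=0,
                             frac_full_length=1.0, add_adapters=False, seed=1),
        )
        rep = detect_termini_from_reads(reads, g)
        assert rep.dtr_length == dtr_len
        assert rep.dtr_sequence == g.seq[:dtr_len]
        assert rep.n_supporting_reads == len(rep.per_read_lengths) == 6

    def test_noisy_reads_with_adapters(self, default_genome):
        g, _, _ = default_genome
        reads = simulate_reads(g, ReadSimParams(n_reads=20, seed=4))
        rep = detect_termini_from_reads(reads, g)
        assert rep.dtr_length == 193

    def test_circularly_permuted_control_zero(self, small_genome):
        g, _, _ = small_genome
        perm = GenomeRecord(id="perm", seq=g.seq[193:])  # strip the repeat copy
        reads = simulate_reads(
            perm, ReadSimParams(n_reads=20, seed=5, circular_permutation=True)
        )
        rep = detect_termini_from_reads(reads, perm)
        assert rep.dtr_length == 0

    def test_no_qualifying_reads_warns(self, small_genome):
        g, _, _ = small_genome
        short = [ReadRecord(id="r", seq=g.seq[:1000])]
        rep = detect_termini_from_reads(short, g)
        assert rep.dtr_length == 0 and rep.warning is not None


class TestDtrInAssembly:
    def test_planted_exact(self, small_genome):
        g, _, _ = small_genome
        assert detect_dtr_in_assembly(g).dtr_length == 193

    def test_random_sequence_below_25(self, rng):
        g = GenomeRecord(id="r", seq=random_dna(rng, 40000))
        assert detect_dtr_in_assembly(g).dtr_length < 25

    def test_five_substitutions_still_detected(self, rng):
        g, _, _ = synthesize_phage_genome(GenomeSpec(length=20000, n_genes=20, seed=6))
        seq = list(g.seq)
        for p in rng.choice(193, size=5, replace=False):
            seq[p] = "ACGT".replace(seq[p], "")[rng.integers(0, 3)]
        mutated = GenomeRecord(id="m", seq="".join(seq))
        assert detect_dtr_in_assembly(mutated).dtr_length == 193


class TestDtrBySimilarity:
    def test_own_terminus_two_perfect_hits(self, small_genome):
        g, _, _ = small_genome
        hits = find_dtr_by_similarity(g.seq[:193], g)
        assert len(hits) == 2
        assert all(ident == 1.0 for _, _, ident in hits)
        starts = sorted(h[0] for h in hits)
        assert starts[0] == 1 and starts[1] == g.length - 193 + 1

    def test_unrelated_query_empty(self, rng, small_genome):
        g, _, _ = small_genome
        assert find_dtr_by_similarity(random_dna(rng, 200), g) == []

    def test_diverged_terminus_found_at_reduced_identity(self, rng, small_genome):
        g, _, _ = small_genome
        q = list(g.seq[:193])
        for p in rng.choice(193, size=19, replace=False):
            q[p] = "ACGT".replace(q[p], "")[rng.integers(0, 3)]
        hits = find_dtr_by_similarity("".join(q), g)
        assert hits and all(0.82 <= ident <= 0.96 for _, _, ident in hits)

    def test_query_length_validated(self, small_genome):
        g, _, _ = small_genome
        with pytest.raises(ValueError):
            find_dtr_by_similarity("ACGT", g)


class TestFindOrfs:
    def test_constructed_orf(self, rng):
        insert = "ATG" + "AAA" * 30 + "TAA"
        seq = random_dna(rng, 500) + "TAG" + insert + random_dna(rng, 500)
        g = GenomeRecord(id="g", seq=seq)
        start = seq.index(insert) + 1
        found = [(f.start, f.end, f.strand) for f in find_orfs(g)]
        assert (start, start + len(insert) - 1, "+") in found

    def test_empty_genome(self):
        assert find_orfs(GenomeRecord(id="g", seq="")) == []

    def test_planted_gene_recovery(self, default_genome):
        g, feats, _ = default_genome
        called = {(f.start, f.end) for f in find_orfs(g) if f.strand == "+"}
        planted = {(f.start, f.end) for f in feats}
        assert len(planted & called) >= 0.95 * len(planted)


class TestSlipperySites:
    def _cds_with_tail(self, tail):
        # gene: ATG + filler codons + tail (which must end with an in-frame TAA)
        gene = "ATG" + "GCA" * 20 + tail
        seq = "CC" + gene + "GG"
        g = GenomeRecord(id="g", seq=seq)
        cds = CdsFeature("g", 3, 2 + len(gene), "+", "cds1")
        return g, cds

    def test_gggaaag_found(self):
        g, cds = self._cds_with_tail("CTGGGAAAGGCAGCAGCA" + "TAA")
        sites = find_slippery_sites(g, cds)
        assert [s.heptamer for s in sites] == ["GGGAAAG"]

    def test_near_miss_pattern_rejected(self):
        g, cds = self._cds_with_tail("CTGAGAAAGGCAGCAGCA" + "TAA")
        assert find_slippery_sites(g, cds) == []

    def test_cccttta_pattern_accepted(self):
        g, cds = self._cds_with_tail("CTCCCTTTAGCAGCAGCA" + "TAA")
        assert [s.heptamer for s in find_slippery_sites(g, cds)] == ["CCCTTTA"]

    def test_heptamer_outside_window_ignored(self):
        g, cds = self._cds_with_tail("GGGAAAG" + "GCA" * 12 + "TAA")
        assert find_slippery_sites(g, cds) == []

    def test_pattern_validation(self):
        from phagetax.features import SlipperySite

        with pytest.raises(ValueError):
            SlipperySite(position=1, heptamer="GAGAAAG", cds_label="x", offset_to_stop=10)


class TestPredictExtendedIsoform:
    def test_printed_mcp_coordinates(self):
        # CDS 7253-8314 with heptamer 8293-8299 and -1 stop ending 9930
        g, cds = synthesize_frameshift_construct(seed=1)
        (site,) = find_slippery_sites(g, cds)
        rep = predict_extended_isoform(g, cds, site)
        assert rep.natural_length_aa == 353
        assert rep.extended_length_aa == 892
        assert rep.extended_end == 9930
        assert not rep.premature_stop
        # one re-read nucleotide makes the extended span divisible by 3
        assert (rep.extended_end - cds.start + 2) % 3 == 0

    def test_early_minus1_stop_is_premature(self):
        # a -1-frame TAG beginning 39 nt downstream of the heptamer truncates
        # the extension to a near-invisible ~13 extra residues
        # -1 stop begins 39 nt downstream of the heptamer end: 8338..8340
        g, cds = synthesize_frameshift_construct(
            cds_start=7253, cds_end=8314, heptamer_start=8293,
            minus1_stop_end=8340, seed=2,
        )
        (site,) = find_slippery_sites(g, cds)
        rep = predict_extended_isoform(g, cds, site)
        assert rep.premature_stop
        assert rep.extended_length_aa - rep.natural_length_aa <= 20

    def test_misaligned_heptamer_rejected(self):
        g, cds = synthesize_frameshift_construct(seed=3)
        from phagetax.features import SlipperySite

        bad = SlipperySite(position=8292, heptamer="GGGAAAG", cds_label="mcp",
                           offset_to_stop=22)
        with pytest.raises(ValueError, match="codon boundary"):
            predict_extended_isoform(g, cds, bad)

    def test_runaway_frame_rejected(self):
        # genome ends before any -1-frame stop
        gene = "ATG" + "GCA" * 40 + "CTG" + "GGAAAG" + "GCAGCAGCAGCA" + "TAA"
        seq = gene + "GCA" * 5  # -1 frame over GCA repeats never hits a stop
        g = GenomeRecord(id="g", seq=seq)
        cds = CdsFeature("g", 1, len(gene), "+", "x")
        (site,) = find_slippery_sites(g, cds)
        with pytest.raises(ValueError, match="runaway"):
            predict_extended_isoform(g, cds, site)


class TestCodonUsage:
    def test_single_family_share(self):
        t = codon_usage(["ATGAGAAGATAA"])
        assert t.shares()["AGA"] == 1.0
        assert t.counts["AGA"] == 2

    def test_equal_split_shares(self):
        t = codon_usage(["AGACGT" * 5])
        s = t.shares()
        assert s["AGA"] == pytest.approx(0.5)
        assert s["CGT"] == pytest.approx(0.5)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="CDS #1"):
            codon_usage(["ATGTAAAGA"])

    def test_frame_validated(self):
        with pytest.raises(ValueError):
            codon_usage(["ATGA"])

    def test_order_and_duplication_invariance(self, default_genome):
        g, feats, _ = default_genome
        seqs = [f.extract(g.seq) for f in feats[:20]]
        a = codon_usage(seqs).shares()
        b = codon_usage(seqs[::-1]).shares()
        c = codon_usage(seqs + seqs).shares()
        assert a == b == c


class TestCodonBias:
    def _tables(self):
        phage = CodonUsageTable(counts={"AGA": 202, "CGT": 798})
        host = CodonUsageTable(counts={"AGA": 36, "CGT": 964})
        return phage, host

    def test_printed_aga_fold_change(self):
        phage, host = self._tables()
        (entry,) = [e for e in codon_bias(phage, host) if e.codon == "AGA"]
        assert round(entry.fold_change, 1) == 5.6
        assert entry.direction == "up"

    def test_identical_tables_empty(self):
        phage, _ = self._tables()
        assert codon_bias(phage, phage) == []

    def test_zero_count_handled_with_pseudocount(self):
        phage = CodonUsageTable(counts={"AGA": 10})
        host = CodonUsageTable(counts={"CGT": 10})
        entries = codon_bias(phage, host)
        aga = [e for e in entries if e.codon == "AGA"]
        assert aga and np.isfinite(aga[0].fold_change) and aga[0].unstable

    def test_sorted_by_abs_log_fold(self):
        phage = CodonUsageTable(counts={"AGA": 202, "CGT": 700, "CGC": 98,
                                        "GCA": 900, "GCC": 100})
        host = CodonUsageTable(counts={"AGA": 36, "CGT": 800, "CGC": 164,
                                       "GCA": 500, "GCC": 500})
        entries = codon_bias(phage, host)
        folds = [abs(np.log2(e.fold_change)) for e in entries]
        assert folds == sorted(folds, reverse=True)
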