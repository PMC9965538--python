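import io

import numpy as np
import pytest

from phagetax.align import HSP, find_hsps_nt
from phagetax.gbdp import (
    DistanceMatrix,
    GbdpParams,
    bootstrap_supports,
    distance_matrix_from_hsps,
    gbdp_distance,
    nj_tree,
    optsil_cluster,
    pairwise_hsps,
)
from phagetax.seqio import GenomeRecord
from phagetax.simulate import ClusterSpec, GenomeSpec, simulate_clustered_genomes

from tests.conftest import random_dna
from tests.oracles import random_additive_tree


def _full_hsp(length, identities):
    return HSP(q_start=1, q_end=length, s_start=1, s_end=length, strand="+",
               length=length, identities=identities, score=identities)


class TestGbdpDistance:
    def test_identical_genomes_d0_zero(self, rng):
        seq = random_dna(rng, 5000)
        a, b = GenomeRecord(id="a", seq=seq), GenomeRecord(id="b", seq=seq)
        hsps = find_hsps_nt(a, b)
        assert gbdp_distance(a, b, hsps, "d0") == 0.0

    def test_no_hsps_all_distances_one(self, rng):
        a = GenomeRecord(id="a", seq=random_dna(rng, 1000))
        b = GenomeRecord(id="b", seq=random_dna(rng, 1000))
        for f in ("d0", "d4", "d6"):
            assert gbdp_distance(a, b, [], f) == 1.0

    def test_closed_form_full_coverage_90pct_identity(self, rng):
        seq = random_dna(rng, 1000)
        a, b = GenomeRecord(id="a", seq=seq), GenomeRecord(id="b", seq=seq)
        hsps = [_full_hsp(1000, 900)]
        assert gbdp_distance(a, b, hsps, "d0") == pytest.approx(0.0)
        assert gbdp_distance(a, b, hsps, "d4") == pytest.approx(0.1)
        assert gbdp_distance(a, b, hsps, "d6") == pytest.approx(0.1)

    def test_formula_identity_holds_to_1e12(self, small_genome):
        from phagetax.simulate import evolve_genome

        g, _, _ = small_genome
        for seed in range(3):
            e = evolve_genome(g, 0.12, 0.05, seed=seed)
            hsps = find_hsps_nt(g, e)
            d0 = gbdp_distance(g, e, hsps, "d0")
            d4 = gbdp_distance(g, e, hsps, "d4")
            d6 = gbdp_distance(g, e, hsps, "d6")
            assert abs((1 - d6) - (1 - d4) * (1 - d0)) < 1e-12


class TestNjTree:
    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n = int(rng.integers(4, 7))
            labels, mat, true_bips = random_additive_tree(rng, n)
            tree = nj_tree(DistanceMatrix(ids=labels, values=mat))
            from phagetax.gbdp import _bipartitions

            got = _bipartitions(tree, frozenset(labels))
            assert got == true_bips

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(ids=["a", "b"], values=np.array([[0, 0.1], [0.1, 0]])))

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        labels, mat, true_bips = random_additive_tree(rng, 6)
        perm = rng.permutation(6)
        tree2 = nj_tree(
            DistanceMatrix(ids=[labels[i] for i in perm], values=mat[np.ix_(perm, perm)])
        )
        from phagetax.gbdp import _bipartitions

        assert _bipartitions(tree2, frozenset(labels)) == true_bips


@pytest.fixture(scope="module")
def planted_clades():
    recs, labels = simulate_clustered_genomes(
        ClusterSpec(n_clusters=2, genomes_per_cluster=[3, 3],
                    intra_divergence=0.05, inter_divergence=0.4, seed=3),
        GenomeSpec(length=20000, n_genes=25, seed=3),
    )
    return recs, labels, pairwise_hsps(recs)


class TestBootstrap:
    def test_planted_clade_bipartition_strongly_supported(self, planted_clades):
        recs, labels, store = planted_clades
        tree = bootstrap_supports(recs, GbdpParams(replicates=100, seed=1), store=store)
        clade = frozenset(r.id for r in recs if labels[r.id] == 0)
        supports = {}
        all_tips = frozenset(r.id for r in recs)
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            canon = min(side, all_tips - side, key=lambda s: (len(s), tuple(sorted(s))))
            supports[canon] = float(node.name)
        assert supports[clade] >= 95

    def test_single_replicate_supports_binary(self, planted_clades):
        recs, _, store = planted_clades
        tree = bootstrap_supports(recs, GbdpParams(replicates=1, seed=5), store=store)
        for node in tree.non_tips(include_self=False):
            assert float(node.name) in (0.0, 100.0)

    def test_newick_serializable(self, planted_clades, tmp_path):
        from phagetax.seqio import write_newick
        from skbio.tree import TreeNode

        recs, _, store = planted_clades
        tree = bootstrap_supports(recs, GbdpParams(replicates=10, seed=2), store=store)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = TreeNode.read([p.read_text().strip()])
        assert {t.name for t in back.tips()} == {r.id for r in recs}

    def test_identical_genomes_zero_distances(self, rng):
        seq = random_dna(rng, 4000)
        recs = [GenomeRecord(id=f"g{i}", seq=seq) for i in range(4)]
        dm = distance_matrix_from_hsps(recs, pairwise_hsps(recs))
        np.testing.assert_allclose(dm.values, 0.0, atol=1e-12)


class TestOptsil:
    def _dm(self, vals, ids=None):
        vals = np.array(vals, dtype=float)
        ids = ids or [f"g{i}" for i in range(len(vals))]
        return DistanceMatrix(ids=ids, values=vals)

    def test_threshold_below_all_distances_singletons(self):
        dm = self._dm([[0, .5, .6], [.5, 0, .7], [.6, .7, 0]])
        assert optsil_cluster(dm, 0.1, F=1.0).n_clusters == 3

    def test_two_tight_planted_clusters(self):
        v = np.full((6, 6), 0.9)
        v[:3, :3] = 0.05
        v[3:, 3:] = 0.05
        np.fill_diagonal(v, 0)
        p = optsil_cluster(self._dm(v), 0.2, F=0.5)
        assert p.n_clusters == 2
        assert len(set(p.assignment[f"g{i}"] for i in range(3))) == 1

    def test_tiny_f_chains_everything(self):
        v = np.array([[0, .1, .9], [.1, 0, .1], [.9, .1, 0]], float)
        assert optsil_cluster(self._dm(v), 0.2, F=1e-9).n_clusters == 1

    def test_f_one_limit_is_complete_linkage(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            v = rng.uniform(0, 1, (n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            t = float(rng.uniform(0.2, 0.8))
            got = optsil_cluster(self._dm(v), t, F=1.0)
            want = fcluster(linkage(squareform(v), "complete"), t, criterion="distance")
            got_sets = {frozenset(c) for c in got.clusters()}
            want_sets = {}
            for i, c in enumerate(want):
                want_sets.setdefault(c, set()).add(f"g{i}")
            assert got_sets == {frozenset(s) for s in want_sets.values()}

    def test_f_zero_limit_is_single_linkage(self):
        import networkx as nx

        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            v = rng.uniform(0, 1, (n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            t = float(rng.uniform(0.2, 0.8))
            got = optsil_cluster(self._dm(v), t, F=1e-9)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(
                (i, j) for i in range(n) for j in range(i + 1, n) if v[i, j] <= t
            )
            want = {frozenset(f"g{i}" for i in comp) for comp in nx.connected_components(g)}
            assert {frozenset(c) for c in got.clusters()} == want
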