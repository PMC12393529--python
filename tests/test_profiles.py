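"""RPKM, Bray-Curtis, UPGMA, and host-profile concordance."""

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from symbiopan.cophylogeny import patristic_distances
from symbiopan.io_formats import ReadCountTable, SquareMatrix, tree_from_string
from symbiopan.profiles import (
    RpkmProfile,
    bray_curtis,
    compute_rpkm,
    mean_rpkm_by_group,
    profile_concordance,
    upgma,
)
from symbiopan.synthetic import block_association, simulate_read_counts, yule_tree


def make_counts(counts, lengths, libs):
    counts = np.asarray(counts)
    return ReadCountTable(
        samples=[f"s{i}" for i in range(counts.shape[0])],
        genomes=[f"g{j}" for j in range(counts.shape[1])],
        counts=counts,
        genome_length_bp=np.asarray(lengths),
        library_size=np.asarray(libs),
    )


class TestRpkm:
    def test_unit_example(self):
        # 1,000 reads on a 1 Mbp genome in a 1 M-read library -> RPKM 1.0
        t = make_counts([[1000]], [1_000_000], [1_000_000])
        assert compute_rpkm(t, 0.0).values[0, 0] == pytest.approx(1.0)

    def test_threshold_zeroes_small_values(self):
        t = make_counts([[50]], [1_000_000], [1_000_000])  # RPKM 0.05
        assert compute_rpkm(t, 0.1).values[0, 0] == 0.0
        assert compute_rpkm(t, 0.01).values[0, 0] == pytest.approx(0.05)

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(5, 7))
        lengths = rng.integers(3_000_000, 6_000_000, size=7)
        libs = counts.sum(axis=1) * 10 + 1
        t = make_counts(counts, lengths, libs)
        prof = compute_rpkm(t, 0.0)
        for i in range(5):
            for j in range(7):
                expected = counts[i, j] / ((lengths[j] / 1e3) * (libs[i] / 1e6))
                assert prof.values[i, j] == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_joint_count_library_scaling(self):
        t1 = make_counts([[100, 10], [5, 200]], [4_000_000, 5_000_000], [2000, 3000])
        t2 = make_counts([[300, 30], [15, 600]], [4_000_000, 5_000_000], [6000, 9000])
        a = compute_rpkm(t1, 0.0).values
        b = compute_rpkm(t2, 0.0).values
        assert np.allclose(a, b)


class TestBrayCurtis:
    def test_identical_and_disjoint_samples(self):
        prof = RpkmProfile(
            ["a", "b", "c"], ["g1", "g2"],
            np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]]), 0.1,
        )
        d = bray_curtis(prof)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0  # disjoint supports

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 5, size=(6, 9))
        prof = RpkmProfile(
            [f"s{i}" for i in range(6)], [f"g{j}" for j in range(9)], values, 0.0
        )
        d = bray_curtis(prof)
        for i in range(6):
            for j in range(6):
                num = sum(abs(values[i, k] - values[j, k]) for k in range(9))
                den = sum(values[i, k] + values[j, k] for k in range(9))
                assert d.values[i, j] == pytest.approx(num / den if den else 0.0)
        assert (d.values >= 0).all() and (d.values <= 1).all()


class TestUpgma:
    def test_two_items_make_a_half_height_cherry(self):
        d = SquareMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]), "distance")
        tree = upgma(d)
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(1.0)

    def test_recovers_generating_ultrametric_tree(self):
        # 4-point ultrametric: ((a,b):~, (c,d):~) with heights 1, 2, 4
        labels = ["a", "b", "c", "d"]
        D = np.array([
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 4],
            [8, 8, 4, 0],
        ], dtype=float)
        tree = upgma(SquareMatrix(labels, D, "distance"))
        recon = patristic_distances(tree).to_frame().loc[labels, labels].to_numpy()
        assert np.allclose(recon, D)

    def test_output_is_ultrametric_and_matches_scipy_cophenet(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(1, 10, (7, 7))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        labels = [f"s{i}" for i in range(7)]
        d = SquareMatrix(labels, values, "distance")
        tree = upgma(d)
        depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in tree.leaf_node_iter()
        }
        assert np.ptp(list(depths.values())) < 1e-9
        Z = hierarchy.linkage(squareform(values, checks=False), method="average")
        expected = squareform(hierarchy.cophenet(Z))
        recon = patristic_distances(tree).to_frame().loc[labels, labels].to_numpy()
        assert np.allclose(recon, expected, atol=1e-9)

    def test_tie_break_is_deterministic_lexicographic(self):
        # equilateral triangle: merge (a, b) first by the documented rule
        D = np.full((3, 3), 5.0)
        np.fill_diagonal(D, 0.0)
        tree = upgma(SquareMatrix(["c", "a", "b"], D, "distance"))
        from symbiopan.io_formats import tree_to_string

        newick = tree_to_string(tree)
        assert "(a:2.5,b:2.5)" in newick


class TestConcordance:
    def _simulate(self, seed, shuffle=False):
        rng = np.random.default_rng(seed)
        host, _ = yule_tree(16, 1.0, rng)
        assoc = block_association(host, 4, 3)
        table, s2h = simulate_read_counts(host, assoc, 0.5, 200.0, seed=seed)
        prof = compute_rpkm(table, 0.1, s2h)
        if shuffle:
            hosts = list(s2h.values())
            rng.shuffle(hosts)
            prof.sample_to_host = dict(zip(s2h.keys(), hosts))
        return host, prof

    def test_block_structured_profiles_detected(self):
        rejected = 0
        for seed in range(50):
            host, prof = self._simulate(seed)
            res = profile_concordance(host, prof, n_permutations=99, seed=seed)
            rejected += res.p_value < 0.05
        assert rejected >= 45  # >= 90% power

    def test_shuffled_profiles_reject_at_alpha(self):
        from scipy import stats

        rejected = 0
        n = 50
        for seed in range(n):
            host, prof = self._simulate(500 + seed, shuffle=True)
            res = profile_concordance(host, prof, n_permutations=99, seed=seed)
            rejected += res.p_value < 0.05
        lo, hi = stats.binom.interval(0.95, n, 0.05)
        assert lo <= rejected <= hi

    def test_full_chain_is_deterministic(self):
        host, prof = self._simulate(7)
        a = profile_concordance(host, prof, n_permutations=99, seed=3)
        b = profile_concordance(host, prof, n_permutations=99, seed=3)
        assert (a.m2, a.p_value) == (b.m2, b.p_value)


def test_mean_rpkm_by_group_reporting():
    prof = RpkmProfile(
        ["s1", "s2", "s3"], ["g1", "g2"],
        np.array([[2.0, 4.0], [1.0, 1.0], [0.0, 6.0]]), 0.1,
    )
    out = mean_rpkm_by_group(prof, {"s1": "famA", "s2": "famA", "s3": "famB"})
    assert out["famA"] == pytest.approx((3.0 + 1.0) / 2)
    assert out["famB"] == pytest.approx(3.0)
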