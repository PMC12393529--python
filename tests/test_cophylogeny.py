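"""Patristic distances, PCoA, PACo, generalized RF, and classification."""

import numpy as np
import pytest

import brute
from conftest import one_to_one_assoc
from symbiopan.cophylogeny import (
    classify_phylosymbiosis,
    congruence_rf,
    generalized_rf,
    map_symbiont_tips,
    nontrivial_splits,
    paco,
    patristic_distances,
    pcoa,
)
from symbiopan.io_formats import (
    AssociationMatrix,
    SquareMatrix,
    ValidationError,
    tree_from_string,
    tree_tip_labels,
)
from symbiopan.synthetic import CophyloSimConfig, simulate_cophylogeny, yule_tree


class TestPatristic:
    def test_hand_computed_examples(self):
        d = patristic_distances(tree_from_string("((A:1,B:1):1,C:2);")).to_frame()
        assert d.loc["A", "B"] == 2.0
        assert d.loc["A", "C"] == 4.0
        star = patristic_distances(tree_from_string("(A:1,B:1,C:1,D:1);"))
        off = star.values[~np.eye(4, dtype=bool)]
        assert (off == 2.0).all()

    def test_matches_dijkstra_on_edge_graph(self):
        rng = np.random.default_rng(1)
        tree, _ = yule_tree(20, 1.0, rng)
        d = patristic_distances(tree).to_frame()
        for (a, b), expected in brute.shortest_path_patristic(tree).items():
            assert d.loc[a, b] == pytest.approx(expected, abs=1e-9)


class TestPcoa:
    def test_collinear_points_recovered_on_single_axis(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(SquareMatrix(["a", "b", "c"], D, "distance"), "none")
        assert res.coords.shape[1] == 1
        recon = np.abs(res.coords[:, 0][:, None] - res.coords[:, 0][None, :])
        assert np.allclose(recon, D, atol=1e-9)

    def test_planar_euclidean_distances_recovered(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(SquareMatrix([f"p{i}" for i in range(10)], D, "distance"), "none")
        recon = np.sqrt(((res.coords[:, None] - res.coords[None, :]) ** 2).sum(-1))
        assert np.abs(recon - D).max() < 1e-6

    def test_ultrametric_tree_distances_are_euclidean_capable(self):
        # UPGMA-style ultrametric distances need no correction
        from symbiopan.profiles import upgma

        rng = np.random.default_rng(3)
        raw = rng.uniform(0.2, 1.0, (8, 8))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        tree = upgma(SquareMatrix([f"s{i}" for i in range(8)], values, "distance"))
        d = patristic_distances(tree)
        res = pcoa(d, "none")
        assert res.eigenvalues.min() > -1e-9

    @pytest.mark.parametrize("correction", ["cailliez", "lingoes"])
    def test_corrections_make_all_eigenvalues_nonnegative(self, correction):
        host, symb, _ = simulate_cophylogeny(
            CophyloSimConfig(n_hosts=12, switch_prob=0.5, seed=5)
        )
        res = pcoa(patristic_distances(symb), correction)
        assert res.eigenvalues.min() >= -1e-9
        if correction == "cailliez":
            # corrected distances are reproduced by the embedding
            D = patristic_distances(symb).values
            Dc = D + res.constant * (1 - np.eye(D.shape[0]))
            recon = np.sqrt(
                np.maximum(((res.coords[:, None] - res.coords[None, :]) ** 2).sum(-1), 0)
            )
            assert np.abs(recon - Dc).max() < 1e-6


class TestPaco:
    def test_identical_trees_reach_minimal_p(self, codiverged):
        host, _, _ = codiverged
        d = patristic_distances(host)
        assoc = one_to_one_assoc(d.labels, d.labels)
        res = paco(d, d, assoc, n_permutations=999, seed=1)
        assert res.m2 < 0.05
        assert res.p_value == pytest.approx(1 / 1000)

    def test_r2_complements_m2(self):
        # the published Faviidae coral analysis reports m2 = 0.59
        assert classify_phylosymbiosis  # namespace guard
        from symbiopan.cophylogeny import PacoResult

        res = PacoResult(0.59, 1 - 0.59, 0.025, 1000, "r0", 0)
        assert res.r2 == pytest.approx(0.41)

    def test_m2_matches_direct_procrustes_construction(self):
        for seed in range(5):
            host, symb, assoc = simulate_cophylogeny(
                CophyloSimConfig(n_hosts=10, switch_prob=0.4, seed=seed)
            )
            hd = patristic_distances(host).reorder(assoc.hosts)
            sd = patristic_distances(symb).reorder(assoc.symbionts)
            res = paco(hd, sd, assoc, n_permutations=9, seed=0)
            X = pcoa(hd, "cailliez").coords
            Y = pcoa(sd, "cailliez").coords
            hi = np.array([h for h, _ in assoc.link_pairs()])
            si = np.array([s for _, s in assoc.link_pairs()])
            assert res.m2 == pytest.approx(
                brute.procrustes_residual(X[hi], Y[si]), abs=1e-8
            )

    def test_invariant_to_tip_reordering_and_rescaling(self):
        host, symb, assoc = simulate_cophylogeny(
            CophyloSimConfig(n_hosts=10, switch_prob=0.3, seed=2)
        )
        hd = patristic_distances(host)
        sd = patristic_distances(symb)
        base = paco(hd, sd, assoc, n_permutations=9, seed=0).m2
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(hd.labels))
        hd_shuf = SquareMatrix(
            [hd.labels[i] for i in idx], hd.values[np.ix_(idx, idx)], "distance"
        )
        sd_scaled = SquareMatrix(sd.labels, sd.values * 7.3, "distance")
        alt = paco(hd_shuf, sd_scaled, assoc, n_permutations=9, seed=0).m2
        assert alt == pytest.approx(base, abs=1e-9)

    def test_too_few_links_rejected(self):
        d = patristic_distances(tree_from_string("((A:1,B:1):1,C:2);"))
        assoc = AssociationMatrix(["A"], ["A"], np.array([[1]]))
        with pytest.raises(ValidationError):
            paco(d, d, assoc, n_permutations=9, seed=0)

    def test_p_value_floor(self, codiverged):
        host, _, _ = codiverged
        d = patristic_distances(host)
        assoc = one_to_one_assoc(d.labels, d.labels)
        res = paco(d, d, assoc, n_permutations=99, seed=3)
        assert res.p_value >= 1 / 100


class TestGeneralizedRF:
    def test_identical_topologies_are_at_distance_zero(self):
        t1 = tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = tree_from_string("((C:2,D:1):3,(A:1,B:2):1);")
        assert generalized_rf(t1, t2).distance == 0.0

    def test_four_tip_conflict_matches_direct_mi_formula(self):
        t1 = tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = tree_from_string("((A:1,C:1):1,(B:1,D:1):1);")
        res = generalized_rf(t1, t2)
        tips = frozenset("ABCD")
        mi = brute.mi_splits(frozenset("CD"), frozenset("BD"), tips)
        h = 2 * brute.h2(2, 4)
        assert res.distance == pytest.approx(1 - 2 * mi / h)

    def test_symmetry_and_mismatched_tips_error(self):
        t1 = tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = tree_from_string("((A:1,C:1):1,(B:1,D:1):1);")
        assert generalized_rf(t1, t2).distance == generalized_rf(t2, t1).distance
        t3 = tree_from_string("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValidationError, match="E"):
            generalized_rf(t1, t3)

    @pytest.mark.parametrize("n_leaves", [5, 6])
    def test_matching_equals_exhaustive_enumeration(self, n_leaves):
        labels = [chr(ord("A") + i) for i in range(n_leaves)]
        graphs = brute.enumerate_unrooted_binary(labels)
        trees = [tree_from_string(brute.graph_to_newick(g, labels)) for g in graphs]
        splits = [brute.graph_splits(g, labels) for g in graphs]
        # package splits agree with graph-derived splits
        for t, s in zip(trees, splits):
            assert set(nontrivial_splits(t)) == s
        tips = frozenset(labels)
        rng = np.random.default_rng(0)
        n = len(trees)
        # all ordered pairs for 5 leaves; a full cross-section for 6
        if n_leaves == 5:
            pairs = [(i, j) for i in range(n) for j in range(n)]
        else:
            pairs = [(i, j) for i in range(n) for j in range(i, n)]
        for i, j in pairs:
            got = generalized_rf(trees[i], trees[j]).distance
            expected = brute.brute_generalized_rf(splits[i], splits[j], tips)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_mean_distance_increases_with_host_switching(self):
        means = []
        for sp in (0.0, 0.4, 0.8):
            ds = []
            for seed in range(50):
                host, symb, assoc = simulate_cophylogeny(
                    CophyloSimConfig(n_hosts=16, switch_prob=sp, seed=seed)
                )
                ds.append(congruence_rf(host, symb, assoc, 1, seed).distance)
            means.append(np.mean(ds))
        assert means[0] < means[1] < means[2]


class TestTipMapping:
    def test_one_to_one_returns_single_relabeled_tree(self, codiverged):
        host, symb, assoc = codiverged
        trees = map_symbiont_tips(symb, assoc, 100, 0)
        assert len(trees) == 1
        assert sorted(tree_tip_labels(trees[0])) == sorted(assoc.hosts)

    def test_subsampling_frequencies_are_uniform(self):
        # H1 has three linked tips whose terminal edge lengths survive
        # pruning distinctly, so the chosen tip is identifiable per subsample
        symb = tree_from_string(
            "((s1:1,(s2:0.5,s3:0.25):1):1,(s4:1,s5:1):1);"
        )
        links = np.array([[1, 1, 1, 0, 0], [0, 0, 0, 1, 0], [0, 0, 0, 0, 1]])
        assoc = AssociationMatrix(
            ["H1", "H2", "H3"], ["s1", "s2", "s3", "s4", "s5"], links
        )
        n_sub = 300
        trees = map_symbiont_tips(symb, assoc, n_sub, 5)
        assert len(trees) == n_sub
        # after pruning, H1's terminal edge absorbs the suppressed
        # unifurcations: s1 -> 1+1, s2 -> 0.5+1+1, s3 -> 0.25+1+1
        length_to_tip = {2.0: "s1", 2.5: "s2", 2.25: "s3"}
        counts = {"s1": 0, "s2": 0, "s3": 0}
        for t in trees:
            leaf = next(
                l for l in t.leaf_node_iter() if l.taxon.label == "H1"
            )
            counts[length_to_tip[round(leaf.edge.length, 6)]] += 1
        # binomial sd ~ 8.2 at n=300, p=1/3; allow 4 sd
        for tip in counts:
            assert abs(counts[tip] - 100) < 33

    def test_subsampling_is_deterministic_under_fixed_seed(self):
        host, symb, assoc = simulate_cophylogeny(
            CophyloSimConfig(n_hosts=6, multi_assoc_rate=2.0, seed=21)
        )
        from symbiopan.io_formats import tree_to_string

        a = map_symbiont_tips(symb, assoc, 20, 5)
        b = map_symbiont_tips(symb, assoc, 20, 5)
        assert [tree_to_string(t) for t in a] == [tree_to_string(t) for t in b]

    def test_congruence_rf_requires_four_hosts(self):
        host, symb, assoc = simulate_cophylogeny(CophyloSimConfig(n_hosts=8, seed=1))
        small = tree_from_string("((A:1,B:1):1,C:2);")
        with pytest.raises(ValidationError):
            congruence_rf(small, symb, assoc, 1, 0)


TABLE1_STYLE_ROWS = [
    # (host clade, p, m2, RF, expected signal, expected congruence)
    ("Animalia", 0.00, 0.93, 0.85, "low", "none"),
    ("Mollusca", 0.01, 0.60, 0.60, "high", "weak"),
    ("Cnidaria", 0.01, 0.89, 0.85, "low", "none"),
    ("Porifera", 0.47, 0.86, 0.93, "none", "none"),
    ("Nematoda", 0.00, 0.80, None, "high", "none"),
    ("Bivalvia", 0.01, 0.65, 0.75, "high", "weak"),
    ("Faviidae", 0.03, 0.59, 0.73, "high", "weak"),
]


class TestClassification:
    @pytest.mark.parametrize("row", TABLE1_STYLE_ROWS, ids=lambda r: r[0])
    def test_published_survey_labels_reproduced(self, row):
        _, p, m2, rf, signal, congruence = row
        call = classify_phylosymbiosis(p, 1 - m2, rf)
        assert (call.signal, call.congruence) == (signal, congruence)

    def test_reported_triples_from_survey_text(self):
        # low signal / no congruence at p = 0.011, R2 = 0.11
        c = classify_phylosymbiosis(0.011, 0.11, 0.85)
        assert (c.signal, c.congruence) == ("low", "none")
        # high signal / no congruence at p < 0.001, R2 = 0.20
        c = classify_phylosymbiosis(0.0009, 0.20)
        assert (c.signal, c.congruence) == ("high", "none")
        # no signal at p = 0.47 regardless of R2
        c = classify_phylosymbiosis(0.47, 0.14, 0.93)
        assert (c.signal, c.congruence) == ("none", "none")

    def test_congruence_requires_signal(self):
        for p in np.linspace(0, 1, 21):
            for r2 in np.linspace(0, 1, 21):
                call = classify_phylosymbiosis(float(p), float(r2))
                if call.congruence != "none":
                    assert call.signal != "none"

    def test_rf_gate(self):
        assert classify_phylosymbiosis(0.01, 0.5, 0.9, rf_gate=0.8).congruence == "none"
        assert classify_phylosymbiosis(0.01, 0.5, 0.7, rf_gate=0.8).congruence == "weak"
        assert classify_phylosymbiosis(0.01, 0.7, 0.7, rf_gate=0.8).congruence == "strong"
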