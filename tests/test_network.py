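"""Accessory-network construction and assortativity."""

import itertools

import numpy as np
import pytest

from symbiopan.io_formats import GeneFamilyMatrix, GenomeMetadata, SquareMatrix, ValidationError
from symbiopan.network import (
    build_network,
    filter_accessory,
    genome_similarity,
    label_assortativity,
)
from symbiopan.pangenome import partition_gene_families


def toy_sim(labels, values):
    return SquareMatrix(labels, np.asarray(values, float), "similarity")


class TestFilterAccessory:
    def test_core_only_matrix_is_an_error(self):
        m = GeneFamilyMatrix(["f"], ["a", "b", "c"], np.ones((1, 3), dtype=np.int8))
        s = partition_gene_families(m)
        with pytest.raises(ValidationError, match="threshold"):
            filter_accessory(m, s, 0.05)

    def test_prevalence_boundary(self):
        # 100 genomes: prevalence 0.04 dropped, 0.06 kept at filter 0.05
        n = 100
        presence = np.zeros((3, n), dtype=np.int8)
        presence[0, :] = 1
        presence[1, :4] = 1
        presence[2, :6] = 1
        m = GeneFamilyMatrix(["core", "rare", "common"], [f"g{i}" for i in range(n)], presence)
        s = partition_gene_families(m)
        kept = filter_accessory(m, s, 0.05)
        assert kept.families == ["common"]

    def test_matches_brute_force_set_comprehension(self, small_pangenome):
        m, _ = small_pangenome
        s = partition_gene_families(m)
        kept = filter_accessory(m, s, 0.05)
        n = len(m.genomes)
        expected = {
            fam
            for i, fam in enumerate(m.families)
            if s.classification[fam] == "accessory" and m.presence[i].sum() / n > 0.05
        }
        assert set(kept.families) == expected


class TestSimilarity:
    def test_identical_and_disjoint_columns(self):
        presence = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=np.int8)
        m = GeneFamilyMatrix(["f1", "f2", "f3"], ["a", "b", "c"], presence)
        sim = genome_similarity(m, "jaccard")
        assert sim.values[0, 1] == 1.0
        assert sim.values[0, 2] == 0.0

    def test_matches_brute_force_sets(self):
        rng = np.random.default_rng(2)
        presence = (rng.random((10, 6)) < 0.4).astype(np.int8)
        presence[:, 0] |= presence.sum(axis=1) == 0  # keep families non-empty
        m = GeneFamilyMatrix(
            [f"f{i}" for i in range(10)], [f"g{j}" for j in range(6)], presence
        )
        sim = genome_similarity(m, "jaccard")
        for i, j in itertools.combinations(range(6), 2):
            si = {k for k in range(10) if presence[k, i]}
            sj = {k for k in range(10) if presence[k, j]}
            expected = len(si & sj) / len(si | sj) if si | sj else 0.0
            assert sim.values[i, j] == pytest.approx(expected)

    def test_jaccard_ignores_families_absent_from_both(self):
        # families carried only by a third genome must not alter sim(x, y)
        base = np.array([[1, 0, 0], [0, 1, 1], [1, 1, 0]], dtype=np.int8)
        extra = np.array([[0, 0, 1], [0, 0, 1]], dtype=np.int8)
        m_small = GeneFamilyMatrix(["a", "b", "c"], ["x", "y", "z"], base)
        m_big = GeneFamilyMatrix(
            ["a", "b", "c", "d", "e"], ["x", "y", "z"], np.vstack([base, extra])
        )
        assert genome_similarity(m_small).values[0, 1] == pytest.approx(
            genome_similarity(m_big).values[0, 1]
        )


class TestBuildNetwork:
    def test_threshold_zero_gives_complete_graph(self):
        sim = toy_sim(["a", "b", "c"], [[1, .2, .3], [.2, 1, .4], [.3, .4, 1]])
        net = build_network(sim, 0.0)
        assert net.number_of_edges() == 3

    def test_threshold_one_gives_edgeless_graph_with_nodes(self):
        sim = toy_sim(["a", "b"], [[1, .9], [.9, 1]])
        net = build_network(sim, 1.0)
        assert net.number_of_edges() == 0 and net.number_of_nodes() == 2

    def test_edge_set_matches_brute_filter_and_is_monotone(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0, 1, (8, 8))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 1.0)
        sim = SquareMatrix([f"g{i}" for i in range(8)], values, "similarity")
        prev_edges = None
        for thr in (0.2, 0.5, 0.8):
            net = build_network(sim, thr)
            expected = {
                frozenset((sim.labels[i], sim.labels[j]))
                for i in range(8) for j in range(i + 1, 8)
                if values[i, j] >= thr
            }
            got = {frozenset(e) for e in net.edges}
            assert got == expected
            if prev_edges is not None:
                assert got <= prev_edges
            prev_edges = got


class TestAssortativity:
    def test_two_cliques_without_cross_edges_score_one(self):
        labels = [f"g{i}" for i in range(6)]
        values = np.full((6, 6), 0.1)
        values[:3, :3] = 0.9
        values[3:, 3:] = 0.9
        np.fill_diagonal(values, 1.0)
        sim = SquareMatrix(labels, values, "similarity")
        meta = [
            GenomeMetadata(g, "host_associated" if i < 3 else "free_living")
            for i, g in enumerate(labels)
        ]
        net = build_network(sim, 0.5, meta)
        assert label_assortativity(net, "lifestyle") == pytest.approx(1.0)

    def test_random_labels_on_complete_graph_near_zero(self):
        n = 20
        values = np.full((n, n), 0.9)
        np.fill_diagonal(values, 1.0)
        labels = [f"g{i}" for i in range(n)]
        sim = SquareMatrix(labels, values, "similarity")
        rs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            meta = [
                GenomeMetadata(
                    g, "host_associated" if rng.random() < 0.5 else "free_living"
                )
                for g in labels
            ]
            net = build_network(sim, 0.5, meta)
            rs.append(label_assortativity(net, "lifestyle"))
        assert abs(np.mean(rs)) < 0.1

    def test_edgeless_network_is_an_error(self):
        sim = toy_sim(["a", "b"], [[1, 0.1], [0.1, 1]])
        net = build_network(sim, 0.9)
        with pytest.raises(ValidationError):
            label_assortativity(net, "lifestyle")

    def test_block_structured_accessory_content_beats_random_labels(self):
        # genomes in the same planted block share accessory genes; block
        # labels should be more assortative than shuffled labels
        rng = np.random.default_rng(9)
        n_blocks, per_block, n_fam = 4, 6, 60
        genomes = [f"g{i:02d}" for i in range(n_blocks * per_block)]
        presence = np.zeros((n_fam, len(genomes)), dtype=np.int8)
        for f in range(n_fam):
            block = f % n_blocks
            cols = slice(block * per_block, (block + 1) * per_block)
            presence[f, cols] = (rng.random(per_block) < 0.8).astype(np.int8)
            presence[f] |= (rng.random(len(genomes)) < 0.05).astype(np.int8)
        keep = presence.sum(axis=1) > 0
        m = GeneFamilyMatrix(
            [f"f{f}" for f in np.flatnonzero(keep)], genomes, presence[keep]
        )
        sim = genome_similarity(m)
        net = build_network(sim, 0.1)
        for i, g in enumerate(genomes):
            net.nodes[g]["block"] = f"B{i // per_block}"
        r_block = label_assortativity(net, "block")
        wins = 0
        for seed in range(20):
            srng = np.random.default_rng(100 + seed)
            shuffled = srng.permutation([net.nodes[g]["block"] for g in genomes])
            for g, lab in zip(genomes, shuffled):
                net.nodes[g]["random"] = lab
            if r_block > label_assortativity(net, "random"):
                wins += 1
        assert wins >= 19
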