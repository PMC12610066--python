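"""Distances, neighbor joining, bootstrap, PCA, GRM, tree cutting and
grouping concordance."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from slafkit import sim
from slafkit.structure import (
    bootstrap_support,
    cross_tabulate,
    cut_tree,
    genetic_groups,
    grm,
    hierarchical_tree,
    neighbor_joining,
    p_distance,
    partition_concordance,
    pca,
)
from slafkit.variants import PopulationMap

from conftest import make_matrix


def path_length_matrix(tree, ids):
    """Oracle: leaf-to-leaf path lengths of a tree by summing branch lengths."""
    out = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                d = tree.find(a).distance(tree.find(b))
                out[i, j] = out[j, i] = d
    return out


class TestPDistance:
    def test_identical_samples_zero(self):
        matrix = make_matrix([[(0, 1), (0, 1)], [(1, 1), (1, 1)]])
        D = p_distance(matrix)
        assert D["s0", "s1"] == 0.0

    def test_opposite_homozygotes_maximal(self):
        matrix = make_matrix([[(0, 0), (1, 1)], [(0, 0), (1, 1)]])
        assert p_distance(matrix)["s0", "s1"] == 1.0

    def test_hand_count_with_het(self):
        # locus 1: 0/0 vs 0/1 -> 0.5; locus 2: 0/0 vs 0/0 -> 0
        matrix = make_matrix([[(0, 0), (0, 1)], [(0, 0), (0, 0)]])
        assert p_distance(matrix)["s0", "s1"] == pytest.approx(0.25)

    def test_missing_excluded_pairwise(self):
        matrix = make_matrix([[(0, 0), (1, 1)], [None, (0, 0)]])
        assert p_distance(matrix)["s0", "s1"] == 1.0

    def test_no_shared_loci_is_an_error(self):
        matrix = make_matrix([[(0, 0), None], [None, (0, 0)]])
        with pytest.raises(ValueError, match="share no typed loci"):
            p_distance(matrix)

    def test_triangle_inequality_on_complete_data(self, sim_dataset):
        _, matrix, _ = sim_dataset
        small = matrix.take_sites(range(300)).take_samples(matrix.sample_ids[:12])
        D = p_distance(small).data
        n = D.shape[0]
        for i, j, k in itertools.combinations(range(n), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestNeighborJoining:
    def test_two_taxa_total_length(self):
        dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["a", "b"])
        tree = neighbor_joining(dm)
        total = sum(t.length or 0 for t in tree.traverse(include_self=False))
        assert total == pytest.approx(0.4)

    def test_three_taxa_closed_form(self):
        d_ab, d_ac, d_bc = 0.3, 0.5, 0.6
        dm = DistanceMatrix(
            [[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]], ids=["a", "b", "c"]
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["b"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["c"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_additive_matrix_recovered_exactly(self):
        # random binary tree over 8 taxa, distances from its path lengths
        rng = np.random.default_rng(42)
        ids = [f"t{i}" for i in range(8)]
        newick = "((((t0:0.11,t1:0.07):0.05,t2:0.21):0.04,(t3:0.09,t4:0.13):0.08):0.03,(t5:0.06,(t6:0.17,t7:0.02):0.12):0.10);"
        source = TreeNode.read([newick])
        D = path_length_matrix(source, ids)
        tree = neighbor_joining(DistanceMatrix(D, ids=ids))
        np.testing.assert_allclose(path_length_matrix(tree, ids), D, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(Exception):
            DistanceMatrix([[0, 1], [2, 0]], ids=["a", "b"])


@pytest.fixture(scope="module")
def clade_matrix():
    # two clades of 6 samples with 40 fixed differences + shared noise
    rng = np.random.default_rng(3)
    cols = []
    for _ in range(40):
        cols.append([(0, 0)] * 6 + [(1, 1)] * 6)
    for _ in range(40):
        calls = [tuple(sorted(rng.integers(0, 2, 2))) for _ in range(12)]
        cols.append([(int(a), int(b)) for a, b in calls])
    return make_matrix(cols)


class TestBootstrap:
    def test_perfect_split_gets_full_support(self, clade_matrix):
        tree = bootstrap_support(clade_matrix, replicates=50, seed=0)
        clade_a = frozenset(f"s{i}" for i in range(6))
        supports = {}
        for node in tree.traverse(include_self=False):
            if node.is_tip() or node.name is None:
                continue
            tips = frozenset(t.name for t in node.tips())
            supports[tips] = float(node.name)
            assert 0.0 <= float(node.name) <= 1.0
        key = [k for k in supports if k in (clade_a, frozenset(f"s{i}" for i in range(6, 12)))]
        assert key and all(supports[k] == 1.0 for k in key)

    def test_deterministic_under_seed(self, clade_matrix):
        t1 = bootstrap_support(clade_matrix, replicates=30, seed=11)
        t2 = bootstrap_support(clade_matrix, replicates=30, seed=11)
        assert str(t1) == str(t2)

    def test_support_increases_with_divergence(self):
        supports = []
        for n_fixed in (1, 5, 25):
            cols = [[(0, 0)] * 5 + [(1, 1)] * 5] * n_fixed
            rng = np.random.default_rng(9)
            for _ in range(60):
                cols.append(
                    [tuple(int(x) for x in sorted(rng.integers(0, 2, 2))) for _ in range(10)]
                )
            tree = bootstrap_support(make_matrix(cols), replicates=60, seed=5)
            clade = frozenset(f"s{i}" for i in range(5))
            best = 0.0
            for node in tree.traverse(include_self=False):
                if node.is_tip() or node.name is None:
                    continue
                tips = frozenset(t.name for t in node.tips())
                if tips in (clade, frozenset(f"s{i}" for i in range(5, 10))):
                    best = float(node.name)
            supports.append(best)
        assert supports == sorted(supports)
        assert supports[-1] > supports[0]

    def test_replicates_validation(self, clade_matrix):
        with pytest.raises(ValueError):
            bootstrap_support(clade_matrix, replicates=0)


class TestPca:
    def test_two_groups_separate_on_pc1(self):
        cols = []
        for _ in range(30):
            cols.append([(0, 0)] * 5 + [(1, 1)] * 5)
        for _ in range(30):
            cols.append([(0, 1), (0, 0), (0, 1), (1, 1), (0, 0)] * 2)
        res = pca(make_matrix(cols), n_components=4)
        pc1 = res.coordinates[:, 0]
        assert pc1[:5].max() < pc1[5:].min() or pc1[5:].max() < pc1[:5].min()
        assert res.variance_fraction[0] > res.variance_fraction[1]

    def test_variance_fractions_valid(self, sim_dataset):
        _, matrix, _ = sim_dataset
        res = pca(matrix.take_sites(range(500)), n_components=6)
        vf = res.variance_fraction
        assert (np.diff(vf) <= 1e-12).all()
        assert 0 < vf.sum() <= 1 + 1e-9
        assert (vf >= 0).all()

    def test_monomorphic_matrix_rejected(self):
        matrix = make_matrix([[(0, 0), (0, 0)], [(1, 1), (1, 1)]])
        with pytest.raises(ValueError, match="polymorphic"):
            pca(matrix)


class TestGrm:
    def test_duplicated_sample_matches_diagonal(self):
        cols = [
            [(0, 1), (0, 1), (1, 1), (0, 0)],
            [(0, 0), (0, 0), (0, 1), (1, 1)],
            [(1, 1), (1, 1), (0, 1), (0, 0)],
            [(0, 1), (0, 1), (0, 0), (1, 1)],
        ]
        G = grm(make_matrix(cols))
        assert G.iloc[0, 1] == pytest.approx(G.iloc[0, 0])

    def test_unstructured_off_diagonal_near_zero_and_psd(self):
        config = sim.SimConfig(
            n_ancestral_pops=1, fst_per_pop=0.0, n_loci=2000, missing_rate=0.0, seed=5
        )
        matrix, _ = sim.simulate_population(config)
        G = grm(matrix).to_numpy()
        off = G[~np.eye(len(G), dtype=bool)]
        assert abs(off.mean()) < 0.01
        assert np.diag(G).mean() == pytest.approx(1.0, abs=0.05)
        evals = np.linalg.eigvalsh(G)
        assert evals.min() > -1e-8


class TestCutTree:
    def test_k_one_and_k_n(self):
        tree = TreeNode.read(["((a:1,b:1):2,(c:1,d:1):2):0;"])
        assert set(cut_tree(tree, 1).values()) == {"C1"}
        part = cut_tree(tree, 4)
        assert len(set(part.values())) == 4

    def test_k_validation(self):
        tree = TreeNode.read(["(a:1,b:1);"])
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 3)

    def test_three_clades_recovered_from_clean_tree(self):
        newick = (
            "(((a1:.01,a2:.01):.01,a3:.02):.5,((b1:.01,b2:.01):.5,"
            "((c1:.01,c2:.02):.01,c3:.01):.5):.02);"
        )
        part = cut_tree(TreeNode.read([newick]), 3)
        groups = {}
        for leaf, label in part.items():
            groups.setdefault(label, set()).add(leaf)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset({"a1", "a2", "a3"}),
            frozenset({"b1", "b2"}),
            frozenset({"c1", "c2", "c3"}),
        }


class TestConcordance:
    def test_identical_partitions(self):
        p = {"a": "x", "b": "y", "c": "x"}
        assert partition_concordance(p, p) == 1.0

    def test_one_swapped_sample(self):
        # oracle: best over all label bijections of 2-cluster agreement
        p1 = {s: ("L" if i < 3 else "R") for i, s in enumerate("abcdef")}
        p2 = dict(p1)
        p2["c"], p2["d"] = p2["d"], p2["c"]
        best = 0
        for perm in itertools.permutations(["L", "R"]):
            relabel = dict(zip(["L", "R"], perm))
            best = max(best, sum(p1[s] == relabel[p2[s]] for s in p1))
        assert best == 4
        assert partition_concordance(p1, p2) == pytest.approx(4 / 6)

    def test_relabeling_invariance(self):
        p1 = {"a": "x", "b": "y", "c": "x", "d": "z"}
        p2 = {"a": "1", "b": "2", "c": "2", "d": "3"}
        renamed = {s: f"G{v}" for s, v in p2.items()}
        assert partition_concordance(p1, p2) == partition_concordance(p1, renamed)

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partition_concordance({"a": "x"}, {"b": "x"})


class TestCrossTabulate:
    def test_row_totals_and_ratio(self):
        partition = {f"s{i}": ("G1" if i < 4 else "G2") for i in range(10)}
        pm = PopulationMap({f"s{i}": ("B" if i % 2 else "Q") for i in range(10)})
        table = cross_tabulate(partition, pm)
        assert table.loc["G1", "All"] == 4
        assert table.loc["All", "All"] == 10
        assert table.loc["G1", "Ratio(%)"] == pytest.approx(40.0)
        cols = [c for c in table.columns if c not in ("All", "Ratio(%)")]
        assert (table.loc["All", cols] == table.loc[["G1", "G2"], cols].sum()).all()

    def test_empty_cluster_absent_unmapped_rejected(self):
        with pytest.raises(ValueError):
            cross_tabulate({"a": "G1"}, PopulationMap({}))


class TestStructureRecovery:
    def test_groups_match_truth(self, sim_dataset, truth_partition):
        from slafkit.variants import filter_sites

        _, matrix, _ = sim_dataset
        part = genetic_groups(filter_sites(matrix), k=3)
        assert partition_concordance(part, truth_partition) >= 0.95

    def test_silhouette_positive_on_pca(self, sim_dataset):
        from sklearn.metrics import silhouette_score

        _, matrix, truth = sim_dataset
        res = pca(matrix, n_components=2)
        score = silhouette_score(res.coordinates, truth.ancestral_assignment)
        assert score > 0

    def test_hierarchical_tree_is_a_valid_tree(self, sim_dataset):
        _, matrix, _ = sim_dataset
        res = pca(matrix.take_sites(range(400)), n_components=2)
        tree = hierarchical_tree(res.coordinates, res.sample_ids)
        assert sorted(t.name for t in tree.tips()) == sorted(matrix.sample_ids)
        assert all((t.length or 0) >= 0 for t in tree.traverse(include_self=False))
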