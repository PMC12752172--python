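"""Alpha/beta diversity against independent brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from microcore import (
    CountTable,
    bray_curtis,
    chao1,
    pcoa,
    rarefy,
    shannon,
    simulate_tree,
    unweighted_unifrac,
)


def brute_shannon(counts):
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * np.log(p)
    return h


def brute_chao1(counts):
    s_obs = sum(1 for c in counts if c > 0)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def brute_bray_curtis(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def brute_unifrac(tree, present_a, present_b):
    """Edge walk: sum branch lengths unique to either sample over shared+unique."""
    unique = shared = 0.0
    for node in tree.tree.traverse(include_self=False):
        below = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        in_a = bool(below & present_a)
        in_b = bool(below & present_b)
        if in_a and in_b:
            shared += node.length
        elif in_a or in_b:
            unique += node.length
    return unique / (unique + shared)


class TestAlphaOracles:
    def test_shannon_known_values(self):
        assert shannon(np.array([5, 5, 5, 5])) == pytest.approx(np.log(4), abs=1e-12)
        assert shannon(np.array([10, 0, 0])) == pytest.approx(0.0, abs=1e-12)

    def test_chao1_formula(self):
        counts = np.array([1, 1, 1, 1, 2, 2, 5, 6, 7, 8])  # S=10, F1=4, F2=2
        assert chao1(counts) == pytest.approx(12.0)
        no_singletons = np.array([3, 4, 5])
        assert chao1(no_singletons) == pytest.approx(3.0)

    def test_random_vectors_match_brute_force(self, tiny_table):
        for j in range(tiny_table.n_samples):
            col = tiny_table.counts[:, j]
            assert shannon(col) == pytest.approx(brute_shannon(col), abs=1e-10)
            assert chao1(col) == pytest.approx(brute_chao1(col), abs=1e-10)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            shannon(np.zeros(3))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = CountTable(
            np.array([[5, 5, 5, 0], [3, 3, 0, 7]]).T,
            [f"O{i}" for i in range(4)],
            ["a", "b"],
        )
        # a vs a would be 0; a vs b shares O0, O1 only partially
        dm = bray_curtis(t, use_proportions=False)
        assert dm["a", "a"] == 0.0
        disjoint = CountTable(
            np.array([[5, 0], [0, 3]]), ["O1", "O2"], ["a", "b"]
        )
        assert bray_curtis(disjoint, use_proportions=False)["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        t = CountTable(np.array([[2, 0], [1, 1], [0, 2]]), ["A", "B", "C"], ["s1", "s2"])
        dm = bray_curtis(t, use_proportions=False)
        assert dm["s1", "s2"] == pytest.approx(2 / 3)

    def test_matches_brute_force_on_random_table(self, tiny_table):
        dm = bray_curtis(tiny_table, use_proportions=False)
        for j in range(6):
            for k in range(j + 1, 6):
                expected = brute_bray_curtis(
                    tiny_table.counts[:, j], tiny_table.counts[:, k]
                )
                assert dm.data[j, k] == pytest.approx(expected, abs=1e-10)

    def test_bounds_and_symmetry(self, tiny_table):
        dm = bray_curtis(tiny_table)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        assert np.allclose(dm.data, dm.data.T)


class TestUnweightedUnifrac:
    def test_identical_presence_sets(self):
        tree = simulate_tree(6, seed=0)
        counts = np.array([[3, 5]] * 6)
        t = CountTable(counts, tree.tip_names, ["a", "b"])
        dm = unweighted_unifrac(t, tree)
        assert dm["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_four_tip_hand_tree(self, tmp_path):
        from microcore import read_tree

        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,(C:1,D:1):1);")
        tree = read_tree(path)
        t = CountTable(
            np.array([[1, 1], [1, 0], [0, 1], [0, 0]]), list("ABCD"), ["s1", "s2"]
        )
        dm = unweighted_unifrac(t, tree)
        expected = brute_unifrac(tree, {"A", "B"}, {"A", "C"})
        assert dm["s1", "s2"] == pytest.approx(expected, abs=1e-12)

    def test_matches_edge_walk_on_random_tree(self):
        tree = simulate_tree(12, seed=3)
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 3, size=(12, 5))
        counts[0] += 1
        t = CountTable(counts, tree.tip_names, [f"s{j}" for j in range(5)])
        dm = unweighted_unifrac(t, tree)
        present = [set(np.array(t.otu_ids)[counts[:, j] > 0]) for j in range(5)]
        for j in range(5):
            for k in range(j + 1, 5):
                assert dm.data[j, k] == pytest.approx(
                    brute_unifrac(tree, present[j], present[k]), abs=1e-10
                )

    def test_missing_otu_named_in_error(self):
        tree = simulate_tree(4, seed=0)
        t = CountTable(np.ones((2, 2), dtype=int), ["OTU_1", "ghost"], ["a", "b"])
        with pytest.raises(ValueError, match="ghost"):
            unweighted_unifrac(t, tree)


class TestPcoa:
    def test_euclidean_recovery(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 3))
        from skbio import DistanceMatrix

        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(20)])
        res = pcoa(d)
        rec = squareform(pdist(res.coordinates[:, :3]))
        assert np.abs(rec - d.data).max() < 1e-8

    def test_eigenvalues_sorted_and_proportions(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 4))
        from skbio import DistanceMatrix

        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(10)])
        res = pcoa(d)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        pos = res.proportion_explained[res.eigenvalues > 0]
        assert pos.sum() == pytest.approx(1.0)
        assert (res.proportion_explained >= 0).all()

    def test_matches_skbio_on_bray_curtis(self, tiny_table):
        import skbio.stats.ordination as sko

        dm = bray_curtis(tiny_table)
        ours = pcoa(dm)
        ref = sko.pcoa(dm)
        n_axes = min(ours.coordinates.shape[1], 3)
        for ax in range(n_axes):
            ref_ax = ref.samples.iloc[:, ax].to_numpy()
            got = ours.coordinates[:, ax]
            sign = np.sign(np.dot(ref_ax, got)) or 1.0
            assert np.allclose(got, sign * ref_ax, atol=1e-8)

    def test_zero_distances_give_zero_coordinates(self):
        from skbio import DistanceMatrix

        d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(d)
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)


class TestRarefy:
    def test_column_sums_equal_depth(self, tiny_table):
        depth = int(tiny_table.library_sizes().min())
        out = rarefy(tiny_table, seed=0)
        assert (out.counts.sum(axis=0) == depth).all()
        assert (out.counts <= tiny_table.counts).all()

    def test_full_depth_identity(self):
        t = CountTable(np.array([[3], [7]]), ["A", "B"], ["S1"])
        out = rarefy(t, depth=10, seed=1)
        assert out == t

    def test_hypergeometric_expectation(self):
        counts = np.array([[60], [30], [10]])
        t = CountTable(counts, ["A", "B", "C"], ["S1"])
        reps = np.array(
            [rarefy(t, depth=20, seed=s).counts[:, 0] for s in range(1000)]
        )
        expected = 20 * counts[:, 0] / 100
        assert np.abs(reps.mean(axis=0) - expected).max() < 0.5

    def test_shallow_sample_handling(self, tiny_table):
        depth = int(tiny_table.library_sizes().max())
        with pytest.raises(ValueError, match="below rarefaction depth"):
            rarefy(tiny_table, depth=depth + 1)
        out = rarefy(tiny_table, depth=depth, drop_small=True, seed=0)
        assert out.n_samples >= 1
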