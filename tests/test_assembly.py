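"""betaMNTD/betaNTI null models and the Sloan neutral fit."""

import numpy as np
import pytest

from microcore import (
    CountTable,
    beta_mntd,
    beta_nti,
    classify_partition,
    fit_sloan_neutral,
    simulate_metacommunity,
    simulate_neutral_counts,
    simulate_tree,
)
from microcore.assembly import _predicted_occupancy


def brute_bmntd(dist, counts, weighted=True):
    """Loop-based betaMNTD oracle over all sample pairs."""
    n_taxa, n_samp = counts.shape
    out = np.zeros((n_samp, n_samp))
    for j in range(n_samp):
        for k in range(n_samp):
            if j == k:
                continue
            present_k = np.nonzero(counts[:, k])[0]
            present_j = np.nonzero(counts[:, j])[0]
            if weighted:
                fj = counts[:, j] / counts[:, j].sum()
                fk = counts[:, k] / counts[:, k].sum()
            else:
                fj = (counts[:, j] > 0) / (counts[:, j] > 0).sum()
                fk = (counts[:, k] > 0) / (counts[:, k] > 0).sum()
            s = 0.0
            for i in present_j:
                s += fj[i] * min(dist[i, i2] for i2 in present_k)
            for i in present_k:
                s += fk[i] * min(dist[i, i2] for i2 in present_j)
            out[j, k] = s / 2
    return out


class TestBetaMntd:
    def test_identical_communities_zero(self):
        tree = simulate_tree(5, seed=0)
        counts = np.tile(np.array([[3], [1], [0], [2], [0]]), (1, 2))
        t = CountTable(counts, tree.tip_names, ["a", "b"])
        dm = beta_mntd(t, tree)
        assert dm["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_monodominant_sister_tips(self, tmp_path):
        from microcore import read_tree

        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:3);")
        tree = read_tree(path)
        t = CountTable(np.array([[9, 0], [0, 4], [0, 0]]), list("ABC"), ["a", "b"])
        dm = beta_mntd(t, tree)
        assert dm["a", "b"] == pytest.approx(2.0)  # patristic A-B distance

    def test_weighted_equals_unweighted_for_equal_abundances(self):
        tree = simulate_tree(8, seed=1)
        counts = (np.random.default_rng(0).integers(0, 2, size=(8, 4)) * 5).astype(int)
        counts[0] = 5  # keep every sample non-empty, all present taxa equal
        t = CountTable(counts, tree.tip_names, [f"s{j}" for j in range(4)])
        w = beta_mntd(t, tree, weighted=True)
        u = beta_mntd(t, tree, weighted=False)
        assert np.allclose(w.data, u.data, atol=1e-12)

    def test_matches_brute_force(self):
        tree = simulate_tree(10, seed=2)
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 6, size=(10, 6))
        counts[0] += 1
        t = CountTable(counts, tree.tip_names, [f"s{j}" for j in range(6)])
        dist = tree.patristic().filter(t.otu_ids).data
        for weighted in (True, False):
            got = beta_mntd(t, tree, weighted=weighted).data
            want = brute_bmntd(dist, counts.astype(float), weighted)
            assert np.abs(got - (want + want.T) / 2).max() < 1e-10


class TestBetaNti:
    def test_seed_determinism(self):
        tree = simulate_tree(30, seed=0)
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 8, size=(30, 6))
        counts[0] += 1
        t = CountTable(counts, tree.tip_names, [f"s{j}" for j in range(6)])
        a = beta_nti(t, tree, n_null=49, seed=9)
        b = beta_nti(t, tree, n_null=49, seed=9)
        assert np.array_equal(a.bnti.to_numpy(), b.bnti.to_numpy(), equal_nan=True)

    def test_relabeling_samples_is_irrelevant(self):
        tree = simulate_tree(25, seed=4)
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 8, size=(25, 5))
        counts[0] += 1
        t1 = CountTable(counts, tree.tip_names, [f"s{j}" for j in range(5)])
        t2 = CountTable(counts, tree.tip_names, [f"x{j}" for j in range(5)])
        a = beta_nti(t1, tree, n_null=29, seed=0)
        b = beta_nti(t2, tree, n_null=29, seed=0)
        assert np.allclose(a.bnti.to_numpy(), b.bnti.to_numpy(), equal_nan=True)

    def test_null_data_calibrated(self):
        """Communities with no phylogenetic structure give betaNTI ~ N(0,1)."""
        tree = simulate_tree(150, seed=11)
        rng = np.random.default_rng(3)
        counts = np.zeros((150, 15), dtype=int)
        for j in range(15):
            idx = rng.choice(150, size=40, replace=False)
            counts[idx, j] = rng.poisson(rng.lognormal(2, 1, size=40)) + 1
        t = CountTable(counts, tree.tip_names, [f"s{j}" for j in range(15)])
        res = beta_nti(t, tree, n_null=199, seed=5)
        vals = res.pair_values()
        assert -0.5 < np.nanmean(vals) < 0.5
        assert np.nanmean(np.abs(vals) < 2) > 0.85


class TestSloanNeutral:
    def test_predicted_occupancy_monotone_in_abundance(self):
        p = np.linspace(1e-5, 0.05, 50)
        pred = _predicted_occupancy(0.1, 10_000, p)
        assert (np.diff(pred) >= -1e-12).all()
        assert ((pred >= 0) & (pred <= 1)).all()

    def test_parameter_recovery_small(self):
        meta = simulate_metacommunity(300, seed=2)
        tab = simulate_neutral_counts(meta, 0.1, np.full(40, 8000), seed=3)
        fit = fit_sloan_neutral(tab)
        assert abs(fit.m_hat - 0.1) / 0.1 < 0.25
        assert fit.r_squared > 0.8

    def test_partition_fractions_sum_to_one(self):
        meta = simulate_metacommunity(200, seed=5)
        tab = simulate_neutral_counts(meta, 0.1, np.full(30, 5000), seed=6)
        fit = fit_sloan_neutral(tab)
        counts = fit.partition_counts()
        assert counts.sum() == len(fit.per_otu)

    def test_exact_prediction_classified_neutral(self):
        meta = simulate_metacommunity(200, seed=7)
        tab = simulate_neutral_counts(meta, 0.1, np.full(30, 5000), seed=8)
        fit = fit_sloan_neutral(tab)
        # wherever observed equals predicted exactly it must be neutral
        close = (fit.per_otu["occupancy"] - fit.per_otu["predicted"]).abs() < 1e-6
        assert (fit.per_otu.loc[close, "partition"] == "neutral").all()

    def test_consistent_presence_taxon_above(self):
        """A rare taxon guaranteed present everywhere exceeds the envelope."""
        meta = simulate_metacommunity(300, seed=9)
        tab = simulate_neutral_counts(meta, 0.02, np.full(50, 3000), seed=10)
        counts = tab.counts.copy()
        # overwrite one rare taxon: always detected at ~3 reads
        rare = np.argsort(meta)[5]
        counts[rare] = np.random.default_rng(0).poisson(3, size=50) + 1
        t2 = CountTable(counts, tab.otu_ids, tab.sample_ids)
        fit = fit_sloan_neutral(t2)
        assert fit.per_otu.loc[tab.otu_ids[rare], "partition"] == "above"

    def test_classify_partition_matches_table(self):
        meta = simulate_metacommunity(100, seed=1)
        tab = simulate_neutral_counts(meta, 0.1, np.full(20, 4000), seed=2)
        fit = fit_sloan_neutral(tab)
        labels = classify_partition(fit)
        above = fit.per_otu["occupancy"] > fit.per_otu["ci_high"]
        assert (labels[above] == "above").all()

    def test_saturated_occupancies_rejected(self):
        counts = np.ones((12, 5), dtype=int) * 3
        t = CountTable(counts, [f"O{i}" for i in range(12)], [f"s{j}" for j in range(5)])
        with pytest.raises(ValueError, match="gradient"):
            fit_sloan_neutral(t)
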