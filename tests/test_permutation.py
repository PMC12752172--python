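"""PERMANOVA decomposition, permutation p-values, stepwise db-RDA, and the
distance-vs-distance regression."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from microcore import (
    SampleMetadata,
    SimulationConfig,
    bray_curtis,
    distance_regression,
    permanova,
    simulate_dataset,
    simulate_metacommunity,
    simulate_neutral_counts,
    stepwise_dbrda_select,
)
from microcore.permutation import _gower_center, _hat


def _labels_meta(labels, ids):
    return SampleMetadata(pd.DataFrame({"g": labels}, index=ids), {})


class TestPermanova:
    def test_r2_decomposition_sums_to_one(self, small_dataset):
        dm = bray_curtis(small_dataset.table)
        res = permanova(dm, small_dataset.metadata, ["amendment", "Ca"], n_perm=49, seed=0)
        r2 = res.table["R2"]
        assert r2.drop("Total").sum() == pytest.approx(1.0, abs=1e-10)
        p = res.table["p"].dropna()
        assert ((p > 0) & (p <= 1)).all()
        assert (p >= 1 / 50).all()

    def test_perfect_separation_gives_extreme_p(self):
        # two tight clusters, labels matching them exactly; permutations that
        # merely relabel within clusters tie with the observed F, so the
        # attainable p floor is the fraction of partition-preserving
        # permutations (~0.8% for balanced 5+5), not 1/(n_perm+1)
        d = np.full((10, 10), 0.9)
        d[:5, :5] = 0.05
        d[5:, 5:] = 0.05
        np.fill_diagonal(d, 0.0)
        ids = [f"s{i}" for i in range(10)]
        dm = DistanceMatrix(d, ids=ids)
        meta = _labels_meta(["a"] * 5 + ["b"] * 5, ids)
        res = permanova(dm, meta, ["g"], n_perm=999, seed=1)
        p = res.table.at["g", "p"]
        assert 1 / 1000 <= p <= 0.03

    def test_exhaustive_oracle_n6(self):
        meta_p = simulate_metacommunity(50, seed=9)
        tab = simulate_neutral_counts(meta_p, 0.2, np.full(6, 2000), seed=10)
        dm = bray_curtis(tab)
        labels = ["a", "a", "a", "b", "b", "b"]
        g = _gower_center(dm.data)
        h0 = _hat(np.ones((6, 1)))
        hg = _hat(np.column_stack([np.ones(6), (np.array(labels) == "b").astype(float)]))
        sst = np.trace(g)

        def fstat(perm):
            gp = g[np.ix_(perm, perm)]
            return (np.sum(hg * gp) - np.sum(h0 * gp)) / ((sst - np.sum(hg * gp)) / 4)

        f_obs = fstat(list(range(6)))
        p_exhaustive = (
            sum(fstat(list(p)) >= f_obs - 1e-10 for p in permutations(range(6))) / 720
        )
        res = permanova(dm, _labels_meta(labels, tab.sample_ids), ["g"], n_perm=9999, seed=5)
        assert res.table.at["g", "p"] == pytest.approx(p_exhaustive, abs=0.02)

    def test_type_one_error_calibrated(self):
        """Random labels on neutral communities reject at ~alpha."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 60
        for rep in range(n_rep):
            meta_p = simulate_metacommunity(100, seed=500 + rep)
            tab = simulate_neutral_counts(meta_p, 0.1, np.full(20, 2000), seed=700 + rep)
            dm = bray_curtis(tab)
            labels = rng.choice(["a", "b"], size=20)
            res = permanova(dm, _labels_meta(labels, tab.sample_ids), ["g"], n_perm=99, seed=rep)
            rejections += res.table.at["g", "p"] <= 0.05
        # exact binomial 95% acceptance band around 0.05 at n=60: [0, 7]
        assert rejections <= 7

    def test_constant_term_rejected(self, small_dataset):
        dm = bray_curtis(small_dataset.table)
        meta = small_dataset.metadata
        meta.data["const"] = "x"
        with pytest.raises(ValueError, match="constant"):
            permanova(dm, meta, ["const"], n_perm=9, seed=0)


class TestStepwiseDbrda:
    def test_true_driver_selected(self):
        ds = simulate_dataset(
            SimulationConfig(n_taxa=150, n_samples=40, n_effect_taxa=25, effect_size=2.0, seed=3)
        )
        dm = bray_curtis(ds.table)
        sel = stepwise_dbrda_select(
            dm, ds.metadata, ["Ca", "LOI", "pH", "P", "K", "Na"], n_perm=99, seed=2
        )
        assert "Ca" in sel.selected or "LOI" in sel.selected

    def test_pure_noise_rarely_selects(self):
        hits = 0
        for rep in range(15):
            meta_p = simulate_metacommunity(80, seed=100 + rep)
            tab = simulate_neutral_counts(meta_p, 0.1, np.full(24, 2000), seed=200 + rep)
            dm = bray_curtis(tab)
            rng = np.random.default_rng(rep)
            md = SampleMetadata(
                pd.DataFrame(
                    {f"x{i}": rng.normal(size=24) for i in range(4)},
                    index=tab.sample_ids,
                ),
                {},
            )
            sel = stepwise_dbrda_select(
                dm, md, [f"x{i}" for i in range(4)], n_perm=99, seed=rep
            )
            hits += len(sel.selected)
        # expected ~ alpha_enter * candidates * reps = 0.05*4*15 = 3
        assert hits <= 9

    def test_empty_selection_allowed(self):
        meta_p = simulate_metacommunity(60, seed=0)
        tab = simulate_neutral_counts(meta_p, 0.1, np.full(15, 2000), seed=1)
        dm = bray_curtis(tab)
        md = SampleMetadata(
            pd.DataFrame({"noise": np.random.default_rng(0).normal(size=15)}, index=tab.sample_ids),
            {},
        )
        sel = stepwise_dbrda_select(dm, md, ["noise"], n_perm=99, seed=3)
        assert isinstance(sel.selected, list)
        assert len(sel.trace) >= 1


class TestDistanceRegression:
    def _dm(self, data, ids):
        return DistanceMatrix(data, ids=ids)

    def test_identity_and_scaling(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(8)]
        same = distance_regression(self._dm(d, ids), self._dm(d, ids))
        assert same.slope == pytest.approx(1.0, abs=1e-12)
        assert same.intercept == pytest.approx(0.0, abs=1e-12)
        half = distance_regression(self._dm(d, ids), self._dm(0.5 * d, ids))
        assert half.slope == pytest.approx(0.5, abs=1e-12)

    def test_unrelated_distances_give_flat_slope(self):
        rng = np.random.default_rng(1)
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(25)]
        d1 = squareform(pdist(rng.normal(size=(25, 3))))
        d2 = squareform(pdist(rng.normal(size=(25, 3))))
        res = distance_regression(self._dm(d1, ids), self._dm(d2, ids))
        assert abs(res.slope) < 2 * res.stderr

    def test_too_few_samples_rejected(self):
        ids = ["a", "b"]
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            distance_regression(self._dm(d, ids), self._dm(d, ids))
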