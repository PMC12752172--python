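"""Abundance-occupancy core selection: index, contribution curve, overlap."""

import numpy as np
import pandas as pd
import pytest

from microcore import (
    CountTable,
    bc_contribution_curve,
    core_overlap,
    fit_sloan_neutral,
    neutral_overlay,
    occupancy_index,
    occupancy_models,
    select_core,
    simulate_metacommunity,
    simulate_neutral_counts,
)


def _groups(table, mapping):
    return pd.Series(mapping)


class TestOccupancyIndex:
    def test_ubiquitous_and_absent_extremes(self):
        counts = np.array([[1, 1, 1, 1], [0, 0, 0, 0], [1, 0, 1, 0]])
        t = CountTable(counts, ["full", "empty", "half"], ["a1", "a2", "b1", "b2"])
        groups = _groups(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        r = occupancy_index(t, groups)
        assert r.at["full", "index"] == 1.0
        assert r.at["empty", "index"] == 0.0
        assert 0 < r.at["half", "index"] < 1

    def test_hand_computed_two_group_example(self):
        # present in 2/2 of group A and 1/2 of group B
        counts = np.array([[5, 3, 2, 0]])
        t = CountTable(counts, ["OTU_1"], ["a1", "a2", "b1", "b2"])
        groups = _groups(t, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        r = occupancy_index(t, groups)
        assert r.at["OTU_1", "site_occupancy"] == pytest.approx(0.75)
        assert r.at["OTU_1", "replication_consistency"] == pytest.approx(0.5)
        assert r.at["OTU_1", "index"] == pytest.approx(0.625)

    def test_index_invariant_to_per_sample_rescaling(self, tiny_table):
        groups = _groups(tiny_table, {s: "G" for s in tiny_table.sample_ids})
        r1 = occupancy_index(tiny_table, groups)
        scaled = CountTable(
            tiny_table.counts * np.array([1, 2, 3, 4, 5, 6]),
            tiny_table.otu_ids,
            tiny_table.sample_ids,
        )
        r2 = occupancy_index(scaled, groups)
        assert np.allclose(r1["index"], r2["index"])

    def test_ties_broken_by_abundance_then_id(self):
        counts = np.array([[1, 1], [9, 9], [9, 9]])
        t = CountTable(counts, ["zlow", "bbig", "abig"], ["s1", "s2"])
        r = occupancy_index(t, _groups(t, {"s1": "G", "s2": "G"}))
        # all indices equal (all present everywhere); order by abundance then id
        assert list(r.index[:2]) == ["abig", "bbig"]

    def test_missing_group_label_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="without a group"):
            occupancy_index(tiny_table, pd.Series({"S1": "A"}))


class TestContributionCurve:
    def test_endpoints(self, tiny_table):
        groups = _groups(tiny_table, {s: "G" for s in tiny_table.sample_ids})
        ranking = occupancy_index(tiny_table, groups)
        curve = bc_contribution_curve(tiny_table, list(ranking.index))
        e = curve["E"].to_numpy()
        assert e[-1] == pytest.approx(1.0, abs=1e-10)
        assert (np.diff(e) >= -1e-10).all()
        assert np.allclose(curve["C"], 1 - curve["E"])

    def test_single_driver_table(self):
        counts = np.array([[10, 0], [5, 5], [3, 3]])
        t = CountTable(counts, ["driver", "flat1", "flat2"], ["s1", "s2"])
        curve = bc_contribution_curve(t, ["driver", "flat1", "flat2"])
        assert curve["E"].iloc[0] == pytest.approx(1.0)

    def test_unknown_otu_in_ranking_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="unknown"):
            bc_contribution_curve(tiny_table, ["nope"])


class TestSelectCore:
    def _fake(self, e_values):
        otus = [f"O{i}" for i in range(len(e_values))]
        curve = pd.DataFrame({"otu": otus, "E": e_values, "C": 1 - np.asarray(e_values)})
        curve.index = pd.RangeIndex(1, len(otus) + 1, name="k")
        ranking = pd.DataFrame(
            {"index": np.linspace(1, 0.5, len(otus)), "occupancy": 1.0},
            index=otus,
        )
        return ranking, curve

    def test_stopping_rule_example(self):
        ranking, curve = self._fake([0.50, 0.80, 0.95, 0.96, 0.965])
        res = select_core(ranking, curve, delta=0.02)
        assert res.stopping_rank == 3
        assert res.core == ["O0", "O1", "O2"]

    def test_all_increments_large_keeps_everything(self):
        ranking, curve = self._fake([0.2, 0.5, 0.8, 1.0])
        res = select_core(ranking, curve, delta=0.02)
        assert res.core == ["O0", "O1", "O2", "O3"]

    def test_at_least_one_taxon(self):
        ranking, curve = self._fake([0.99, 0.995, 1.0])
        res = select_core(ranking, curve, delta=0.02)
        assert res.stopping_rank == 1

    def test_decreasing_curve_rejected(self):
        ranking, curve = self._fake([0.5, 0.4, 1.0])
        with pytest.raises(ValueError, match="non-decreasing"):
            select_core(ranking, curve)

    def test_dominant_structured_taxa_recovered(self):
        """Three taxa carrying ~all between-sample variation form the core."""
        rng = np.random.default_rng(0)
        n = 12
        flat = np.tile(rng.integers(50, 60, size=(20, 1)), (1, n))
        drivers = rng.integers(0, 2, size=(3, n)) * 2000
        counts = np.vstack([drivers, flat])
        ids = [f"core{i}" for i in range(3)] + [f"bg{i}" for i in range(20)]
        t = CountTable(counts, ids, [f"s{j}" for j in range(n)])
        groups = _groups(t, {s: "G" for s in t.sample_ids})
        ranking = occupancy_index(t, groups)
        # rank by contribution: put drivers first explicitly
        order = [i for i in ids if i.startswith("core")] + [
            i for i in ids if i.startswith("bg")
        ]
        curve = bc_contribution_curve(t, order)
        res = select_core(ranking, curve, delta=0.02)
        assert set(res.core) >= {"core0", "core1", "core2"}


class TestOccupancyModelsAndOverlap:
    def test_identical_composition_identical_cores(self, small_dataset):
        cores = occupancy_models(
            small_dataset.table, small_dataset.metadata, model_var="amendment"
        )
        assert "all" in cores
        again = occupancy_models(
            small_dataset.table, small_dataset.metadata, model_var="amendment"
        )
        for k in cores:
            assert cores[k].core == again[k].core  # seedless determinism

    def test_level_specific_taxon(self):
        counts = np.array(
            [[10, 30, 0, 0], [5, 5, 5, 5], [800, 900, 1000, 1100]]
        )
        t = CountTable(counts, ["only_a", "everywhere", "big"], ["a1", "a2", "b1", "b2"])
        meta = pd.DataFrame(
            {"amendment": ["FYM", "FYM", "None", "None"], "farm_id": ["f1", "f2", "f1", "f2"]},
            index=t.sample_ids,
        )
        from microcore import SampleMetadata

        md = SampleMetadata(meta, {"amendment": ("None", "FYM", "Digestate", "Slurry")})
        cores = occupancy_models(t, md, model_var="amendment", delta=0.001)
        assert "only_a" in cores["FYM"].core
        assert "only_a" not in cores["None"].core

    def test_overlap_set_arithmetic(self):
        a = {"A", "B", "C"}
        b = {"B", "C", "D"}
        res = core_overlap({"x": a, "y": b})
        assert res.pairwise[("x", "y")] == pytest.approx(50.0)
        assert res.venn["x"] == 1 and res.venn["y"] == 1 and res.venn["x+y"] == 2
        identical = core_overlap({"x": a, "y": set(a)})
        assert identical.total_sharing == pytest.approx(100.0)
        disjoint = core_overlap({"x": a, "y": {"Z"}})
        assert disjoint.total_sharing == 0.0

    def test_neutral_overlay_counts(self):
        meta = simulate_metacommunity(150, seed=1)
        tab = simulate_neutral_counts(meta, 0.1, np.full(20, 4000), seed=2)
        fit = fit_sloan_neutral(tab)
        groups = pd.Series({s: "G" for s in tab.sample_ids})
        keep = [o for o, tot in zip(tab.otu_ids, tab.counts.sum(axis=1)) if tot > 0]
        sub = tab.select_otus(keep)
        ranking = occupancy_index(sub, groups)
        curve = bc_contribution_curve(sub, list(ranking.index))
        res = select_core(ranking, curve)
        overlay = neutral_overlay(res, fit)
        assert len(overlay) == len(res.core)
        assert set(overlay.unique()) <= {"above", "neutral", "below"}
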