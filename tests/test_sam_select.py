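import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ileum_integrate.sam_select import (
    SamConfig,
    estimate_s0,
    pairwise_union,
    sam_fdr,
    sam_statistic,
)


class TestSamStatistic:
    def test_hand_computed_example(self):
        values = np.array([[1, 2, 3, 4, 5, 6.0]])
        d, s, fold = sam_statistic(values, ["A"] * 3 + ["B"] * 3, s0=0.0)
        np.testing.assert_allclose(s, np.sqrt(4 / 6.0))
        np.testing.assert_allclose(d, 3.0 / np.sqrt(4 / 6.0))
        np.testing.assert_allclose(fold, 8.0)  # 2**(5-2)

    def test_identical_groups_give_zero_d_unit_fold(self):
        values = np.array([[1, 2, 3, 1, 2, 3.0]])
        d, _, fold = sam_statistic(values, ["A"] * 3 + ["B"] * 3, s0=0.0)
        assert d[0] == 0.0
        assert fold[0] == 1.0

    def test_equals_pooled_t_when_s0_zero(self, random_matrix):
        values, labels = random_matrix
        d, _, _ = sam_statistic(values, labels, s0=0.0)
        a = values.loc[:, np.array(labels) == "A"]
        b = values.loc[:, np.array(labels) == "B"]
        t = stats.ttest_ind(b, a, axis=1, equal_var=True).statistic
        np.testing.assert_allclose(d, t, atol=1e-10)

    def test_antisymmetric_under_class_swap(self, random_matrix):
        values, labels = random_matrix
        d_ab, _, _ = sam_statistic(values, labels, s0=0.1, classes=("A", "B"))
        d_ba, _, _ = sam_statistic(values, labels, s0=0.1, classes=("B", "A"))
        np.testing.assert_allclose(d_ab, -d_ba, atol=1e-12)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sam_statistic(np.ones((1, 3)), ["A", "B", "B"])


class TestEstimateS0:
    def test_degenerate_scales_give_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            s0 = estimate_s0(np.ones(100), np.full(100, 2.0))
        assert s0 == 0.0

    def test_fixed_percentile_is_quantile(self, rng):
        s = rng.uniform(0.5, 2.0, size=500)
        s0 = estimate_s0(np.zeros(500), s, "fixed_percentile", percentile=0.5)
        assert s0 == pytest.approx(np.median(s))

    def test_reproducible_on_simulated_matrix(self, rng):
        diff = rng.normal(size=1000)
        s = rng.gamma(2.0, 0.3, size=1000)
        assert estimate_s0(diff, s) == estimate_s0(diff, s)


class TestSamFdr:
    def test_exhaustive_enumeration_for_small_balanced_design(self, rng):
        values = pd.DataFrame(rng.normal(size=(30, 6)))
        labels = ["A"] * 3 + ["B"] * 3
        cfg1 = SamConfig(n_permutations=200, seed=1)
        cfg2 = SamConfig(n_permutations=200, seed=999)
        r1 = sam_fdr(values, labels, cfg1)
        r2 = sam_fdr(values, labels, cfg2)
        assert r1.exhaustive and r1.n_permutations_used == 20
        pd.testing.assert_frame_equal(r1.table, r2.table)  # seed-independent

    def test_empty_call_fdr_zero_convention(self, rng):
        values = pd.DataFrame(rng.normal(size=(40, 12)))
        labels = ["A"] * 6 + ["B"] * 6
        res = sam_fdr(values, labels, SamConfig(n_permutations=50, seed=3))
        empty = res.delta_table[res.delta_table["n_called"] == 0]
        assert (empty["fdr"] == 0).all()

    def test_planted_shift_false_call_proportion(self):
        # 100 of 1000 probes shifted by 2 sd, 10 vs 10; observed FDP at the
        # q<=0.05 cutoff stays modest across replicates (fold gate off)
        n_rep, fdps = 20, []
        for rep in range(n_rep):
            rng = np.random.default_rng(7 + rep)
            values = rng.normal(size=(1000, 20))
            values[:100, 10:] += 2.0
            labels = ["A"] * 10 + ["B"] * 10
            cfg = SamConfig(
                fold_change_min=1.0, n_permutations=100, seed=7 + rep
            )
            res = sam_fdr(pd.DataFrame(values), labels, cfg)
            called = res.table.index[res.table["q"] <= 0.05]
            if len(called) == 0:
                continue
            false_calls = sum(1 for i in called if i >= 100)
            fdps.append(false_calls / len(called))
        assert np.mean(fdps) <= 0.15

    def test_null_call_rate_controlled(self):
        # fraction of probes called at q<=0.05 on label-permuted null data
        rates = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            values = pd.DataFrame(rng.normal(size=(300, 16)))
            labels = ["A"] * 8 + ["B"] * 8
            cfg = SamConfig(fold_change_min=1.0, n_permutations=100, seed=rep)
            res = sam_fdr(values, labels, cfg)
            rates.append((res.table["q"] <= 0.05).mean())
        assert np.mean(rates) <= 0.10

    def test_q_monotone_from_the_extremes(self, rng):
        values = pd.DataFrame(rng.normal(size=(200, 16)))
        values.iloc[:40, 8:] += 1.5
        labels = ["A"] * 8 + ["B"] * 8
        # fold gate off: the slab calling rule alone orders q by |d - dbar|
        cfg = SamConfig(fold_change_min=1.0, n_permutations=100, seed=5)
        res = sam_fdr(values, labels, cfg)
        t = res.table.sort_values("d")
        pos = t[t["d"] > 0]["q"].to_numpy()
        neg = t[t["d"] < 0]["q"].to_numpy()
        # moving outward (larger |d|) can only tighten q
        assert (np.diff(pos) <= 1e-12).all()
        assert (np.diff(neg) >= -1e-12).all()

    def test_calls_respect_fold_and_fdr_gates(self, rng):
        values = pd.DataFrame(rng.normal(size=(300, 16)))
        values.iloc[:50, 8:] += 2.0
        labels = ["A"] * 8 + ["B"] * 8
        cfg = SamConfig(fold_change_min=1.5, fdr_max=0.05, n_permutations=100, seed=2)
        res = sam_fdr(values, labels, cfg)
        called = res.table[res.table["call"] != 0]
        if len(called):
            fold = called["fold_change"].to_numpy()
            assert ((fold >= 1.5 - 1e-9) | (fold <= 1 / 1.5 + 1e-9)).all()
            assert (called["q"] <= cfg.fdr_max + 1e-12).all()


class TestPairwiseUnion:
    def test_small_enumeration(self):
        union, venn = pairwise_union({"c1": {"a", "b"}, "c2": {"b", "c"}, "c3": set()})
        assert union == {"a", "b", "c"}
        assert venn[("c1",)] == 1
        assert venn[("c2",)] == 1
        assert venn[("c1", "c2")] == 1
        assert venn[("c1", "c2", "c3")] == 0

    def test_identical_sets_all_in_triple_overlap(self):
        s = {"x", "y", "z"}
        union, venn = pairwise_union({"a": s, "b": s, "c": s})
        assert union == s
        assert venn[("a", "b", "c")] == 3
        assert venn[("a",)] == 0

    def test_disjoint_sets_additive(self):
        union, _ = pairwise_union(
            {"a": {1, 2}, "b": {3, 4, 5}, "c": {6, 7, 8, 9}}
        )
        assert len(union) == 9
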