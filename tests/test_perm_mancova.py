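import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ileum_integrate.perm_mancova import (
    AliasedTermError,
    DesignVariable,
    permuted_responses,
    sequential_mancova,
    stepwise_select,
)


def _factor(labels, name="group"):
    return DesignVariable(name, "categorical", pd.Series(labels))


def _covariate(values, name="x"):
    return DesignVariable(name, "continuous", pd.Series(np.asarray(values, float)))


class TestDesignVariable:
    def test_categorical_df_is_levels_minus_one(self):
        v = _factor(["a", "b", "c", "a"])
        assert v.df == 2
        assert v.design_columns().shape == (4, 2)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            DesignVariable("x", "continuous", pd.Series([1.0, np.nan]))

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            _factor(["a", "a", "a"])


class TestSequentialMancova:
    def test_hand_anova_with_exhaustive_permutation(self):
        y = np.array([1, 2, 3, 4, 5, 6.0])
        res = sequential_mancova(y, [_factor(["A"] * 3 + ["B"] * 3)], exhaustive=True)
        row = res.table.iloc[0]
        assert row["ss"] == pytest.approx(13.5)
        assert res.residual_ss == pytest.approx(4.0)
        assert row["pseudo_f"] == pytest.approx(13.5)
        assert row["p"] == pytest.approx(0.1)  # 2 of 20 distinct assignments

    def test_univariate_pseudo_f_equals_classical_anova(self, rng):
        for _ in range(20):
            y = rng.normal(size=18)
            labels = rng.choice(["a", "b", "c"], size=18)
            while len(set(labels)) < 3:
                labels = rng.choice(["a", "b", "c"], size=18)
            res = sequential_mancova(y, [_factor(labels)], n_perm=9, seed=0)
            f_oracle = stats.f_oneway(*(y[labels == g] for g in set(labels))).statistic
            assert res.table["pseudo_f"].iloc[0] == pytest.approx(f_oracle, abs=1e-10)

    def test_multivariate_pseudo_f_matches_skbio_permanova(self, rng):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        y = rng.normal(size=(20, 4))
        labels = ["a"] * 10 + ["b"] * 10
        res = sequential_mancova(y, [_factor(labels)], n_perm=9, seed=0)
        dm = skbio_dist.DistanceMatrix(
            np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1)),
            ids=[str(i) for i in range(20)],
        )
        oracle = skbio_dist.permanova(dm, grouping=labels, permutations=9)
        assert res.table["pseudo_f"].iloc[0] == pytest.approx(
            oracle["test statistic"], abs=1e-8
        )

    def test_ss_decomposition_exact(self, rng):
        y = rng.normal(size=(30, 5))
        terms = [
            _factor(rng.choice(["a", "b", "c"], 30), "f1"),
            _covariate(rng.normal(size=30), "x1"),
            _factor(rng.choice(["u", "v"], 30), "f2"),
        ]
        res = sequential_mancova(y, terms, n_perm=9, seed=1)
        assert res.table["ss"].sum() + res.residual_ss == pytest.approx(
            res.total_ss, abs=1e-8
        )
        assert ((res.table["r2"] >= 0) & (res.table["r2"] <= 1)).all()

    def test_sequential_ss_invariant_to_later_term_order(self, rng):
        y = rng.normal(size=(25, 3))
        a = _covariate(rng.normal(size=25), "a")
        b = _covariate(rng.normal(size=25), "b")
        c = _covariate(rng.normal(size=25), "c")
        r1 = sequential_mancova(y, [a, b, c], n_perm=9, seed=0)
        r2 = sequential_mancova(y, [a, c, b], n_perm=9, seed=0)
        assert r1.table.loc["a", "ss"] == pytest.approx(r2.table.loc["a", "ss"], abs=1e-9)

    def test_pseudo_f_and_p_invariant_to_response_scaling(self, rng):
        y = rng.normal(size=(20, 4))
        term = [_factor(["a"] * 10 + ["b"] * 10)]
        r1 = sequential_mancova(y, term, n_perm=99, seed=7)
        r2 = sequential_mancova(y / np.log(10), term, n_perm=99, seed=7)
        assert r1.table["pseudo_f"].iloc[0] == pytest.approx(
            r2.table["pseudo_f"].iloc[0]
        )
        assert r1.table["p"].iloc[0] == r2.table["p"].iloc[0]

    def test_p_never_zero(self, rng):
        y = rng.normal(size=(20, 3))
        y[10:] += 50.0  # overwhelming effect
        res = sequential_mancova(
            y, [_factor(["a"] * 10 + ["b"] * 10)], n_perm=99, seed=0
        )
        # the (1 + hits)/(1 + n_perm) estimator is bounded away from zero
        assert 1 / 100 <= res.table["p"].iloc[0] <= 0.05

    def test_aliased_term_rejected_by_name(self, rng):
        y = rng.normal(size=(12, 2))
        x = rng.normal(size=12)
        with pytest.raises(AliasedTermError, match="x_copy"):
            sequential_mancova(
                y, [_covariate(x, "x"), _covariate(x, "x_copy")], n_perm=9, seed=0
            )

    def test_too_many_terms_rejected(self, rng):
        y = rng.normal(size=(5, 2))
        terms = [_covariate(rng.normal(size=5), f"x{i}") for i in range(5)]
        with pytest.raises(ValueError, match="support"):
            sequential_mancova(y, terms, n_perm=9, seed=0)


class TestPermutationSchemes:
    def test_identity_permutation_reproduces_f(self, rng):
        y = rng.normal(size=(10, 3))
        perms = np.arange(10)[None, :]
        for scheme in ("raw", "freedman_lane"):
            h0 = np.full((10, 10), 0.1)
            ystar = permuted_responses(y, perms, scheme, h_reduced=h0)
            np.testing.assert_allclose(ystar[0], y, atol=1e-12)

    def test_schemes_coincide_for_intercept_only_reduced_model(self, rng):
        y = rng.normal(size=(12, 4))
        perms = np.array([rng.permutation(12) for _ in range(5)])
        h0 = np.full((12, 12), 1 / 12)
        raw = permuted_responses(y, perms, "raw")
        fl = permuted_responses(y, perms, "freedman_lane", h_reduced=h0)
        np.testing.assert_allclose(raw, fl, atol=1e-10)

    def test_unknown_scheme_rejected(self, rng):
        with pytest.raises(ValueError, match="scheme"):
            permuted_responses(rng.normal(size=(4, 2)), np.arange(4)[None], "bootstrap")

    def test_freedman_lane_size_with_strong_covariate(self):
        # null term tested alongside a covariate that drives the response:
        # rejection rate at nominal 0.05 stays within the binomial band
        n, n_sim, n_perm = 30, 200, 199
        rejections = 0
        for i in range(n_sim):
            rng = np.random.default_rng(5000 + i)
            x_strong = rng.normal(size=n)
            y = np.outer(x_strong, [2.0, -1.0, 1.5]) + rng.normal(size=(n, 3))
            terms = [
                _covariate(x_strong, "strong"),
                _covariate(rng.normal(size=n), "null_term"),
            ]
            res = sequential_mancova(
                y, terms, n_perm=n_perm, seed=i, scheme="freedman_lane"
            )
            rejections += int(res.table.loc["null_term", "p"] <= 0.05)
        assert 0.02 <= rejections / n_sim <= 0.09


class TestStepwiseSelect:
    def test_collinear_candidate_never_enters(self, rng):
        n = 30
        x = rng.normal(size=n)
        y = np.outer(x, [1.0, 0.5]) + 0.1 * rng.normal(size=(n, 2))
        cands = [_covariate(x, "x"), _covariate(x, "x_copy")]
        trace, final = stepwise_select(y, cands, n_perm=99, seed=3)
        assert trace.entries["term"].tolist() == ["x"]
        assert final is not None

    def test_planted_predictor_enters_first(self, rng):
        n = 40
        x = rng.normal(size=n)
        y = np.outer(x, [1.0, -1.0, 0.5]) + 0.3 * rng.normal(size=(n, 3))
        cands = [_covariate(rng.normal(size=n), f"noise{i}") for i in range(6)]
        cands.append(_covariate(x, "planted"))
        trace, _ = stepwise_select(y, cands, n_perm=199, seed=4)
        assert trace.entries["term"].iloc[0] == "planted"

    def test_forced_first_enters_unconditionally(self, rng):
        y = rng.normal(size=(24, 3))
        cands = [
            _covariate(rng.normal(size=24), "a"),
            _covariate(rng.normal(size=24), "b"),
        ]
        trace, final = stepwise_select(
            y, cands, n_perm=49, seed=0, forced_first=["b"]
        )
        assert trace.entries["term"].iloc[0] == "b"
        assert bool(trace.entries["forced"].iloc[0])
        assert final.table.index[0] == "b"

    def test_unknown_forced_variable_rejected(self, rng):
        y = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="zz"):
            stepwise_select(
                y, [_covariate(rng.normal(size=10), "a")], forced_first=["zz"],
                n_perm=9, seed=0,
            )

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            stepwise_select(rng.normal(size=(10, 2)), [], n_perm=9, seed=0)

    def test_max_steps_caps_free_entries(self, rng):
        n = 40
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = np.outer(x1, [2.0, 1.0]) + np.outer(x2, [1.0, -2.0])
        y += 0.1 * rng.normal(size=(n, 2))
        cands = [_covariate(x1, "x1"), _covariate(x2, "x2")]
        trace, _ = stepwise_select(y, cands, n_perm=99, seed=0, max_steps=1)
        assert len(trace.entries) == 1
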