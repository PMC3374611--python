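import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from ileum_integrate.calibration import adjusted_rand_index
from ileum_integrate.gene_clustering import (
    cluster_centroids,
    concentration_check,
    correlation_dissimilarity,
    r2_curve,
    ward_cluster,
    ward_tree,
)


def _frame(values):
    arr = np.asarray(values, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"p{i}" for i in range(arr.shape[0])],
        columns=[f"s{i}" for i in range(arr.shape[1])],
    )


class TestCorrelationDissimilarity:
    def test_self_zero_negation_two(self):
        m = _frame([[1, 2, 3], [-1, -2, -3]])
        d = correlation_dissimilarity(m)
        assert d.iloc[0, 0] == 0.0
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_hand_computed_pair(self):
        d = correlation_dissimilarity(_frame([[1, 2, 3], [1, 2, 4]]))
        r = np.corrcoef([1, 2, 3], [1, 2, 4])[0, 1]
        assert d.iloc[0, 1] == pytest.approx(1 - r)
        assert d.iloc[0, 1] == pytest.approx(0.01801949, abs=1e-6)

    def test_invariant_to_positive_affine_rescaling(self, rng):
        base = rng.normal(size=(10, 8))
        scaled = base * rng.uniform(0.5, 3.0, size=(10, 1)) + rng.normal(size=(10, 1))
        d1 = correlation_dissimilarity(_frame(base))
        d2 = correlation_dissimilarity(_frame(scaled))
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-10)

    def test_zero_variance_probe_named(self):
        m = _frame([[1, 1, 1], [1, 2, 3]])
        with pytest.raises(ValueError, match="p0"):
            correlation_dissimilarity(m)


class TestWardCluster:
    def test_k_equals_n_gives_singletons(self, rng):
        m = _frame(rng.normal(size=(8, 5)))
        d = correlation_dissimilarity(m)
        assignment, _ = ward_cluster(d, k=8)
        assert assignment.nunique() == 8

    def test_k_out_of_range_rejected(self, rng):
        d = correlation_dissimilarity(_frame(rng.normal(size=(5, 4))))
        with pytest.raises(ValueError, match="k must be"):
            ward_cluster(d, k=6)

    def test_recovers_noisy_template_structure(self):
        rng = np.random.default_rng(11)
        templates = np.eye(3).repeat(4, axis=1)  # 3 orthogonal 12-sample profiles
        probes = np.vstack(
            [t + rng.normal(0, 0.05, size=(30, 12)) for t in templates]
        )
        truth = np.repeat([0, 1, 2], 30)
        d = correlation_dissimilarity(_frame(probes))
        assignment, _ = ward_cluster(d, k=3)
        assert adjusted_rand_index(truth, assignment.to_numpy()) == 1.0
        # cross-check our ARI against scikit-learn's
        sk = pytest.importorskip("sklearn.metrics")
        assert sk.adjusted_rand_score(truth, assignment.to_numpy()) == 1.0

    def test_equals_euclidean_ward_on_standardized_profiles(self, rng):
        m = _frame(rng.normal(size=(15, 10)))
        d = correlation_dissimilarity(m)
        tree = ward_tree(d, "sqrt2d")
        z = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        oracle = linkage(z, method="ward")
        np.testing.assert_allclose(tree[:, 2], oracle[:, 2], atol=1e-8)

    def test_merge_heights_nondecreasing(self, rng):
        d = correlation_dissimilarity(_frame(rng.normal(size=(20, 6))))
        tree = ward_tree(d)
        assert (np.diff(tree[:, 2]) >= -1e-12).all()


class TestR2Curve:
    def test_endpoints_and_monotonicity(self, rng):
        m = _frame(rng.normal(size=(12, 6)))
        d = correlation_dissimilarity(m)
        tree = ward_tree(d)
        curve = r2_curve(m, tree, range(1, 13))
        assert curve[1] == pytest.approx(0.0, abs=1e-12)
        assert curve[12] == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(curve.to_numpy()) >= -1e-10).all()


class TestClusterCentroids:
    def test_singleton_cluster_is_the_profile(self):
        m = _frame([[1, 2, 3], [7, 8, 9]])
        assignment = pd.Series([1, 2], index=m.index)
        for method in ("median", "mean", "pc1"):
            cent = cluster_centroids(m, assignment, method)
            if method == "pc1":
                r = np.corrcoef(cent.loc[1], m.iloc[0])[0, 1]
                assert abs(r) == pytest.approx(1.0)
            else:
                np.testing.assert_allclose(cent.loc[1], m.iloc[0])

    def test_elementwise_median(self):
        m = _frame([[0, 0], [1, 1], [5, 5]])
        assignment = pd.Series([1, 1, 1], index=m.index)
        np.testing.assert_allclose(
            cluster_centroids(m, assignment, "median").loc[1], [1, 1]
        )

    def test_pc1_on_rank_one_cluster_matches_mean_profile(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0])
        m = _frame(np.outer([1.0, 2.0, 0.5], profile))
        assignment = pd.Series([1, 1, 1], index=m.index)
        cent = cluster_centroids(m, assignment, "pc1")
        meanp = m.mean(axis=0).to_numpy()
        r = np.corrcoef(cent.loc[1], meanp)[0, 1]
        assert r == pytest.approx(1.0)

    def test_methods_agree_up_to_scale_on_rank_one(self, rng):
        profile = rng.normal(size=6)
        m = _frame(np.outer(rng.uniform(0.5, 2.0, 5), profile))
        assignment = pd.Series(np.ones(5, dtype=int), index=m.index)
        med = cluster_centroids(m, assignment, "median").loc[1]
        pc1 = cluster_centroids(m, assignment, "pc1").loc[1]
        assert abs(np.corrcoef(med, pc1)[0, 1]) == pytest.approx(1.0)

    def test_incomplete_assignment_rejected(self):
        m = _frame([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="missing"):
            cluster_centroids(m, pd.Series([1], index=["p0"]), "mean")


class TestConcentrationCheck:
    def test_containment_not_flagged(self):
        probes = [f"p{i}" for i in range(10)]
        coarse = pd.Series([1] * 10, index=probes)
        fine = pd.Series([3] * 10, index=probes)
        out = concentration_check(fine, coarse)
        assert out.loc[1, "top_fraction"] == 1.0
        assert not out.loc[1, "flagged"]

    def test_uniform_spread_flagged(self):
        probes = [f"p{i}" for i in range(10)]
        coarse = pd.Series([1] * 10, index=probes)
        fine = pd.Series(range(10), index=probes)
        out = concentration_check(fine, coarse, top=2, threshold=0.40)
        assert out.loc[1, "top_fraction"] == pytest.approx(0.2)
        assert out.loc[1, "flagged"]

    def test_matches_brute_force_contingency(self, rng):
        probes = [f"p{i}" for i in range(60)]
        coarse = pd.Series(rng.integers(1, 5, 60), index=probes)
        fine = pd.Series(rng.integers(1, 9, 60), index=probes)
        out = concentration_check(fine, coarse, top=2)
        for lab in out.index:
            members = coarse.index[coarse == lab]
            tab = {}
            for p in members:
                tab[fine[p]] = tab.get(fine[p], 0) + 1
            expected = sum(sorted(tab.values(), reverse=True)[:2]) / len(members)
            assert out.loc[lab, "top_fraction"] == pytest.approx(expected)

    def test_disjoint_probe_sets_rejected(self):
        with pytest.raises(ValueError, match="share"):
            concentration_check(
                pd.Series([1], index=["a"]), pd.Series([1], index=["b"])
            )
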