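import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from stdeconv import (
    ClusteringComparison,
    ProportionMatrix,
    ValidationError,
    adjusted_rand_index,
    cluster_proportions,
    evaluate_dataset,
    js_divergence,
    pearson,
    purity,
    rmse,
)


def _purity_oracle(true, pred):
    """Majority-vote transcription: sum over clusters of the modal class."""
    total = 0
    for c in set(pred):
        members = [t for t, p in zip(true, pred) if p == c]
        total += max(members.count(v) for v in set(members))
    return total / len(true)


def _ari_pair_counting_oracle(true, pred):
    """ARI from explicit pair agreement counts."""
    n = len(true)
    a = b = c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        same_t = true[i] == true[j]
        same_p = pred[i] == pred[j]
        a += same_t and same_p
        b += same_t and not same_p
        c += not same_t and same_p
        d += not same_t and not same_p
    total = a + b + c + d
    expected = (a + b) * (a + c) / total
    max_index = 0.5 * ((a + b) + (a + c))
    if max_index == expected:
        return 1.0
    return (a - expected) / (max_index - expected)


class TestRMSE:
    def test_identity_is_zero(self, rng):
        p = rng.dirichlet(np.ones(3), size=4)
        assert rmse(p, p) == 0.0

    def test_uniform_vs_one_hot(self):
        pred = np.full((1, 4), 0.25)
        truth = np.array([[1.0, 0, 0, 0]])
        assert rmse(pred, truth) == pytest.approx(np.sqrt(0.1875), abs=1e-9)

    def test_one_hot_worst_case_bound(self, rng):
        k = 5
        for _ in range(50):
            pred = np.eye(k)[rng.integers(k, size=10)]
            truth = np.eye(k)[rng.integers(k, size=10)]
            assert rmse(pred, truth) <= np.sqrt(2 / k) + 1e-12

    def test_column_permutation_invariance(self, rng):
        p = rng.dirichlet(np.ones(4), size=6)
        q = rng.dirichlet(np.ones(4), size=6)
        perm = rng.permutation(4)
        assert rmse(p, q) == pytest.approx(rmse(p[:, perm], q[:, perm]))


class TestClusterProportions:
    def test_exact_one_hot_rows_cluster_purely(self):
        values = np.eye(3)[np.repeat(np.arange(3), 5)]
        labels = cluster_proportions(values, k=3, seed=0)
        truth = np.repeat(np.arange(3), 5)
        cmp = ClusteringComparison.from_labels(truth, labels)
        assert purity(cmp) == 1.0

    def test_same_seed_same_labels(self, rng):
        values = rng.dirichlet(np.ones(3), size=30)
        a = cluster_proportions(values, 3, seed=5)
        b = cluster_proportions(values, 3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_bad_k_rejected(self, rng):
        with pytest.raises(ValidationError):
            cluster_proportions(rng.dirichlet(np.ones(2), size=5), 0)


class TestARI:
    def test_identical_labelings_give_one(self):
        cmp = ClusteringComparison.from_labels([1, 1, 2, 2, 3], [5, 5, 6, 6, 7])
        assert adjusted_rand_index(cmp) == pytest.approx(1.0)

    def test_hand_derived_cross_case(self):
        cmp = ClusteringComparison.from_labels([1, 1, 2, 2], [1, 2, 1, 2])
        assert adjusted_rand_index(cmp) == pytest.approx(-0.5)

    def test_invariant_to_cluster_renaming(self, rng):
        t = rng.integers(0, 3, size=20)
        p = rng.integers(0, 3, size=20)
        renamed = np.array([{0: 7, 1: 5, 2: 9}[v] for v in p])
        assert adjusted_rand_index(
            ClusteringComparison.from_labels(t, p)
        ) == pytest.approx(adjusted_rand_index(ClusteringComparison.from_labels(t, renamed)))

    def test_matches_pair_counting_and_sklearn_oracles(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 7))
            t = rng.integers(0, 3, size=n)
            p = rng.integers(0, 3, size=n)
            if len(set(t)) == 1 and len(set(p)) == 1:
                continue
            ours = adjusted_rand_index(ClusteringComparison.from_labels(t, p))
            assert ours == pytest.approx(_ari_pair_counting_oracle(list(t), list(p)), abs=1e-10)
            assert ours == pytest.approx(adjusted_rand_score(t, p), abs=1e-10)


class TestPurity:
    def test_perfect_clusters_give_one(self):
        cmp = ClusteringComparison.from_labels(["A", "A", "B"], [0, 0, 1])
        assert purity(cmp) == 1.0

    def test_hand_case_five_sixths(self):
        true = ["A", "A", "B", "B", "B", "B"]
        pred = [0, 0, 0, 1, 1, 1]  # clusters {A,A,B} and {B,B,B}
        cmp = ClusteringComparison.from_labels(true, pred)
        assert purity(cmp) == pytest.approx(5 / 6)

    def test_single_cluster_balanced_classes(self):
        cmp = ClusteringComparison.from_labels([0, 1, 2, 0, 1, 2], [9] * 6)
        assert purity(cmp) == pytest.approx(1 / 3)

    def test_matches_majority_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 8))
            t = list(rng.integers(0, 3, size=n))
            p = list(rng.integers(0, 3, size=n))
            cmp = ClusteringComparison.from_labels(t, p)
            assert purity(cmp) == pytest.approx(_purity_oracle(t, p), abs=1e-12)


class TestJSDivergence:
    def test_identical_is_zero(self, rng):
        p = rng.dirichlet(np.ones(4))
        assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_attains_ln2(self):
        assert js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.log(2))

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            v = js_divergence(p, q)
            assert v == pytest.approx(js_divergence(q, p), abs=1e-12)
            assert 0.0 <= v <= np.log(2) + 1e-12

    def test_base2_rescales_to_unit_interval(self):
        assert js_divergence([1.0, 0.0], [0.0, 1.0], base2=True) == pytest.approx(1.0)

    def test_renormalization_warns(self):
        with pytest.warns(UserWarning, match="renormalized"):
            js_divergence([0.5, 0.4], [0.5, 0.5])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            js_divergence([-0.1, 1.1], [0.5, 0.5])


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        p = rng.normal(size=6)
        assert pearson(p, p) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        p = rng.normal(size=8)
        assert pearson(p, 2 * p + 3) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(-1.0)

    def test_zero_variance_returns_nan(self):
        assert np.isnan(pearson([1.0, 1.0, 1.0], [0.2, 0.5, 0.3]))


class TestEvaluateDataset:
    def test_perfect_prediction(self, rng):
        values = rng.dirichlet(np.ones(3), size=12)
        pm = ProportionMatrix(values, ["a", "b", "c"])
        layers = np.argmax(values, axis=1)
        report = evaluate_dataset(pm, pm, true_layer_labels=layers)
        assert report["rmse"] == 0.0
        assert report["mean_js"] == pytest.approx(0.0, abs=1e-12)
        assert report["mean_pearson"] == pytest.approx(1.0)

    def test_report_columns(self, rng):
        values = rng.dirichlet(np.ones(3), size=6)
        pm = ProportionMatrix(values, ["a", "b", "c"])
        bare = evaluate_dataset(pm, pm)
        assert set(bare) == {"rmse", "mean_js", "mean_pearson", "n_pearson_excluded"}
        labelled = evaluate_dataset(pm, pm, true_layer_labels=np.argmax(values, axis=1))
        assert set(labelled) == set(bare) | {"ari", "purity"}

    def test_mean_js_is_arithmetic_mean_of_per_spot_values(self, rng):
        p = ProportionMatrix(rng.dirichlet(np.ones(3), size=5), ["a", "b", "c"])
        q = ProportionMatrix(rng.dirichlet(np.ones(3), size=5), ["a", "b", "c"])
        report = evaluate_dataset(p, q)
        per_spot = [js_divergence(pi, qi) for pi, qi in zip(p.values, q.values)]
        assert report["mean_js"] == pytest.approx(np.mean(per_spot), abs=1e-12)


class TestDivergenceProperties:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=60)
    @given(
        raw_p=st.lists(st.floats(0.001, 10.0), min_size=2, max_size=6),
        raw_q=st.lists(st.floats(0.001, 10.0), min_size=2, max_size=6),
    )
    def test_js_symmetric_bounded_and_zero_iff_equal(self, raw_p, raw_q):
        k = min(len(raw_p), len(raw_q))
        p = np.array(raw_p[:k]) / np.sum(raw_p[:k])
        q = np.array(raw_q[:k]) / np.sum(raw_q[:k])
        v = js_divergence(p, q)
        assert 0.0 <= v <= np.log(2) + 1e-12
        assert v == pytest.approx(js_divergence(q, p), abs=1e-12)
        assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-12)
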