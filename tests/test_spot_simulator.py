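import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from stdeconv import (
    SpotSimSpec,
    ValidationError,
    assign_coordinates,
    largest_remainder_allocation,
    mix_spots,
    sample_proportions,
    simulate_spots,
)


class TestSampleProportions:
    def test_max_types_one_gives_one_hot_rows(self):
        spec = SpotSimSpec(n_spots=50, max_types_per_spot=1, seed=2)
        pm = sample_proportions(spec, n_types=4)
        assert np.all(np.sort(pm.values, axis=1)[:, :-1] == 0)
        np.testing.assert_allclose(pm.values.max(axis=1), 1.0)

    def test_rows_on_simplex(self):
        pm = sample_proportions(SpotSimSpec(n_spots=200, seed=3), n_types=5)
        np.testing.assert_allclose(pm.values.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pm.values >= 0)

    def test_symmetric_dirichlet_mean_is_uniform(self):
        """Monte-Carlo: with alpha=1 over all 3 types, per-type mean ~ 1/3."""
        spec = SpotSimSpec(
            n_spots=10_000, max_types_per_spot=3, dirichlet_alpha=1.0, seed=4
        )
        pm = sample_proportions(spec, n_types=3)
        means = pm.values.mean(axis=0)
        # by symmetry the per-spot proportion has mean 1/3; bound its
        # variance by the Dirichlet(1,1,1) marginal variance 1/18
        se = np.sqrt((1 / 18) / spec.n_spots)
        assert np.all(np.abs(means - 1 / 3) < 3 * se * 3)

    def test_zero_types_rejected(self):
        with pytest.raises(ValidationError):
            sample_proportions(SpotSimSpec(), n_types=0)


class TestLargestRemainder:
    @pytest.mark.parametrize(
        "c,props,expected",
        [
            (10, [0.55, 0.45], [6, 4]),  # tie on fractions 0.5/0.5 -> lowest index
            (10, [0.54, 0.46], [5, 5]),
            (7, [1.0, 0.0], [7, 0]),
            (5, [0.2, 0.2, 0.6], [1, 1, 3]),
        ],
    )
    def test_hand_cases(self, c, props, expected):
        assert largest_remainder_allocation(c, np.array(props)).tolist() == expected

    def test_allocation_always_sums_to_c(self, rng):
        for _ in range(100):
            k = rng.integers(1, 6)
            p = rng.dirichlet(np.ones(k))
            c = int(rng.integers(1, 30))
            assert largest_remainder_allocation(c, p).sum() == c


class TestMixSpots:
    def test_expression_is_exact_sum_of_logged_cells(self, small_ref):
        spec = SpotSimSpec(n_spots=40, seed=5)
        props = sample_proportions(spec, 3, small_ref.type_names)
        ds, realized, log = mix_spots(small_ref, props, spec)
        for i in range(ds.n_spots):
            np.testing.assert_array_equal(
                ds.expr[i], small_ref.counts[log[i]].sum(axis=0)
            )

    def test_realized_proportions_match_allocations(self, small_ref):
        spec = SpotSimSpec(n_spots=40, seed=5)
        props = sample_proportions(spec, 3, small_ref.type_names)
        ds, realized, log = mix_spots(small_ref, props, spec)
        labels = np.asarray(small_ref.cell_types, dtype=object)
        for i in range(ds.n_spots):
            counts = np.array(
                [(labels[log[i]] == t).sum() for t in realized.cell_type_names]
            )
            np.testing.assert_allclose(realized.values[i], counts / counts.sum())

    def test_one_hot_props_give_one_hot_realized(self, small_ref):
        spec = SpotSimSpec(n_spots=30, max_types_per_spot=1, seed=6)
        props = sample_proportions(spec, 3, small_ref.type_names)
        _, realized, _ = mix_spots(small_ref, props, spec)
        # realized rows are exactly one-hot; the drawn proportions agree
        # up to the float error of a singleton Dirichlet draw
        assert set(np.unique(realized.values)) == {0.0, 1.0}
        np.testing.assert_allclose(realized.values, props.values, atol=1e-12)

    def test_integer_reference_gives_integer_spots(self, small_ref):
        spec = SpotSimSpec(n_spots=20, seed=7)
        props = sample_proportions(spec, 3, small_ref.type_names)
        ds, _, _ = mix_spots(small_ref, props, spec)
        assert np.array_equal(ds.expr, np.round(ds.expr))

    def test_missing_type_rejected(self, small_ref):
        from stdeconv import ProportionMatrix

        pm = ProportionMatrix(np.array([[1.0]]), ["not_a_type"])
        with pytest.raises(ValidationError, match="not_a_type"):
            mix_spots(small_ref, pm, SpotSimSpec(n_spots=1, n_spatial_clusters=1))


class TestAssignCoordinates:
    def test_output_shape(self, small_sim):
        ds, props, _, spec = small_sim
        coords = assign_coordinates(props, spec)
        assert coords.shape == (props.n_spots, 2)

    def test_single_cluster_concentrates_around_anchor(self):
        from stdeconv import ProportionMatrix

        rng = np.random.default_rng(1)
        pm = ProportionMatrix(rng.dirichlet(np.ones(3), size=500), ["a", "b", "c"])
        spec = SpotSimSpec(n_spots=500, n_spatial_clusters=1, jitter_sd=2.0, seed=8)
        coords = assign_coordinates(pm, spec)
        center = coords.mean(axis=0)
        r = np.linalg.norm(coords - center, axis=1)
        # 2-D Gaussian: P(r > 4 sd) is ~3e-4
        assert (r < 4 * spec.jitter_sd).mean() >= 0.99

    def test_within_cluster_tighter_than_cross_cluster(self, small_sim):
        ds, props, _, spec = small_sim
        d = squareform(pdist(ds.coords))
        # recover cluster identity from anchor proximity: small jitter
        from sklearn.cluster import KMeans

        labels = KMeans(3, n_init=10, random_state=0).fit_predict(ds.coords)
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        within = d[same].mean()
        cross = d[~same & (d > 0)].mean()
        assert within < cross

    def test_spatial_correlation_dial(self, small_sim):
        """Nearby spots have more similar compositions than random pairs."""
        ds, props, _, spec = small_sim
        d = squareform(pdist(ds.coords))
        l1 = squareform(pdist(props.values, metric="cityblock"))
        near = (d > 0) & (d < 2 * spec.jitter_sd)
        far = d > 0
        assert near.sum() > 0
        assert l1[near].mean() < l1[far].mean()


def test_simulate_spots_deterministic(small_ref):
    spec = SpotSimSpec(n_spots=25, seed=123)
    a = simulate_spots(small_ref, spec)
    b = simulate_spots(small_ref, spec)
    np.testing.assert_array_equal(a[0].expr, b[0].expr)
    np.testing.assert_array_equal(a[0].coords, b[0].coords)
    np.testing.assert_array_equal(a[1].values, b[1].values)


class TestAllocationProperties:
    from hypothesis import given, settings, strategies as st

    @settings(derandomize=True, max_examples=60)
    @given(
        c=st.integers(min_value=1, max_value=60),
        weights=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=6),
    )
    def test_largest_remainder_is_a_faithful_rounding(self, c, weights):
        p = np.array(weights) / np.sum(weights)
        alloc = largest_remainder_allocation(c, p)
        assert alloc.sum() == c
        assert np.all(alloc >= np.floor(c * p) - 1e-9)
        assert np.all(alloc <= np.ceil(c * p) + 1e-9)
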