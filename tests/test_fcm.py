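import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokemap import fcm
from strokemap import preprocess as pp
from strokemap.synth import generate_feature_table


def literal_membership_oracle(X, V, m):
    """Entrywise transcription of the membership formula."""
    n, c = len(X), len(V)
    U = np.zeros((n, c))
    for i in range(n):
        d = [np.linalg.norm(X[i] - V[k]) for k in range(c)]
        for k in range(c):
            U[i, k] = 1.0 / sum((d[k] / d[j]) ** (2.0 / (m - 1.0)) for j in range(c))
    return U


class TestUpdateMemberships:
    def test_equidistant_point_splits_evenly(self):
        X = np.array([[0.0, 0.0]])
        V = np.array([[1.0, 0.0], [-1.0, 0.0]])
        for m in (1.2, 2.0, 3.0):
            assert np.allclose(fcm.update_memberships(X, V, m), [[0.5, 0.5]])

    def test_coincident_point_gets_full_membership(self):
        X = np.array([[1.0, 2.0], [5.0, 5.0]])
        V = np.array([[1.0, 2.0], [3.0, 0.0]])
        U = fcm.update_memberships(X, V, 2.0)
        assert np.allclose(U[0], [1.0, 0.0])

    def test_point_on_two_centroids_splits_between_them(self):
        X = np.array([[1.0, 1.0]])
        V = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 9.0]])
        assert np.allclose(fcm.update_memberships(X, V, 2.0), [[0.5, 0.5, 0.0]])

    def test_matches_literal_formula(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(5, 4))
        V = rng.normal(size=(3, 4))
        U = fcm.update_memberships(X, V, 2.0)
        assert np.abs(U - literal_membership_oracle(X, V, 2.0)).max() < 1e-12

    def test_invalid_fuzzifier(self):
        with pytest.raises(ValueError, match="exceed 1"):
            fcm.update_memberships(np.zeros((2, 2)), np.ones((2, 2)), 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.floats(1.05, 4.0))
    def test_rows_normalized_and_bounded(self, seed, m):
        rng = np.random.default_rng(seed)
        U = fcm.update_memberships(rng.normal(size=(6, 3)), rng.normal(size=(3, 3)), m)
        assert np.all(U >= 0) and np.all(U <= 1)
        assert np.allclose(U.sum(axis=1), 1.0, atol=1e-9)


class TestUpdateCentroids:
    def test_uniform_membership_single_cluster_is_mean(self):
        X = np.arange(12.0).reshape(6, 2)
        U = np.ones((6, 1))
        assert np.allclose(fcm.update_centroids(X, U, 2.0), X.mean(0))

    def test_hard_membership_is_kmeans_means(self):
        X = np.array([[0.0], [1.0], [10.0], [12.0]])
        U = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        V = fcm.update_centroids(X, U, 2.0)
        assert np.allclose(V, [[0.5], [11.0]])

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 3))
        U = rng.dirichlet(np.ones(4), size=8)
        m = 1.7
        V = fcm.update_centroids(X, U, m)
        expected = (U**m).T @ X / (U**m).sum(0)[:, None]
        assert np.abs(V - expected).max() < 1e-12


class TestXieBeni:
    def test_zero_for_points_on_centroids(self):
        X = np.array([[0.0, 0.0], [4.0, 4.0]])
        U = np.eye(2)
        assert fcm.xie_beni(X, U, X.copy(), 2.0) == 0.0

    def test_pencil_and_paper_instance(self):
        # 1-D points 0,2,10,12; centroids 1 and 11; hard memberships.
        # compactness = 1+1+1+1 = 4; min separation^2 = 100; n = 4
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        V = np.array([[1.0], [11.0]])
        U = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        assert fcm.xie_beni(X, U, V, 2.0) == pytest.approx(4 / (4 * 100))

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        V = rng.normal(size=(3, 2))
        U = fcm.update_memberships(X, V, 2.0)
        a = fcm.xie_beni(X, U, V, 2.0)
        b = fcm.xie_beni(7.0 * X, U, 7.0 * V, 2.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_duplicate_centroids_error(self):
        X = np.array([[0.0], [1.0]])
        V = np.array([[0.5], [0.5]])
        U = np.full((2, 2), 0.5)
        with pytest.raises(ValueError, match="duplicate"):
            fcm.xie_beni(X, U, V, 2.0)


def two_clouds(seed=0, n=40):
    rng = np.random.default_rng(seed)
    a = rng.normal([0, 0], 0.3, size=(n, 2))
    b = rng.normal([6, 6], 0.3, size=(n, 2))
    return np.vstack([a, b]), np.array([0] * n + [1] * n)


class TestFitFcm:
    def test_separable_clouds_recovered(self):
        X, truth = two_clouds()
        model, U = fcm.fit_fcm(X, c=2, m=2.0, seed=1)
        hard = U.argmax(1)
        assert (hard == truth).all() or (hard == 1 - truth).all()
        assert model.converged

    def test_deterministic_under_fixed_seed(self):
        X, _ = two_clouds(3)
        _, U1 = fcm.fit_fcm(X, c=2, m=1.8, seed=5)
        _, U2 = fcm.fit_fcm(X, c=2, m=1.8, seed=5)
        assert np.array_equal(U1, U2)

    def test_objective_trace_non_increasing(self):
        for seed in range(5):
            X, _ = two_clouds(seed)
            model, _ = fcm.fit_fcm(X, c=3, m=2.0, seed=seed, n_init=2)
            trace = np.array(model.objective_trace)
            assert np.all(np.diff(trace) <= 1e-9 * max(trace[0], 1.0))

    def test_near_hard_limit_matches_nearest_centroid(self):
        X, _ = two_clouds(2)
        model, U = fcm.fit_fcm(X, c=2, m=1.01, seed=0)
        d = np.linalg.norm(X[:, None, :] - model.centroids[None], axis=2)
        assert (U.argmax(1) == d.argmin(1)).all()
        assert U.max(1).min() > 0.999

    def test_nonfinite_input_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="non-finite"):
            fcm.fit_fcm(X, c=2, m=2.0)

    def test_needs_more_points_than_clusters(self):
        with pytest.raises(ValueError, match="more points"):
            fcm.fit_fcm(np.zeros((3, 2)), c=3, m=2.0)

    def test_exhaustive_restarts_find_no_better_optimum(self):
        """On a tiny instance, 100 extra seeded fits never beat the
        configured multi-start by more than numerical tolerance."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 2))
        model, _ = fcm.fit_fcm(X, c=2, m=2.0, seed=0, n_init=10)
        best = min(
            fcm.fit_fcm(X, c=2, m=2.0, seed=s, n_init=1)[0].objective_trace[-1]
            for s in range(100)
        )
        assert model.objective_trace[-1] <= best + 1e-9


class TestSelectParameters:
    def test_planted_cluster_count_small(self, schedule):
        """Four well-separated archetype groups out of a {2,4,6} grid."""
        t = generate_feature_table(
            n_features=120, archetype_fraction=1.0, schedule=schedule,
            noise_cv=0.02, tic_spread=0.0, drift_amplitude=0.0,
            missing_rate=0.0, seed=2,
        )
        keep = t.feature_meta["archetype"].isin(["C", "H", "L", "O"])
        t.intensities = t.intensities.loc[keep]
        t.feature_meta = t.feature_meta.loc[keep]
        shape = pp.pool_and_standardize(pp.gap_fill(t))
        c_star, m_star, table = fcm.select_parameters(
            shape.values.to_numpy(), c_grid=(2, 4, 6), m_grid=(1.2, 2.0),
            seed=0, n_init=3,
        )
        assert c_star == 4
        assert len(table) == 6

    def test_deterministic_grid_table(self):
        X, _ = two_clouds(1, n=15)
        _, _, t1 = fcm.select_parameters(X, (2, 3), (1.5, 2.0), seed=4, n_init=2)
        _, _, t2 = fcm.select_parameters(X, (2, 3), (1.5, 2.0), seed=4, n_init=2)
        assert t1.equals(t2)

    def test_single_blob_smoke(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 2))
        c_star, m_star, table = fcm.select_parameters(X, (2, 3), (2.0,), seed=0,
                                                      n_init=2)
        assert set(table["c"]) == {2, 3}

    def test_invalid_m_grid(self):
        with pytest.raises(ValueError, match="exceed 1"):
            fcm.select_parameters(np.zeros((10, 2)), (2,), (0.9, 2.0))
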