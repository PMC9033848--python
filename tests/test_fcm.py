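import numpy as np
import pytest

from frpbp import fcm_fit, fcm_objective, update_centers, update_memberships
from frpbp.fcm import DegenerateClusterError


def brute_objective(states, U, Z, omega):
    total = 0.0
    for i in range(len(states)):
        for k in range(len(Z)):
            d2 = float(np.sum((np.atleast_1d(states[i]) - np.atleast_1d(Z[k])) ** 2))
            total += U[i, k] ** omega * d2
    return total


def reference_fcm(states, c, omega, alpha, seed, max_iter=300):
    """Independent loop-based FCM used as the oracle for fcm_fit."""
    states = np.atleast_2d(np.asarray(states, float))
    if states.shape[0] == 1:
        states = states.T
    rng = np.random.default_rng(seed)
    n = states.shape[0]
    U = rng.random((n, c))
    U = U / U.sum(axis=1, keepdims=True)
    Z = np.zeros((c, states.shape[1]))
    for _ in range(max_iter):
        for j in range(c):
            w = U[:, j] ** omega
            Z[j] = (w[:, None] * states).sum(axis=0) / w.sum()
        U_new = np.zeros_like(U)
        for i in range(n):
            d = np.sqrt(((states[i] - Z) ** 2).sum(axis=1))
            if np.any(d == 0):
                U_new[i, int(np.argmin(d))] = 1.0
                continue
            for k in range(c):
                U_new[i, k] = 1.0 / np.sum((d[k] / d) ** (2.0 / (omega - 1.0)))
        delta = np.max(np.abs(U_new - U))
        U = U_new
        if delta <= alpha:
            break
    return U, Z, brute_objective(states, U, Z, omega)


class TestObjective:
    def test_single_cluster_direct_sum(self):
        states = np.array([[0.0], [2.0]])
        U = np.ones((2, 1))
        Z = np.array([[1.0]])
        assert fcm_objective(states, U, Z, 2.0) == pytest.approx(2.0)

    def test_zero_when_states_sit_on_centers(self):
        states = np.array([[1.0, 2.0], [3.0, 4.0]])
        U = np.eye(2)
        assert fcm_objective(states, U, states.copy(), 2.0) == 0.0

    def test_matches_brute_force(self, rng):
        states = rng.standard_normal((12, 3))
        U = rng.random((12, 4))
        U /= U.sum(axis=1, keepdims=True)
        Z = rng.standard_normal((4, 3))
        assert fcm_objective(states, U, Z, 1.7) == pytest.approx(
            brute_objective(states, U, Z, 1.7), abs=1e-12
        )

    def test_rejects_omega_at_most_one(self):
        with pytest.raises(ValueError, match="exceed 1"):
            fcm_objective(np.zeros((2, 1)), np.ones((2, 1)), np.zeros((1, 1)), 1.0)


class TestMembershipUpdate:
    def test_inverse_distance_ratio(self):
        # d = (1, 3): mu_1 = 1/(1 + (1/3)^2) = 9/10
        u = update_memberships(np.array([[0.0]]), np.array([[1.0], [3.0]]), 2.0)
        np.testing.assert_allclose(u, [[0.9, 0.1]], atol=1e-12)

    def test_equidistant_state_splits_evenly(self):
        u = update_memberships(np.array([[0.0]]), np.array([[-2.0], [2.0]]), 2.0)
        np.testing.assert_allclose(u, [[0.5, 0.5]], atol=1e-12)

    def test_state_on_center_is_crisp(self):
        u = update_memberships(np.array([[2.0]]), np.array([[5.0], [2.0], [2.0]]), 2.0)
        np.testing.assert_array_equal(u, [[0.0, 1.0, 0.0]])  # first zero-distance cluster

    def test_rows_sum_to_one(self, rng):
        u = update_memberships(rng.standard_normal((30, 2)), rng.standard_normal((5, 2)), 2.5)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((u >= 0) & (u <= 1))


class TestCenterUpdate:
    def test_uniform_weights_give_mean(self, rng):
        states = rng.standard_normal((8, 2))
        z = update_centers(states, np.ones((8, 1)), 2.0)
        np.testing.assert_allclose(z[0], states.mean(axis=0), atol=1e-12)

    def test_hand_weighted_mean(self):
        states = np.array([[0.0], [2.0]])
        U = np.array([[1.0], [0.5]])
        z = update_centers(states, U, 2.0)
        assert z[0, 0] == pytest.approx(0.4)

    def test_matches_brute_force(self, rng):
        states = rng.standard_normal((10, 3))
        U = rng.random((10, 3))
        w = U**2.1
        expected = (w.T @ states) / w.sum(axis=0)[:, None]
        np.testing.assert_allclose(update_centers(states, U, 2.1), expected, atol=1e-12)

    def test_empty_cluster_raises(self):
        U = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DegenerateClusterError):
            update_centers(np.zeros((2, 1)), U, 2.0)


class TestFit:
    def test_separated_groups_get_crisp_memberships(self, rng):
        a = rng.normal(0.0, 0.01, size=(10, 2))
        b = rng.normal(10.0, 0.01, size=(10, 2)) + 5.0
        part = fcm_fit(np.vstack([a, b]), c=2, seed=3)
        top = part.U.max(axis=1)
        assert np.all(top >= 0.99)
        labels = part.U.argmax(axis=1)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_single_cluster_degenerates_to_mean(self, rng):
        states = rng.standard_normal((9, 2))
        part = fcm_fit(states, c=1, seed=0)
        np.testing.assert_allclose(part.U, 1.0)
        np.testing.assert_allclose(part.Z[0], states.mean(axis=0), atol=1e-9)
        scatter = float(np.sum((states - states.mean(axis=0)) ** 2))
        assert part.J == pytest.approx(scatter, rel=1e-9)

    def test_six_point_reference_iteration(self):
        """Fixed seeded 1-D instance agrees with an independent FCM loop."""
        states = np.array([0.0, 0.2, 0.1, 4.0, 4.3, 3.9])
        part = fcm_fit(states, c=2, omega=2.0, alpha=1e-5, seed=11)
        _, _, j_ref = reference_fcm(states, c=2, omega=2.0, alpha=1e-5, seed=11)
        assert part.J == pytest.approx(j_ref, abs=1e-6)

    def test_objective_monotone_and_rows_stochastic(self, rng):
        states = rng.standard_normal((40, 3))
        part = fcm_fit(states, c=4, seed=5)
        hist = np.array(part.J_history)
        assert np.all(np.diff(hist) <= 1e-9)
        np.testing.assert_allclose(part.U.sum(axis=1), 1.0, atol=1e-9)

    def test_relabel_invariance_of_objective(self, rng):
        states = rng.standard_normal((20, 2))
        part = fcm_fit(states, c=3, seed=2)
        perm = [2, 0, 1]
        assert fcm_objective(states, part.U[:, perm], part.Z[perm], 2.0) == pytest.approx(
            part.J, rel=1e-12
        )

    def test_too_few_states_raises(self):
        with pytest.raises(ValueError, match="c=5"):
            fcm_fit(np.zeros((3, 1)), c=5)

    def test_non_convergence_flags_not_raises(self, rng):
        part = fcm_fit(rng.standard_normal((50, 2)), c=3, seed=1, max_iter=2)
        assert part.converged is False
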