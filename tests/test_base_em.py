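import numpy as np
import pytest

from sharpssl import (
    MixtureParams,
    class_moments,
    e_step,
    em_importance,
    hierarchical_init,
    m_step,
    run_em,
    select_run,
    soft_between_covariance,
)
from sharpssl.base_em import observed_nll, sphere_init


def tanh_iterate(Z, y, mu, T):
    """Independent closed-form symmetric-family EM iterate.

    mu <- (1/n) { sum_{y!=0} (-1)^y z + sum_{y=0} z tanh<z, mu> }.
    """
    Z = np.asarray(Z, float)
    for _ in range(T):
        acc = np.zeros_like(mu)
        for i in range(len(y)):
            if y[i] != 0:
                acc += (-1.0) ** y[i] * Z[i]
            else:
                acc += Z[i] * np.tanh(Z[i] @ mu)
        mu = acc / len(y)
    return mu


class TestEStep:
    def test_labeled_rows_are_one_hot(self, rng):
        params = MixtureParams(rng.normal(size=(3, 2)), np.eye(2))
        Z = rng.normal(size=(6, 2))
        y = np.array([1, 2, 3, 0, 2, 1])
        L = e_step(Z, y, params)
        for i, yi in enumerate(y):
            if yi > 0:
                want = np.zeros(3)
                want[yi - 1] = 1
                assert np.array_equal(L[i], want)

    def test_equidistant_point_gets_uniform_posterior(self):
        params = MixtureParams(np.array([[1.0, 0.0], [-1.0, 0.0]]), np.eye(2))
        L = e_step(np.array([[0.0, 5.0]]), np.array([0]), params)
        assert np.allclose(L, [[0.5, 0.5]])

    def test_one_dimensional_posterior_value(self):
        # z=1, means (-1, +1), unit variance: P(class 2) = 1/(1+e^{-2})
        params = MixtureParams(np.array([[-1.0], [1.0]]), np.eye(1))
        L = e_step(np.array([[1.0]]), np.array([0]), params)
        assert np.allclose(L[0, 1], 1.0 / (1.0 + np.exp(-2.0)))

    def test_rows_sum_to_one(self, rng):
        params = MixtureParams(rng.normal(size=(4, 3)), np.eye(3) * 0.5)
        L = e_step(rng.normal(size=(50, 3)), rng.integers(0, 5, 50), params)
        assert np.allclose(L.sum(axis=1), 1.0, atol=1e-12)


class TestMStep:
    def test_one_hot_reduces_to_supervised_moments(self, rng):
        Z = rng.normal(size=(30, 2))
        y = rng.integers(1, 4, size=30)
        L = np.zeros((30, 3))
        L[np.arange(30), y - 1] = 1.0
        params = m_step(Z, L, "unconstrained")
        mom = class_moments(Z, y, 3)
        assert np.allclose(params.means, mom.means)
        assert np.allclose(params.within, mom.within)

    def test_symmetric_fully_labeled_matches_signed_average(self, rng):
        Z = rng.normal(size=(20, 3))
        y = rng.integers(1, 3, size=20)
        L = np.zeros((20, 2))
        L[np.arange(20), y - 1] = 1.0
        params = m_step(Z, L, "symmetric")
        want = np.mean([(-1.0) ** yi * zi for yi, zi in zip(y, Z)], axis=0)
        assert np.allclose(params.means[1], want)
        assert np.allclose(params.means[0], -want)
        assert np.array_equal(params.within, np.eye(3))

    def test_symmetric_ambiguous_data_centers_at_zero(self):
        L = np.full((2, 2), 0.5)
        params = m_step(np.array([[-1.0], [1.0]]), L, "symmetric")
        assert np.allclose(params.means, 0.0)

    def test_diagonal_family_zeroes_off_diagonal(self, rng):
        Z = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 3))
        L = np.full((40, 2), 0.5)
        params = m_step(Z, L, "diagonal")
        assert np.allclose(params.within, np.diag(np.diag(params.within)))

    def test_zero_mass_class_warns_and_zeroes_mean(self, rng):
        L = np.zeros((5, 2))
        L[:, 0] = 1.0
        with pytest.warns(UserWarning):
            params = m_step(rng.normal(size=(5, 2)) + 10, L, "unconstrained")
        assert np.allclose(params.means[1], 0.0)


class TestRunEm:
    def test_T_one_is_single_composition(self, rng):
        Z = rng.normal(size=(25, 2))
        y = rng.integers(0, 3, size=25)
        init = MixtureParams(rng.normal(size=(2, 2)), np.eye(2))
        params, L = run_em(Z, y, init, "unconstrained", T=1)
        manual = m_step(Z, e_step(Z, y, init), "unconstrained")
        assert np.allclose(params.means, manual.means)
        assert np.allclose(params.within, manual.within)
        assert np.allclose(L, e_step(Z, y, manual))

    def test_T_zero_rejected(self, rng):
        init = MixtureParams(np.zeros((2, 1)), np.eye(1))
        with pytest.raises(ValueError):
            run_em(rng.normal(size=(5, 1)), np.zeros(5, dtype=int), init, T=0)

    def test_fully_labeled_symmetric_is_fixed_after_one_iteration(self, rng):
        Z = rng.normal(size=(30, 2))
        y = rng.integers(1, 3, size=30)
        target = np.mean([(-1.0) ** yi * zi for yi, zi in zip(y, Z)], axis=0)
        for _ in range(3):
            init = sphere_init(2, rng, radius=2.0)
            p1, _ = run_em(Z, y, init, "symmetric", T=1)
            pT, _ = run_em(Z, y, init, "symmetric", T=50)
            assert np.allclose(p1.means[1], target, atol=1e-12)
            assert np.allclose(pT.means[1], target, atol=1e-12)

    def test_symmetric_trajectory_equals_tanh_iterate(self, rng):
        Z = rng.normal(size=(40, 3)) + 0.8
        y = rng.integers(0, 3, size=40)
        mu0 = rng.normal(size=3) * 0.3
        init = MixtureParams(np.stack([-mu0, mu0]), np.eye(3))
        for T in (1, 2, 7):
            params, _ = run_em(Z, y, init, "symmetric", T=T, param_tol=0.0)
            assert np.allclose(params.means[1], tanh_iterate(Z, y, mu0, T), atol=1e-12)

    def test_nll_never_increases(self, rng):
        Z = np.concatenate([rng.normal(size=(30, 2)) - 1, rng.normal(size=(30, 2)) + 1])
        y = rng.integers(0, 3, size=60)
        params = MixtureParams(rng.normal(size=(2, 2)), np.eye(2))
        prev = observed_nll(Z, y, params)
        for _ in range(40):
            params = m_step(Z, e_step(Z, y, params), "unconstrained")
            cur = observed_nll(Z, y, params)
            assert cur <= prev + 1e-8
            prev = cur


class TestSoftBetween:
    def test_all_mass_on_one_class(self):
        params = MixtureParams(np.array([[2.0], [5.0]]), np.eye(1))
        L = np.zeros((4, 2))
        L[:, 0] = 1.0
        mu_tot, between = soft_between_covariance(L, params)
        assert np.allclose(mu_tot, [2.0])
        assert np.allclose(between, 0.0)

    def test_balanced_two_point_variance(self):
        params = MixtureParams(np.array([[-1.0], [1.0]]), np.eye(1))
        L = np.full((10, 2), 0.5)
        mu_tot, between = soft_between_covariance(L, params)
        assert np.allclose(mu_tot, 0.0)
        assert np.allclose(between, 1.0)

    def test_sign_flip_invariance(self, rng):
        means = rng.normal(size=(2, 3))
        L = rng.dirichlet([1, 1], size=12)
        _, b1 = soft_between_covariance(L, MixtureParams(means, np.eye(3)))
        _, b2 = soft_between_covariance(L, MixtureParams(-means, np.eye(3)))
        assert np.allclose(b1, b2)


class TestSelectRun:
    def test_single_run(self):
        assert select_run([np.eye(2)]) == 0

    def test_outlier_run_rejected(self):
        Qs = [np.zeros((2, 2)), np.zeros((2, 2)), np.eye(2)]
        # medians of distances to others: 0.5, 0.5, 1 -> tie to index 0
        assert select_run(Qs) == 0

    def test_identical_runs_tie_to_first(self):
        assert select_run([np.eye(3)] * 4 ) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_run([])


class TestEmImportance:
    def test_pure_noise_scores_vanish_with_n(self, rng):
        Z = rng.normal(size=(4000, 2))
        y = np.zeros(4000, dtype=int)
        mu = np.array([0.5, 0.0])
        init = MixtureParams(np.stack([-mu, mu]), np.eye(2))
        scores = em_importance(
            Z, y, 2, family="symmetric", T=500, loglik_rtol=None,
            init_policy=lambda Z_, K_, r_: init, rng=rng,
        )
        # the planted-direction estimate decays to its n^{-1/4} noise floor
        assert scores.max() < 0.05

    def test_symmetric_family_recovers_planted_direction(self, rng):
        n = 20_000
        signs = rng.choice([-1.0, 1.0], size=n)
        Z = rng.normal(size=(n, 2))
        Z[:, 0] += signs
        y = np.where(rng.random(n) < 0.5, np.where(signs < 0, 1, 2), 0)
        scores = em_importance(
            Z, y, 2, family="symmetric", init_policy="random", rng=rng
        )
        # population scores are ((mu*_1)^2, (mu*_2)^2) = (1, 0)
        assert abs(scores[0] - 1.0) < 3 * 0.015
        assert scores[1] < 0.01

    def test_hierarchical_init_is_deterministic(self, rng):
        Z = np.concatenate([rng.normal(size=(40, 2)) - 1.5, rng.normal(size=(40, 2)) + 1.5])
        y = np.zeros(80, dtype=int)
        a = em_importance(Z, y, 2, rng=np.random.default_rng(0))
        b = em_importance(Z, y, 2, rng=np.random.default_rng(123))
        assert np.array_equal(a, b)

    def test_hierarchical_init_splits_separated_clusters(self, rng):
        Z = np.concatenate([rng.normal(size=(30, 2)) - 5, rng.normal(size=(30, 2)) + 5])
        init = hierarchical_init(Z, 2)
        gap = np.linalg.norm(init.means[0] - init.means[1])
        assert gap > 8

    def test_hierarchical_init_matches_cluster_numbers_to_labels(self, rng):
        Z = np.concatenate([rng.normal(size=(30, 1)) - 5, rng.normal(size=(30, 1)) + 5])
        y_true = np.repeat([1, 2], 30)
        for flip in (y_true, 3 - y_true):
            y = np.where(rng.random(60) < 0.3, flip, 0)
            init = hierarchical_init(Z, 2, y=y)
            # class-1 mean must sit on the side the observed labels call 1
            side = np.sign(Z[y == 1].mean())
            assert np.sign(init.means[0, 0]) == side
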