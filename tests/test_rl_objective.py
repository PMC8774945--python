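import numpy as np
import pytest

from qsdlearn import (
    Distribution,
    QueueSpec,
    SoftmaxPolicy,
    average_reward_exact,
    exact_qsd,
    exact_stationary,
    grad_log_onestep,
    grad_log_regen,
    kl_rate_exact,
    logits_for_distribution,
    loopy_chain,
    make_regenerative,
    mm1_queue,
    one_step_distribution,
    policy_distribution,
    policy_gradient_exact,
    policy_gradient_fd,
    policy_jacobian,
    reward,
    value_exact,
)

from .conftest import random_instance


def random_policy(n: int, seed: int) -> SoftmaxPolicy:
    return SoftmaxPolicy(np.random.default_rng(seed).normal(size=n - 1))


class TestSoftmaxPolicy:
    def test_zero_logits_uniform(self):
        d = policy_distribution(SoftmaxPolicy(np.zeros(2)))
        np.testing.assert_allclose(d.probs, 1.0 / 3.0, atol=1e-15)

    def test_two_state_closed_form(self):
        d = policy_distribution(SoftmaxPolicy(np.array([np.log(2.0)])))
        np.testing.assert_allclose(d.probs, [2.0 / 3.0, 1.0 / 3.0], atol=1e-14)

    def test_shift_not_invariant(self):
        # the pinned last logit breaks full shift invariance
        base = policy_distribution(SoftmaxPolicy(np.array([0.4, -0.3]))).probs
        shifted = policy_distribution(
            SoftmaxPolicy(np.array([0.4 + 1.0, -0.3 + 1.0]))).probs
        assert np.abs(base - shifted).max() > 1e-3
        # against the direct formula
        t = np.array([0.4, -0.3])
        direct = np.exp(np.append(t, 0.0))
        direct /= direct.sum()
        np.testing.assert_allclose(base, direct, atol=1e-14)

    def test_overflow_guarded(self):
        d = policy_distribution(SoftmaxPolicy(np.array([400.0, -400.0])))
        assert np.isfinite(d.probs).all()
        assert d.probs.sum() == pytest.approx(1.0)

    def test_logits_inverse(self):
        p = Distribution(np.array([0.2, 0.5, 0.3]))
        pol = logits_for_distribution(p)
        np.testing.assert_allclose(policy_distribution(pol).probs, p.probs,
                                   atol=1e-12)


class TestPolicyJacobian:
    def test_uniform_closed_form(self):
        J = policy_jacobian(SoftmaxPolicy(np.zeros(2)))
        expected = (1.0 / 3.0) * (np.eye(3, 2) - 1.0 / 3.0)
        np.testing.assert_allclose(J, expected, atol=1e-14)

    def test_columns_sum_to_zero(self):
        for seed in range(5):
            J = policy_jacobian(random_policy(6, seed))
            np.testing.assert_allclose(J.sum(axis=0), 0.0, atol=1e-14)

    def test_finite_difference(self):
        pol = random_policy(5, 11)
        J = policy_jacobian(pol)
        h = 1e-6
        for j in range(4):
            tp, tm = pol.theta.copy(), pol.theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (policy_distribution(SoftmaxPolicy(tp)).probs
                  - policy_distribution(SoftmaxPolicy(tm)).probs) / (2 * h)
            np.testing.assert_allclose(J[:, j], fd, atol=1e-8)


class TestReward:
    def test_zero_at_qsd(self, two_state):
        alpha, _ = exact_qsd(two_state)
        pol = logits_for_distribution(alpha)
        for x in range(2):
            for y in range(2):
                assert reward(two_state, pol, x, y) == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_queue_zero_off_leak(self):
        # only the bottom level leaks, so rewards vanish elsewhere
        K = mm1_queue(QueueSpec(8, 1.25))
        pol = random_policy(8, 3)
        for x in range(1, 7):
            for y in (x - 1, x + 1):
                assert reward(K, pol, x, y) == 0.0

    def test_brute_force_oracle(self, loopy05):
        pol = SoftmaxPolicy(np.array([1.0, 0.0]))
        alpha = policy_distribution(pol).probs
        a = loopy05.absorption
        Ka = loopy05.mass + np.outer(a, alpha)
        beta = np.zeros(3)
        for y in range(3):
            for x in range(3):
                beta[y] += alpha[x] * Ka[x, y]
        Kb = loopy05.mass + np.outer(a, beta)
        for x in range(3):
            for y in range(3):
                expected = -np.log(Ka[x, y] / Kb[x, y])
                assert reward(loopy05, pol, x, y) == pytest.approx(
                    expected, abs=1e-12)

    def test_zero_probability_rejected(self):
        K = mm1_queue(QueueSpec(6, 1.25))
        pol = random_policy(6, 3)
        with pytest.raises(ValueError, match="zero probability"):
            reward(K, pol, 3, 0)   # interior level cannot jump to bottom


class TestAverageReward:
    def test_zero_at_qsd(self, two_state):
        alpha, _ = exact_qsd(two_state)
        assert average_reward_exact(
            two_state, logits_for_distribution(alpha)) == pytest.approx(
                0.0, abs=1e-10)

    def test_nonpositive(self):
        for seed in range(8):
            n = 3 + seed % 4
            K = random_instance(n, 400 + seed)
            assert average_reward_exact(K, random_policy(n, seed)) <= 0.0

    def test_equals_negative_kl_rate(self):
        for seed in range(5):
            n = 3 + seed
            K = random_instance(n, 500 + seed)
            pol = random_policy(n, seed)
            r = average_reward_exact(K, pol)
            kl = kl_rate_exact(K, policy_distribution(pol))
            assert r == pytest.approx(-kl, abs=1e-12)


class TestValueExact:
    def test_zero_at_qsd(self, two_state):
        alpha, _ = exact_qsd(two_state)
        V = value_exact(two_state, logits_for_distribution(alpha))
        np.testing.assert_allclose(V.psi, 0.0, atol=1e-10)

    def test_bellman_residual(self):
        for seed in range(5):
            K = random_instance(6, 600 + seed)
            pol = random_policy(6, seed)
            V = value_exact(K, pol).psi
            alpha = policy_distribution(pol)
            Pa = make_regenerative(K, alpha)
            beta = one_step_distribution(alpha, K)
            Kb = make_regenerative(K, beta).matrix
            R = np.where(Pa.matrix > 0,
                         np.log(np.where(Kb > 0, Kb, 1.0))
                         - np.log(np.where(Pa.matrix > 0, Pa.matrix, 1.0)),
                         0.0)
            r = average_reward_exact(K, pol)
            rhs = (Pa.matrix * (V[None, :] + R - r)).sum(axis=1)
            np.testing.assert_allclose(V, rhs, atol=1e-10)

    def test_truncated_series_oracle(self):
        # V(x) = lim sum_t E[R_t - r | X_0 = x], summed to T = 1e4
        K = random_instance(4, 5)
        pol = SoftmaxPolicy(np.array([0.3, -0.4, 0.1]))
        V = value_exact(K, pol).psi
        alpha = policy_distribution(pol)
        Pa = make_regenerative(K, alpha).matrix
        Kb = make_regenerative(K, one_step_distribution(alpha, K)).matrix
        R = np.where(Pa > 0, np.log(np.where(Kb > 0, Kb, 1.0))
                     - np.log(np.where(Pa > 0, Pa, 1.0)), 0.0)
        r = average_reward_exact(K, pol)
        c = (Pa * R).sum(axis=1) - r
        series = np.zeros(4)
        P_t = np.eye(4)
        for _ in range(10_000):
            series += P_t @ c
            P_t = P_t @ Pa
        np.testing.assert_allclose(V, series, atol=1e-6)

    def test_centering(self):
        for seed in range(5):
            K = random_instance(5, 700 + seed)
            pol = random_policy(5, seed)
            V = value_exact(K, pol).psi
            mu = exact_stationary(
                make_regenerative(K, policy_distribution(pol))).probs
            assert abs(mu @ V) <= 1e-10


class TestGradLogKernels:
    def test_zero_without_absorption(self):
        K = mm1_queue(QueueSpec(7, 1.25))
        pol = random_policy(7, 9)
        for x in (1, 3, 6):
            y = x - 1
            np.testing.assert_allclose(grad_log_regen(K, pol, x, y), 0.0,
                                       atol=1e-15)
            np.testing.assert_allclose(grad_log_onestep(K, pol, x, y), 0.0,
                                       atol=1e-15)

    def test_fd_oracle_regen(self):
        for seed in range(5):
            n = 3 + seed
            K = random_instance(n, 800 + seed)
            pol = random_policy(n, seed)
            alpha = policy_distribution(pol).probs
            h = 1e-6
            for x in range(n):
                for y in range(n):
                    ka = K.mass[x, y] + K.absorption[x] * alpha[y]
                    if ka <= 1e-12:
                        continue
                    g = grad_log_regen(K, pol, x, y)
                    fd = np.empty(n - 1)
                    for j in range(n - 1):
                        tp, tm = pol.theta.copy(), pol.theta.copy()
                        tp[j] += h
                        tm[j] -= h
                        ap = policy_distribution(SoftmaxPolicy(tp)).probs
                        am = policy_distribution(SoftmaxPolicy(tm)).probs
                        fd[j] = (np.log(K.mass[x, y]
                                        + K.absorption[x] * ap[y])
                                 - np.log(K.mass[x, y]
                                          + K.absorption[x] * am[y])) / (2 * h)
                    np.testing.assert_allclose(g, fd, atol=1e-7)

    def test_fd_oracle_onestep(self):
        from qsdlearn.chain_core import make_regenerative as mk

        for seed in range(3):
            n = 4 + seed
            K = random_instance(n, 900 + seed)
            pol = random_policy(n, seed)
            h = 1e-6

            def log_kb(theta, x, y):
                p = policy_distribution(SoftmaxPolicy(theta))
                b = one_step_distribution(p, K)
                return np.log(mk(K, b).matrix[x, y])

            for x in range(n):
                if K.absorption[x] <= 0:
                    continue
                for y in range(n):
                    g = grad_log_onestep(K, pol, x, y)
                    fd = np.empty(n - 1)
                    for j in range(n - 1):
                        tp, tm = pol.theta.copy(), pol.theta.copy()
                        tp[j] += h
                        tm[j] -= h
                        fd[j] = (log_kb(tp, x, y) - log_kb(tm, x, y)) / (2 * h)
                    np.testing.assert_allclose(g, fd, atol=1e-7)

    def test_onestep_expectation_vanishes_at_qsd(self, two_state):
        # stationarity of the optimum: E_{mu x K_alpha}[grad ln K_beta] = 0
        alpha, _ = exact_qsd(two_state)
        pol = logits_for_distribution(alpha)
        Pa = make_regenerative(two_state, alpha)
        mu = exact_stationary(Pa).probs
        total = np.zeros(1)
        for x in range(2):
            for y in range(2):
                total += mu[x] * Pa.matrix[x, y] * grad_log_onestep(
                    two_state, pol, x, y)
        np.testing.assert_allclose(total, 0.0, atol=1e-8)


class TestPolicyGradient:
    def test_zero_at_qsd(self, two_state):
        alpha, _ = exact_qsd(two_state)
        g = policy_gradient_exact(two_state, logits_for_distribution(alpha))
        np.testing.assert_allclose(g, 0.0, atol=1e-8)

    def test_master_fd_property(self):
        # exact vs central finite differences over 50 random (K, theta) pairs
        rng = np.random.default_rng(1)
        for trial in range(50):
            n = int(rng.integers(3, 9))
            K = random_instance(n, 1000 + trial)
            pol = SoftmaxPolicy(rng.normal(size=n - 1))
            g = policy_gradient_exact(K, pol)
            fd = policy_gradient_fd(K, pol, h=1e-5)
            scale = max(np.abs(fd).max(), 1e-10)
            assert np.abs(g - fd).max() / scale <= 1e-5

    def test_baseline_shift_invariance(self):
        K = random_instance(5, 3)
        pol = random_policy(5, 4)
        g = policy_gradient_exact(K, pol)
        for b in (0.0, 1.0, -3.7):
            gb = policy_gradient_exact(K, pol, baseline=b)
            np.testing.assert_allclose(gb, g, atol=1e-10)

    def test_fd_quadratic_convergence(self):
        K = loopy_chain(0.3)
        pol = SoftmaxPolicy(np.array([0.5, -0.2]))
        g = policy_gradient_exact(K, pol)
        errs = [np.abs(policy_gradient_fd(K, pol, h=h) - g).max()
                for h in (1e-2, 1e-3, 1e-4)]
        assert errs[0] / errs[1] > 30        # ~h^2 shrinkage per decade
        assert errs[1] / errs[2] > 30

    def test_fd_matches_on_loopy(self):
        K = loopy_chain(0.3)
        pol = SoftmaxPolicy(np.array([0.5, -0.2]))
        g = policy_gradient_exact(K, pol)
        fd = policy_gradient_fd(K, pol, h=1e-5)
        assert np.abs(g - fd).max() / np.abs(fd).max() <= 1e-5


class TestOptimalityCharacterization:
    def test_forward_direction(self):
        # r = 0 at the QSD logits on every small model-zoo instance
        from qsdlearn import sis_extinction_chain

        instances = [loopy_chain(e) for e in (0.1, 0.5, 0.9)]
        instances += [mm1_queue(QueueSpec(20, 1.25)),
                      sis_extinction_chain(20, 2.0, 1.0)]
        for K in instances:
            alpha, _ = exact_qsd(K)
            pol = logits_for_distribution(alpha)
            assert abs(average_reward_exact(K, pol)) <= 1e-8
            assert np.abs(policy_gradient_exact(K, pol)).max() <= 1e-8
            assert np.abs(value_exact(K, pol).psi).max() <= 1e-8
            assert (np.abs(policy_distribution(pol).probs
                           - alpha.probs).max() <= 1e-8)

    def test_reverse_direction(self):
        # r is strictly negative away from the QSD
        K = loopy_chain(0.3)
        alpha, _ = exact_qsd(K)
        theta_star = logits_for_distribution(alpha).theta
        rng = np.random.default_rng(0)
        for _ in range(100):
            pol = SoftmaxPolicy(theta_star + 0.5 * rng.normal(size=2))
            assert average_reward_exact(K, pol) < -1e-6

    def test_gradient_ascent_sanity(self):
        # full-gradient ascent drives the KL rate down by over an order of
        # magnitude; convergence is linear but the Hessian near the optimum
        # is ill-conditioned, so the absolute floor is modest
        for seed in (3, 7, 11):
            K = random_instance(5, seed)
            theta = np.zeros(4)
            kl0 = kl_rate_exact(K, policy_distribution(SoftmaxPolicy(theta)))
            for _ in range(1500):
                theta = theta + 0.5 * policy_gradient_exact(
                    K, SoftmaxPolicy(theta))
            kl = kl_rate_exact(K, policy_distribution(SoftmaxPolicy(theta)))
            assert kl < 1e-3
            assert kl < kl0 / 10.0
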