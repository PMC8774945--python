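"""Softmax policy, reward, exact average reward / value function, and the
analytic policy gradient with its finite-difference oracle.

The candidate QSD is parameterised as a softmax over ``n`` states with the
last logit pinned to zero, so the free parameter ``theta`` lives in
``R^(n-1)``.  With ``alpha = alpha_theta``, ``beta = alpha K_alpha`` and
``mu`` the stationary law of ``K_alpha``, the objective is the (negative)
KL divergence rate

    ``r(theta) = - sum_{x,y} mu(x) K_alpha(x,y) ln(K_alpha(x,y)/K_beta(x,y))``

which is maximised (at zero) exactly when ``alpha_theta`` is the QSD.  The
per-transition reward is ``R(x,y) = -ln(K_alpha(x,y)/K_beta(x,y))`` and the
differential value function solves the average-reward Bellman equation

    ``V(x) = sum_y K_alpha(x,y) [V(y) + R(x,y) - r]``

normalised by ``sum_x mu(x) V(x) = 0``.

Gradient formulas (validated against central finite differences):

    ``d ln K_alpha(x,y) / d theta = a(x) J[y, :] / K_alpha(x,y)``
    ``d beta(y) / d theta = J^T K[:, y] + s J[y, :] + beta-coupling term``
    ``d ln K_beta(x,y) / d theta = a(x) (d beta(y)/d theta) / K_beta(x,y)``

where ``J`` is the softmax Jacobian and ``s = sum_x alpha(x) a(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_core import (
    Distribution,
    SubMarkovKernel,
    exact_stationary,
    make_regenerative,
    one_step_distribution,
)

__all__ = [
    "SoftmaxPolicy",
    "TabularValue",
    "policy_distribution",
    "policy_jacobian",
    "logits_for_distribution",
    "reward",
    "average_reward_exact",
    "value_exact",
    "grad_log_regen",
    "grad_log_onestep",
    "policy_gradient_exact",
    "policy_gradient_fd",
]

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class SoftmaxPolicy:
    """Free logits ``theta`` of length ``n - 1``; the last logit is pinned at 0."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.theta, dtype=float).ravel()
        if t.size < 1:
            raise ValueError("need at least one free logit (n >= 2)")
        if not np.isfinite(t).all():
            raise ValueError("logits must be finite")
        object.__setattr__(self, "theta", t)

    @property
    def n_states(self) -> int:
        return self.theta.size + 1


@dataclass(frozen=True)
class TabularValue:
    """Tabular value function ``V(x) = psi[x]``."""

    psi: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.psi, dtype=float).ravel()
        if not np.isfinite(p).all():
            raise ValueError("value entries must be finite")
        object.__setattr__(self, "psi", p)

    @property
    def n_states(self) -> int:
        return self.psi.size


def policy_distribution(pol: SoftmaxPolicy) -> Distribution:
    """The distribution ``alpha_theta(i) = e^{theta_i} / (sum_j e^{theta_j} + 1)``."""
    return Distribution(_softmax_probs(pol.theta))


def _softmax_probs(theta: np.ndarray) -> np.ndarray:
    full = np.append(theta, 0.0)
    full = full - full.max()          # log-sum-exp shift
    e = np.exp(full)
    return e / e.sum()


def logits_for_distribution(alpha: Distribution) -> SoftmaxPolicy:
    """Inverse of :func:`policy_distribution` for strictly positive ``alpha``."""
    p = alpha.probs
    if np.any(p <= 0):
        raise ValueError("distribution must be strictly positive")
    return SoftmaxPolicy(np.log(p[:-1]) - np.log(p[-1]))


def policy_jacobian(pol: SoftmaxPolicy) -> np.ndarray:
    """``J[i, j] = d alpha_i / d theta_j = alpha_i (1{i=j} - alpha_j)``.

    Shape ``(n, n-1)``; every column sums to zero.
    """
    a = _softmax_probs(pol.theta)
    n = a.size
    J = -np.outer(a, a[: n - 1])
    J[np.arange(n - 1), np.arange(n - 1)] += a[: n - 1]
    return J


# ---------------------------------------------------------------------------
# reward and exact quantities


def _alpha_beta(K: SubMarkovKernel, pol: SoftmaxPolicy):
    alpha = policy_distribution(pol)
    beta = one_step_distribution(alpha, K)
    return alpha, beta


def reward(K: SubMarkovKernel, pol: SoftmaxPolicy, x: int, y: int) -> float:
    """``R(x, y) = -ln(K_alpha(x, y) / K_beta(x, y))`` for a samplable pair."""
    alpha, beta = _alpha_beta(K, pol)
    ka = K.mass[x, y] + K.absorption[x] * alpha.probs[y]
    kb = K.mass[x, y] + K.absorption[x] * beta.probs[y]
    if ka <= 0:
        raise ValueError(f"transition ({x}, {y}) has zero probability under "
                         "K_alpha and cannot be sampled")
    return float(np.log(max(kb, _LOG_FLOOR)) - np.log(max(ka, _LOG_FLOOR)))


def _reward_matrix(K: SubMarkovKernel, alpha: Distribution,
                   beta: Distribution) -> np.ndarray:
    """Entrywise ``R(x, y)`` with zeros at unsamplable pairs."""
    Ka = K.mass + np.outer(K.absorption, alpha.probs)
    Kb = K.mass + np.outer(K.absorption, beta.probs)
    mask = Ka > 0
    R = np.zeros_like(Ka)
    R[mask] = np.log(Kb[mask]) - np.log(Ka[mask])
    return R


def average_reward_exact(K: SubMarkovKernel, pol: SoftmaxPolicy) -> float:
    """``r(theta) = sum_{x,y} mu(x) K_alpha(x,y) R(x,y)``; always <= 0."""
    alpha, beta = _alpha_beta(K, pol)
    Pa = make_regenerative(K, alpha)
    mu = exact_stationary(Pa)
    R = _reward_matrix(K, alpha, beta)
    return float(np.sum(mu.probs[:, None] * Pa.matrix * R))


def value_exact(K: SubMarkovKernel, pol: SoftmaxPolicy) -> TabularValue:
    """Solve the Bellman system for the differential value function.

    ``(I - K_alpha) V = c`` with ``c(x) = sum_y K_alpha(x,y) R(x,y) - r``
    is rank-deficient by one; the centering row ``mu . V = 0`` pins the
    solution demanded by the series definition of ``V``.
    """
    alpha, beta = _alpha_beta(K, pol)
    Pa = make_regenerative(K, alpha)
    mu = exact_stationary(Pa)
    R = _reward_matrix(K, alpha, beta)
    r = float(np.sum(mu.probs[:, None] * Pa.matrix * R))
    n = K.n_states
    c = (Pa.matrix * R).sum(axis=1) - r
    A = np.vstack([np.eye(n) - Pa.matrix, mu.probs])
    b = np.append(c, 0.0)
    V, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = np.abs((np.eye(n) - Pa.matrix) @ V - c).max()
    if resid > 1e-8:
        raise ArithmeticError(f"Bellman residual {resid:.3e} too large")
    return TabularValue(V)


# ---------------------------------------------------------------------------
# gradients


def grad_log_regen(K: SubMarkovKernel, pol: SoftmaxPolicy,
                   x: int, y: int) -> np.ndarray:
    """``d ln K_alpha(x, y) / d theta``; zero when state ``x`` cannot absorb."""
    alpha = policy_distribution(pol)
    ka = K.mass[x, y] + K.absorption[x] * alpha.probs[y]
    if ka <= 0:
        raise ValueError(f"transition ({x}, {y}) has zero probability")
    J = policy_jacobian(pol)
    return K.absorption[x] * J[y] / ka


def _beta_jacobian(K: SubMarkovKernel, pol: SoftmaxPolicy) -> np.ndarray:
    """``d beta(y) / d theta_j`` as an ``(n, n-1)`` matrix."""
    alpha = policy_distribution(pol).probs
    J = policy_jacobian(pol)
    s = float(alpha @ K.absorption)
    # beta(y) = (alpha K)(y) + s alpha(y); differentiate each factor
    return (K.mass.T @ J) + s * J + np.outer(alpha, K.absorption @ J)


def grad_log_onestep(K: SubMarkovKernel, pol: SoftmaxPolicy,
                     x: int, y: int) -> np.ndarray:
    """``d ln K_beta(x, y) / d theta``; zero when state ``x`` cannot absorb."""
    alpha, beta = _alpha_beta(K, pol)
    kb = K.mass[x, y] + K.absorption[x] * beta.probs[y]
    if kb <= 0:
        raise ValueError(f"transition ({x}, {y}) has zero probability")
    dbeta = _beta_jacobian(K, pol)
    return K.absorption[x] * dbeta[y] / kb


def policy_gradient_exact(K: SubMarkovKernel, pol: SoftmaxPolicy,
                          baseline: float | None = None) -> np.ndarray:
    """Exact gradient of the average reward.

    ``grad r = E[(R(X,Y) - b + V(Y) - V(X)) d ln K_alpha(X,Y)
               + d ln K_beta(X,Y)]`` over ``(X, Y) ~ mu (x) K_alpha(x, .)``.
    The baseline ``b`` defaults to ``r(theta)``; by row-sum conservation any
    constant gives the same value.
    """
    alpha, beta = _alpha_beta(K, pol)
    Pa = make_regenerative(K, alpha)
    mu = exact_stationary(Pa).probs
    R = _reward_matrix(K, alpha, beta)
    r = float(np.sum(mu[:, None] * Pa.matrix * R))
    b = r if baseline is None else float(baseline)
    V = value_exact(K, pol).psi
    J = policy_jacobian(pol)
    dbeta = _beta_jacobian(K, pol)
    a = K.absorption
    Kb = K.mass + np.outer(a, beta.probs)

    # term 1: sum_{x,y} mu(x) K_alpha(x,y) delta(x,y) a(x) J[y,:] / K_alpha(x,y)
    #       = sum_y (sum_x mu(x) a(x) delta(x,y)) J[y,:]
    delta = R - b + V[None, :] - V[:, None]
    w = (mu * a) @ delta                      # length n, but only where samplable
    # unsamplable (K_alpha = 0) pairs have a(x) = 0 or alpha(y) = 0; alpha > 0
    # under the softmax, so the a(x) factor already zeroes them out.
    g1 = w @ J

    # term 2: sum_{x,y} mu(x) K_alpha(x,y) a(x) dbeta[y,:] / K_beta(x,y)
    W = (mu * a)[:, None] * np.divide(Pa.matrix, Kb,
                                      out=np.zeros_like(Kb), where=Kb > 0)
    g2 = W.sum(axis=0) @ dbeta
    return g1 + g2


def policy_gradient_fd(K: SubMarkovKernel, pol: SoftmaxPolicy,
                       h: float = 1e-5) -> np.ndarray:
    """Central finite differences of :func:`average_reward_exact`."""
    if h <= 0:
        raise ValueError("step h must be positive")
    theta = pol.theta
    g = np.empty_like(theta)
    for j in range(theta.size):
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        g[j] = (average_reward_exact(K, SoftmaxPolicy(tp))
                - average_reward_exact(K, SoftmaxPolicy(tm))) / (2 * h)
    return g
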