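"""Benchmark absorbing chains: loopy chain, absorbed M/M/1/N queue,
SIS-style extinction chain, and random strictly sub-Markovian instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .chain_core import SubMarkovKernel

__all__ = [
    "QueueSpec",
    "loopy_chain",
    "mm1_queue",
    "linear_drift_rho",
    "sis_extinction_chain",
    "random_submarkov",
]


def loopy_chain(eps: float, m: int = 3) -> SubMarkovKernel:
    """Fully connected ``m``-state chain leaking mass ``eps`` from every state.

    ``K(x, y) = (1 - eps) / m`` for all live ``x, y``; the QSD is uniform
    for every ``eps`` by symmetry.
    """
    if not 0.0 < eps < 1.0:
        raise ValueError(f"eps must lie in (0, 1), got {eps}")
    if m < 2:
        raise ValueError("need at least 2 live states")
    return SubMarkovKernel(np.full((m, m), (1.0 - eps) / m))


@dataclass(frozen=True)
class QueueSpec:
    """Capacity and drift ratios for the absorbed M/M/1/N queue.

    ``rho`` may be a scalar (broadcast to all levels) or a length-``N``
    vector; only ``rho[0:N-1]`` enter the transition probabilities
    ``lambda_i = rho_i / (rho_i + 1)`` (up) and ``mu_i = 1 / (rho_i + 1)``
    (down).
    """

    capacity: int
    rho: Union[float, np.ndarray]

    def __post_init__(self) -> None:
        if self.capacity < 3:
            raise ValueError("capacity must be at least 3")
        r = np.asarray(self.rho, dtype=float)
        if r.ndim == 0:
            r = np.full(self.capacity, float(r))
        if r.size != self.capacity:
            raise ValueError(
                f"rho must be scalar or length {self.capacity}, got {r.size}")
        if np.any(r <= 0):
            raise ValueError("all rho_i must be positive")
        object.__setattr__(self, "rho", r)


def linear_drift_rho(N: int) -> np.ndarray:
    """State-dependent drift ``rho_i = 2 - 3 (i - 1) / (2 N - 4)``, 1-based ``i``.

    Crosses ``rho = 1`` near ``i = 2 N / 3``, so the QSD develops an
    interior peak there instead of a right boundary layer.
    """
    i = np.arange(1, N + 1, dtype=float)
    return 2.0 - 3.0 * (i - 1.0) / (2.0 * N - 4.0)


def mm1_queue(spec: QueueSpec) -> SubMarkovKernel:
    """Birth-death queue on levels ``1..N`` absorbed at level 0.

    Level 1 moves up with probability ``lambda_1`` and is absorbed with
    probability ``mu_1``; interior levels move up/down with
    ``lambda_i`` / ``mu_i``; level ``N`` reflects to ``N - 1`` surely.
    Only level 1 leaks mass.
    """
    N = spec.capacity
    rho = np.asarray(spec.rho)
    lam = rho / (rho + 1.0)
    mu = 1.0 / (rho + 1.0)
    K = np.zeros((N, N))
    K[0, 1] = lam[0]                       # level 1 up; down is absorption
    for i in range(1, N - 1):              # interior levels 2..N-1 (1-based)
        K[i, i - 1] = mu[i]
        K[i, i + 1] = lam[i]
    K[N - 1, N - 2] = 1.0                  # reflecting top level
    return SubMarkovKernel(K)


def sis_extinction_chain(N: int, beta: float, gamma: float,
                         uniformization: float | None = None) -> SubMarkovKernel:
    """Discrete-time SIS birth-death chain on ``1..N`` infected, absorbed at 0.

    Up rate ``b_i = beta * i * (N - i) / N``, down rate ``d_i = gamma * i``,
    divided by a uniformization constant (default ``max_i(b_i + d_i)``) so
    rows sum to at most one.  The only leak is the recovery of the last
    infected individual (state 1 down to extinction).
    """
    if N < 2:
        raise ValueError("need at least 2 live states")
    if beta < 0 or gamma <= 0:
        raise ValueError("rates must be positive (beta may be 0)")
    i = np.arange(1, N + 1, dtype=float)
    b = beta * i * (N - i) / N
    d = gamma * i
    C = uniformization if uniformization is not None else float((b + d).max())
    if C <= 0:
        raise ValueError("uniformization constant must be positive")
    excess = b + d - C
    if np.any(excess > 1e-12):
        bad = int(np.argmax(excess))
        raise ValueError(
            f"rates at state {bad + 1} exceed the uniformization constant "
            f"({b[bad] + d[bad]:.4g} > {C:.4g})")
    p_up = b / C
    p_down = d / C
    K = np.zeros((N, N))
    for k in range(N):
        if k + 1 < N:
            K[k, k + 1] = p_up[k]
        if k - 1 >= 0:
            K[k, k - 1] = p_down[k]
        K[k, k] = max(0.0, 1.0 - p_up[k] - p_down[k])
    # state 1 loses its down-step to absorption; all other rows sum to 1
    return SubMarkovKernel(K)


def random_submarkov(n: int, leak_states: int, density: float,
                     seed: int) -> SubMarkovKernel:
    """Random irreducible strictly sub-Markovian kernel, reproducible by seed.

    Exactly ``leak_states`` rows have row sum below one (leaks between 5%
    and 30% of the row mass).  Irreducibility is guaranteed by overlaying a
    cyclic permutation before row normalisation.
    """
    if not 1 <= leak_states <= n:
        raise ValueError("need 1 <= leak_states <= n")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    M = rng.random((n, n)) * (rng.random((n, n)) < density)
    cycle = np.roll(np.eye(n), 1, axis=1)
    M = M + 0.3 * cycle                   # forces a Hamiltonian cycle
    M = M / M.sum(axis=1, keepdims=True)
    leak_idx = rng.choice(n, size=leak_states, replace=False)
    leak = rng.uniform(0.05, 0.3, size=leak_states)
    M[leak_idx] *= (1.0 - leak)[:, None]
    K = SubMarkovKernel(M)
    assert K.is_irreducible()
    return K
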