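"""Canonical benchmark runs for the absorbed M/M/1/500 queue.

Both benchmarks learn the QSD with the actor-critic at the published
hyperparameter settings and report the final L2 error against the exact
eigenvector QSD.  Absorption happens only at the bottom level, so every
batch transition is sampled from there (``source_state=0``); transitions
out of any other state carry zero reward and zero gradient.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .actor_critic import ACConfig, LearningRateSchedule, RunTrace, run_actor_critic
from .chain_core import Distribution, SubMarkovKernel, exact_qsd
from .experiments import ramp_logits
from .model_zoo import QueueSpec, linear_drift_rho, mm1_queue

__all__ = [
    "QUEUE_N",
    "constant_rho_theta0",
    "linear_drift_theta0",
    "queue_constant_rho_run",
    "queue_linear_drift_run",
]

QUEUE_N = 500


def constant_rho_theta0(N: int = QUEUE_N) -> np.ndarray:
    """Published ramp init for the constant-drift case:
    ``theta_i = -35 + 35 (i-1) / 498`` for ``i <= N-2``, ``theta_{N-1} = 3``."""
    theta = -35.0 + 35.0 / (N - 2) * np.arange(N - 2)
    return np.append(theta, 3.0)


def linear_drift_theta0(N: int = QUEUE_N) -> np.ndarray:
    """Documented ramp init for the state-dependent-drift case: rise 8 -> 44
    peaking at ``i = 2N/3``, fall to 18 at the last free logit."""
    return ramp_logits(N - 1, int(round(2 * N / 3)) - 1, 8.0, 44.0, 18.0)


def _run(K: SubMarkovKernel, theta0: np.ndarray, lr_theta: float,
         batch_size: int, n_iterations: int, seed: int,
         reference: Optional[Distribution], eval_every: int,
         ) -> tuple[float, RunTrace]:
    if reference is None:
        reference, _ = exact_qsd(K)
    cfg = ACConfig(
        lr_theta=LearningRateSchedule("constant", base=lr_theta),
        lr_psi=LearningRateSchedule("constant", base=1e-4),
        lr_r=LearningRateSchedule("constant", base=1e-4),
        batch_size=batch_size, n_iterations=n_iterations, seed=seed,
        eval_every=eval_every, source_state=0, theta0=theta0)
    _, trace = run_actor_critic(K, cfg, reference=reference)
    return trace.final_error, trace


def queue_constant_rho_run(seed: int, n_iterations: int = 30_000,
                           N: int = QUEUE_N,
                           reference: Optional[Distribution] = None,
                           eval_every: int = 5000) -> tuple[float, RunTrace]:
    """M/M/1/N queue, ``rho = 1.25``: lr_theta 3e-4, batch 64, ramp init."""
    K = mm1_queue(QueueSpec(N, 1.25))
    return _run(K, constant_rho_theta0(N), 3e-4, 64, n_iterations, seed,
                reference, eval_every)


def queue_linear_drift_run(seed: int, n_iterations: int = 40_000,
                           N: int = QUEUE_N,
                           reference: Optional[Distribution] = None,
                           eval_every: int = 5000) -> tuple[float, RunTrace]:
    """M/M/1/N queue, ``rho_i = 2 - 3(i-1)/(2N-4)``: lr_theta 2e-4, batch 128."""
    K = mm1_queue(QueueSpec(N, linear_drift_rho(N)))
    return _run(K, linear_drift_theta0(N), 2e-4, 128, n_iterations, seed,
                reference, eval_every)
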