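"""Reviewed baseline estimators of the quasi-stationary distribution.

Four schemes, all driven by absorbed-episode simulation of the extended
kernel:

* ``run_vanilla`` — the single-particle empirical scheme: the estimate is
  the cumulative occupation fraction (total visits / total time) over all
  episodes, each episode starting from the current estimate.
* ``run_projection`` — projected stochastic approximation: move the
  estimate toward the episode occupation fraction with step ``eps_n`` and
  project back onto the probability simplex.
* ``polyak_average`` — running mean of a sequence of iterates.
* ``run_fleming_viot`` — N interacting particles; an absorbed particle
  instantly adopts the pre-update position of a uniformly chosen survivor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .actor_critic import LearningRateSchedule, RunTrace
from .chain_core import Distribution, SubMarkovKernel, exact_qsd

__all__ = [
    "EpisodeResult",
    "simplex_project",
    "run_episode",
    "run_vanilla",
    "run_projection",
    "polyak_average",
    "run_fleming_viot",
]

StepSchedule = Union[str, float, LearningRateSchedule,
                     Callable[[int], float]]


@dataclass(frozen=True)
class EpisodeResult:
    """Visit counts of one absorbed episode; ``sum(visit_counts) == tau``."""

    visit_counts: np.ndarray
    tau: int

    def __post_init__(self) -> None:
        v = np.asarray(self.visit_counts)
        if self.tau < 1:
            raise ValueError("extinction time must be positive")
        if int(v.sum()) != self.tau:
            raise ValueError("visit counts must sum to the extinction time")
        object.__setattr__(self, "visit_counts", v)


def simplex_project(v: np.ndarray) -> Distribution:
    """Euclidean projection onto the probability simplex.

    Sort-and-threshold algorithm, O(m log m): sort descending, find the
    largest ``j`` with ``v_(j) + (1 - sum_{i<=j} v_(i)) / j > 0``, shift the
    top-``j`` entries by the corresponding multiplier and clip at zero.
    """
    v = np.asarray(v, dtype=float).ravel()
    if not np.isfinite(v).all():
        raise ValueError("entries must be finite")
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    j = np.arange(1, v.size + 1)
    cond = u + (1.0 - css) / j > 0
    rho = int(np.nonzero(cond)[0][-1])
    lam = (1.0 - css[rho]) / (rho + 1)
    w = np.clip(v + lam, 0.0, None)
    return Distribution(w / w.sum())


def run_episode(K: SubMarkovKernel, alpha0: Distribution,
                rng: np.random.Generator,
                _row_cum: Optional[np.ndarray] = None) -> EpisodeResult:
    """Simulate one chain under the extended kernel until absorption.

    Starts from ``X0 ~ alpha0``; counts visits to each live state over
    ``X_0 .. X_{tau-1}``.
    """
    n = K.n_states
    row_cum = np.cumsum(K.mass, axis=1) if _row_cum is None else _row_cum
    counts = np.zeros(n, dtype=np.int64)
    x = int(np.searchsorted(np.cumsum(alpha0.probs), rng.random(),
                            side="right"))
    x = min(x, n - 1)
    while True:
        counts[x] += 1
        cum = row_cum[x]
        u = rng.random()
        if u >= cum[-1]:
            break                                    # absorbed
        x = int(np.searchsorted(cum, u, side="right"))
    return EpisodeResult(visit_counts=counts, tau=int(counts.sum()))


def _resolve_schedule(eps_n: StepSchedule) -> Callable[[int], float]:
    if callable(eps_n):
        return eps_n
    sched = LearningRateSchedule.parse(eps_n)
    return sched.rate


def run_vanilla(K: SubMarkovKernel, n_episodes: int, seed: int,
                alpha0: Optional[Distribution] = None,
                reference: Optional[Distribution] = None,
                eval_every: int = 100,
                recursive: bool = False,
                ) -> tuple[Distribution, RunTrace]:
    """Single-particle empirical scheme.

    Default form maintains the cumulative occupation fraction
    ``alpha_n = (total visits) / (total time)``, which satisfies the
    weighted-average recursion
    ``alpha_{n+1} = alpha_n + (counts - tau * alpha_n) / sum_j tau(j)``
    exactly.  ``recursive=True`` runs that recursion explicitly instead
    (kept for comparison; algebraically identical).
    """
    if n_episodes < 1:
        raise ValueError("need at least one episode")
    n = K.n_states
    rng = np.random.default_rng(seed)
    if reference is None:
        reference, _ = exact_qsd(K)
    ref = reference.probs
    row_cum = np.cumsum(K.mass, axis=1)
    alpha = (alpha0 or Distribution.uniform(n)).probs.copy()
    total_counts = np.zeros(n, dtype=np.int64)
    total_time = 0
    trace = RunTrace()
    for ep in range(1, n_episodes + 1):
        res = run_episode(K, Distribution(alpha), rng, _row_cum=row_cum)
        total_time += res.tau
        if recursive:
            alpha = alpha + (res.visit_counts - res.tau * alpha) / total_time
            alpha = alpha / alpha.sum()
        else:
            total_counts += res.visit_counts
            alpha = total_counts / total_time
        if ep % eval_every == 0 or ep == n_episodes:
            trace.append(ep, float(np.linalg.norm(alpha - ref)))
    return Distribution(alpha), trace


def run_projection(K: SubMarkovKernel, eps_n: StepSchedule, n_episodes: int,
                   seed: int,
                   alpha0: Optional[Distribution] = None,
                   reference: Optional[Distribution] = None,
                   eval_every: int = 100,
                   normalized: bool = True,
                   collect_iterates: bool = False,
                   ) -> tuple[Distribution, RunTrace, Optional[np.ndarray]]:
    """Projected stochastic approximation on the simplex.

    ``alpha_{n+1} = Proj(alpha_n + eps_n * (innovation - alpha_n))``.  The
    default innovation is the episode occupation fraction ``counts / tau``,
    which has the QSD as its unique stable point; ``normalized=False`` uses
    the raw visit counts instead (the typeset form of the reviewed scheme,
    kept for comparison -- its drift degenerates whenever the expected
    occupation profile is flat, so it is not the default).
    """
    if n_episodes < 1:
        raise ValueError("need at least one episode")
    step = _resolve_schedule(eps_n)
    n = K.n_states
    rng = np.random.default_rng(seed)
    if reference is None:
        reference, _ = exact_qsd(K)
    ref = reference.probs
    row_cum = np.cumsum(K.mass, axis=1)
    alpha = (alpha0 or Distribution.uniform(n)).probs.copy()
    trace = RunTrace()
    iterates = np.empty((n_episodes, n)) if collect_iterates else None
    for ep in range(1, n_episodes + 1):
        res = run_episode(K, Distribution(alpha), rng, _row_cum=row_cum)
        innov = (res.visit_counts / res.tau if normalized
                 else res.visit_counts.astype(float))
        alpha = simplex_project(alpha + step(ep) * (innov - alpha)).probs
        if iterates is not None:
            iterates[ep - 1] = alpha
        if ep % eval_every == 0 or ep == n_episodes:
            trace.append(ep, float(np.linalg.norm(alpha - ref)))
    return Distribution(alpha), trace, iterates


def polyak_average(iterates: Union[np.ndarray, Sequence[np.ndarray]],
                   reference: Optional[Distribution] = None,
                   eval_every: int = 100) -> tuple[Distribution, RunTrace]:
    """Running mean ``nu_n = (1/n) sum_{k<=n} alpha_k``, built incrementally."""
    arr = np.asarray(iterates, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a nonempty sequence of iterates")
    ref = reference.probs if reference is not None else None
    nu = np.zeros(arr.shape[1])
    trace = RunTrace()
    for k in range(1, arr.shape[0] + 1):
        nu += (arr[k - 1] - nu) / k
        if ref is not None and (k % eval_every == 0 or k == arr.shape[0]):
            trace.append(k, float(np.linalg.norm(nu - ref)))
    return Distribution(nu / nu.sum()), trace


def run_fleming_viot(K: SubMarkovKernel, n_particles: int, n_steps: int,
                     seed: int,
                     reference: Optional[Distribution] = None,
                     eval_every: int = 50,
                     ) -> tuple[Distribution, Distribution, RunTrace]:
    """Fleming-Viot particle system.

    All particles move synchronously one extended-kernel step per round;
    each absorbed particle adopts the pre-update position of a uniformly
    chosen surviving particle.  Returns the final-time empirical law, the
    empirical law time-averaged over the second half of the run, and an
    error trace of the running (second-half) time average when a reference
    is available.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    if n_steps < 2:
        raise ValueError("need at least 2 steps")
    n = K.n_states
    rng = np.random.default_rng(seed)
    ref = reference.probs if reference is not None else None
    row_cum = np.cumsum(K.mass, axis=1)
    pos = rng.integers(0, n, size=n_particles)
    half = n_steps // 2
    avg_counts = np.zeros(n)
    n_avg = 0
    trace = RunTrace()
    for t in range(1, n_steps + 1):
        cum = row_cum[pos]
        u = rng.random(n_particles)
        new_pos = (cum <= u[:, None]).sum(axis=1)
        absorbed = new_pos >= n
        n_dead = int(absorbed.sum())
        if n_dead:
            survivors = np.flatnonzero(~absorbed)
            if survivors.size == 0:
                raise RuntimeError("all particles absorbed simultaneously")
            donors = survivors[rng.integers(0, survivors.size, size=n_dead)]
            new_pos[absorbed] = pos[donors]          # pre-update positions
        pos = new_pos
        if t > half:
            avg_counts += np.bincount(pos, minlength=n)
            n_avg += 1
            if ref is not None and (t % eval_every == 0 or t == n_steps):
                avg = avg_counts / (n_avg * n_particles)
                trace.append(t, float(np.linalg.norm(avg - ref)))
    final = np.bincount(pos, minlength=n) / n_particles
    time_avg = avg_counts / (n_avg * n_particles)
    return (Distribution(final), Distribution(time_avg), trace)
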