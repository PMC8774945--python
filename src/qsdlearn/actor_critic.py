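"""Actor-critic learning of the quasi-stationary distribution ("ac-alpha").

Each iteration advances a batch of chains one (or more) steps under the
current regenerative kernel ``K_alpha``, forms the TD error

    ``delta(X, Y) = R(X, Y) - r_t + V(Y) - V(X)``

on the final transition of each chain, and applies simultaneous updates

    ``theta <- theta + eta_theta * mean[delta * d ln K_alpha + d ln K_beta]``
    ``psi   <- psi   + eta_psi   * mean[delta * e_X]``
    ``r     <- r     + eta_r     * mean[delta]``

all evaluated at the time-``t`` parameters.  Chains persist across
iterations (warm start).  For kernels whose absorption is confined to a
few states (e.g. the absorbed queue, where only the bottom level leaks),
the gradient is supported on transitions out of those states only; setting
``source_state`` samples every batch transition from that state instead of
running free chains, which is the specialisation used for the queue
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .chain_core import Distribution, SubMarkovKernel, exact_qsd, kl_rate_exact
from .rl_objective import SoftmaxPolicy, TabularValue, _softmax_probs, reward

__all__ = [
    "LearningRateSchedule",
    "ACConfig",
    "ACState",
    "RunTrace",
    "td_error",
    "ac_step",
    "run_actor_critic",
]

_LOG_FLOOR = 1e-300
_THETA_GUARD = 500.0


class DivergenceError(RuntimeError):
    """Raised when the policy logits blow up (step size too large)."""


@dataclass(frozen=True)
class LearningRateSchedule:
    """Step-size schedule ``eta(t)`` for ``t >= 1``.

    kinds: ``constant`` -> ``base``; ``power`` -> ``base * t**(-exponent)``;
    ``floored-power`` -> ``max(t**(-exponent), floor)``.
    """

    kind: str
    base: float = 1.0
    exponent: float = 0.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "power", "floored-power"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "constant" and self.base < 0:
            raise ValueError("constant rate must be nonnegative")
        if self.kind == "floored-power" and self.floor <= 0:
            raise ValueError("floored-power needs a positive floor")

    def rate(self, t: int) -> float:
        if t < 1:
            raise ValueError("schedule index starts at 1")
        if self.kind == "constant":
            return self.base
        if self.kind == "power":
            return self.base * t ** (-self.exponent)
        return max(t ** (-self.exponent), self.floor)

    @classmethod
    def parse(cls, spec: Union[str, float, "LearningRateSchedule"]
              ) -> "LearningRateSchedule":
        """Parse ``const:c``, ``pow:r``, ``fpow:r,c`` or a bare number."""
        if isinstance(spec, LearningRateSchedule):
            return spec
        if isinstance(spec, (int, float)):
            return cls("constant", base=float(spec))
        kind, _, rest = spec.partition(":")
        try:
            if kind == "const":
                return cls("constant", base=float(rest))
            if kind == "pow":
                return cls("power", exponent=float(rest))
            if kind == "fpow":
                r, c = rest.split(",")
                return cls("floored-power", exponent=float(r), floor=float(c))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed schedule spec {spec!r}") from exc
        raise ValueError(f"unknown schedule spec {spec!r} "
                         "(expected const:c, pow:r or fpow:r,c)")


@dataclass(frozen=True)
class ACConfig:
    """Hyperparameters of one actor-critic run."""

    lr_theta: LearningRateSchedule
    lr_psi: LearningRateSchedule
    lr_r: LearningRateSchedule
    batch_size: int = 1
    burn_in_steps: int = 1
    n_iterations: int = 1000
    seed: int = 0
    eval_every: int = 100
    source_state: Optional[int] = None
    theta0: Optional[np.ndarray] = None
    psi0: Optional[np.ndarray] = None
    r0: float = 0.0
    track_kl: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.burn_in_steps < 1:
            raise ValueError("burn_in_steps must be >= 1")


@dataclass(frozen=True)
class ACState:
    """Learner state after ``t`` iterations."""

    pol: SoftmaxPolicy
    val: TabularValue
    r_est: float
    chain_states: np.ndarray
    t: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.r_est):
            raise ValueError("r_est must be finite")


@dataclass
class RunTrace:
    """Per-evaluation record of a learning run."""

    iterations: list[int] = field(default_factory=list)
    l2_error: list[float] = field(default_factory=list)
    r_est: list[float] = field(default_factory=list)
    kl_rate: list[Optional[float]] = field(default_factory=list)

    def append(self, iteration: int, l2: float, r: float = float("nan"),
               kl: Optional[float] = None) -> None:
        if self.iterations and iteration <= self.iterations[-1]:
            raise ValueError("iterations must be strictly increasing")
        self.iterations.append(int(iteration))
        self.l2_error.append(float(l2))
        self.r_est.append(float(r))
        self.kl_rate.append(kl)

    def to_csv(self, path: Union[str, Path],
               header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("iteration,l2_error,r_est,kl_rate\n")
            for i, l2, r, kl in zip(self.iterations, self.l2_error,
                                    self.r_est, self.kl_rate):
                kl_s = "" if kl is None else repr(kl)
                r_s = "" if np.isnan(r) else repr(r)
                fh.write(f"{i},{l2!r},{r_s},{kl_s}\n")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "RunTrace":
        trace = cls()
        lines = [ln for ln in Path(path).read_text().splitlines()
                 if ln and not ln.startswith("#")]
        for ln in lines[1:]:                      # skip the column header
            it, l2, r, kl = ln.split(",")
            trace.append(int(it), float(l2),
                         float(r) if r else float("nan"),
                         float(kl) if kl else None)
        return trace

    @property
    def final_error(self) -> float:
        return self.l2_error[-1]


def td_error(K: SubMarkovKernel, pol: SoftmaxPolicy, val: TabularValue,
             r_est: float, x: int, y: int) -> float:
    """``delta = R(x, y) - r_est + V(y) - V(x)``."""
    return reward(K, pol, x, y) - r_est + float(val.psi[y] - val.psi[x])


# ---------------------------------------------------------------------------
# hot loop


class _ACContext:
    """Per-run precomputation shared across iterations (kernel is fixed)."""

    def __init__(self, K: SubMarkovKernel):
        self.K = K
        self.n = K.n_states
        self.a = K.absorption
        self.Kdense = K.mass
        self.KT = np.ascontiguousarray(K.mass.T)
        self.row_cum = np.cumsum(K.mass, axis=1)    # for two-stage sampling


def _batch_next_states(ctx: _ACContext, X: np.ndarray, alpha_cum: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Vectorised two-stage transition for every chain in ``X``."""
    cum = ctx.row_cum[X]                            # (B, n)
    u = rng.random(X.size)
    Y = (cum <= u[:, None]).sum(axis=1)
    absorbed = Y >= ctx.n
    if absorbed.any():
        u2 = rng.random(int(absorbed.sum()))
        Y[absorbed] = np.searchsorted(alpha_cum, u2, side="right")
    return Y


def ac_step(K: SubMarkovKernel, state: ACState, cfg: ACConfig,
            rng: np.random.Generator,
            _ctx: Optional[_ACContext] = None) -> ACState:
    """One actor-critic iteration; returns the successor state.

    All three updates use the time-``t`` parameters and are applied
    simultaneously; the batch contributes through its mean.
    """
    ctx = _ctx if _ctx is not None else _ACContext(K)
    n, a = ctx.n, ctx.a
    theta = state.pol.theta
    psi = state.val.psi
    t = state.t + 1                                  # schedules index from 1

    alpha = _softmax_probs(theta)
    alpha_cum = np.cumsum(alpha)
    s = float(alpha @ a)
    alphaK = alpha @ ctx.Kdense
    beta = alphaK + s * alpha

    # --- sample the batch ------------------------------------------------
    if cfg.source_state is not None:
        X = np.full(cfg.batch_size, cfg.source_state, dtype=np.int64)
        Y = _batch_next_states(ctx, X, alpha_cum, rng)
        new_chains = Y
    else:
        chains = state.chain_states
        for _ in range(cfg.burn_in_steps):
            X = chains
            chains = _batch_next_states(ctx, X, alpha_cum, rng)
        Y = chains
        new_chains = Y

    # --- per-sample reward and TD error ----------------------------------
    Kxy = ctx.Kdense[X, Y]
    aX = a[X]
    ka = Kxy + aX * alpha[Y]
    kb = Kxy + aX * beta[Y]
    R = np.log(np.maximum(kb, _LOG_FLOOR)) - np.log(np.maximum(ka, _LOG_FLOOR))
    delta = R - state.r_est + psi[Y] - psi[X]

    # --- actor gradient estimate ------------------------------------------
    # d ln K_alpha(x,y)/d theta_j = a(x) alpha_y (1{y=j} - alpha_j) / K_alpha
    # d ln K_beta(x,y)/d theta_j  = a(x) dbeta(y)_j / K_beta with
    # dbeta(y)_j = alpha_j (K(j,y) - (alpha K)(y) + (a_j - 2 s) alpha_y)
    #              + s alpha_y 1{y=j}
    af = alpha[: n - 1]
    c1 = delta * aX * alpha[Y] / ka
    c2 = aX / kb
    M = ctx.KT[Y][:, : n - 1]                        # (B, n-1): K(j, Y_i)
    G = c2[:, None] * (af[None, :]
                       * (M - alphaK[Y][:, None]
                          + (a[: n - 1] - 2.0 * s)[None, :] * alpha[Y][:, None]))
    np.subtract(G, np.outer(c1, af), out=G)
    in_chart = Y < n - 1                             # pinned logit has no e_y
    idx = np.flatnonzero(in_chart)
    G[idx, Y[idx]] += c1[idx] + c2[idx] * s * alpha[Y[idx]]
    g_theta = G.mean(axis=0)

    # --- simultaneous updates ---------------------------------------------
    new_theta = theta + cfg.lr_theta.rate(t) * g_theta
    if np.abs(new_theta).max() > _THETA_GUARD:
        raise DivergenceError(
            f"|theta| exceeded {_THETA_GUARD} at iteration {t}; "
            "reduce the actor step size")
    d_psi = np.zeros(n)
    np.add.at(d_psi, X, delta)
    new_psi = psi + cfg.lr_psi.rate(t) * d_psi / cfg.batch_size
    new_r = state.r_est + cfg.lr_r.rate(t) * float(delta.mean())

    return ACState(pol=SoftmaxPolicy(new_theta), val=TabularValue(new_psi),
                   r_est=new_r, chain_states=new_chains, t=t)


def initial_state(K: SubMarkovKernel, cfg: ACConfig,
                  rng: np.random.Generator) -> ACState:
    """Initial learner state; chains are drawn from ``alpha_{theta_0}``."""
    n = K.n_states
    theta0 = (np.zeros(n - 1) if cfg.theta0 is None
              else np.asarray(cfg.theta0, dtype=float))
    if theta0.size != n - 1:
        raise ValueError(f"theta0 must have length {n - 1}")
    psi0 = (np.zeros(n) if cfg.psi0 is None
            else np.asarray(cfg.psi0, dtype=float))
    alpha0 = _softmax_probs(theta0)
    if cfg.source_state is not None:
        chains = np.full(cfg.batch_size, cfg.source_state, dtype=np.int64)
    else:
        chains = np.searchsorted(np.cumsum(alpha0),
                                 rng.random(cfg.batch_size), side="right")
        chains = np.minimum(chains, n - 1).astype(np.int64)
    return ACState(pol=SoftmaxPolicy(theta0), val=TabularValue(psi0),
                   r_est=cfg.r0, chain_states=chains, t=0)


def run_actor_critic(K: SubMarkovKernel, cfg: ACConfig,
                     reference: Optional[Distribution] = None
                     ) -> tuple[SoftmaxPolicy, RunTrace]:
    """Run ``cfg.n_iterations`` actor-critic steps and record an error trace."""
    if reference is None:
        reference, _ = exact_qsd(K)
    ref = reference.probs
    rng = np.random.default_rng(cfg.seed)
    ctx = _ACContext(K)
    state = initial_state(K, cfg, rng)
    trace = RunTrace()

    def record(st: ACState) -> None:
        alpha = _softmax_probs(st.pol.theta)
        l2 = float(np.linalg.norm(alpha - ref))
        kl = None
        if cfg.track_kl:
            kl = kl_rate_exact(K, Distribution(alpha))
        trace.append(st.t if st.t > 0 else 0, l2, st.r_est, kl)

    for _ in range(cfg.n_iterations):
        state = ac_step(K, state, cfg, rng, _ctx=ctx)
        if state.t % cfg.eval_every == 0 or state.t == cfg.n_iterations:
            record(state)
    return state.pol, trace
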