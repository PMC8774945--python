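"""Sub-Markovian kernels, their regenerative extensions, and exact solvers.

A strictly sub-Markovian kernel ``K`` on states ``{0, ..., n-1}`` has
nonnegative entries and row sums at most one, with at least one row summing
to strictly less than one.  The per-state deficit ``a(x) = 1 - sum_y K(x, y)``
is the probability of one-step absorption into the external cemetery state.
Given a probability vector ``alpha``, the regenerative kernel

    ``K_alpha(x, y) = K(x, y) + a(x) * alpha(y)``

is Markovian on the live states: upon absorption the chain restarts from
``alpha``.  The quasi-stationary distribution (QSD) of ``K`` is the unique
``alpha`` that is stationary for its own regenerative kernel, equivalently
the normalised principal left eigenvector of ``K``.

All states are 0-based in the Python API; text files written/read by
:func:`SubMarkovKernel.save` / :func:`SubMarkovKernel.load` are plain
delimited matrices, so external numbering is purely positional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Distribution",
    "SubMarkovKernel",
    "RegenerativeKernel",
    "make_regenerative",
    "one_step_distribution",
    "exact_qsd",
    "exact_stationary",
    "sample_transition",
    "kl_rate_exact",
]

_ROW_SUM_TOL = 1e-12
_DIST_TOL = 1e-9
_RESIDUAL_TOL = 1e-10


class ReducibleKernelError(ValueError):
    """Raised when a kernel operation requires irreducibility it lacks."""


@dataclass(frozen=True)
class Distribution:
    """A probability vector on the live states.

    Entries must be nonnegative and sum to one within ``1e-9``.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float).ravel()
        object.__setattr__(self, "probs", p)
        if p.size == 0:
            raise ValueError("empty distribution")
        if np.any(p < 0):
            raise ValueError(f"negative probability entries: min={p.min()!r}")
        s = p.sum()
        if abs(s - 1.0) > _DIST_TOL:
            raise ValueError(f"probabilities sum to {s!r}, not 1")

    @property
    def n_states(self) -> int:
        return self.probs.size

    @classmethod
    def uniform(cls, n: int) -> "Distribution":
        return cls(np.full(n, 1.0 / n))

    @classmethod
    def point_mass(cls, n: int, x: int) -> "Distribution":
        p = np.zeros(n)
        p[x] = 1.0
        return cls(p)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Distribution":
        vals = np.loadtxt(path, comments="#", ndmin=1)
        return cls(vals)

    def save(self, path: Union[str, Path], header: str = "") -> None:
        np.savetxt(path, self.probs, header=header)

    def is_strictly_positive(self) -> bool:
        return bool(np.all(self.probs > 0))


@dataclass(frozen=True)
class SubMarkovKernel:
    """A strictly sub-Markovian transition matrix with its absorption vector.

    Parameters
    ----------
    mass
        ``(n, n)`` matrix of transition probabilities among live states.
    absorption
        Length-``n`` vector ``a(x) = 1 - sum_y mass[x, y]``; derived
        automatically and validated if supplied.
    """

    mass: np.ndarray
    absorption: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"kernel must be square, got shape {m.shape}")
        if np.any(m < -_ROW_SUM_TOL) or np.any(m > 1 + _ROW_SUM_TOL):
            raise ValueError("kernel entries must lie in [0, 1]")
        m = np.clip(m, 0.0, 1.0)
        row_sums = m.sum(axis=1)
        if np.any(row_sums > 1 + _ROW_SUM_TOL):
            bad = int(np.argmax(row_sums))
            raise ValueError(f"row {bad} sums to {row_sums[bad]!r} > 1")
        if not np.any(row_sums < 1 - _ROW_SUM_TOL):
            raise ValueError("kernel is Markovian: no row leaks mass "
                             "(strict sub-Markovianity required)")
        a = 1.0 - row_sums
        a[a < 0] = 0.0
        if self.absorption is not None:
            if not np.allclose(self.absorption, a, atol=1e-10):
                raise ValueError("supplied absorption vector inconsistent "
                                 "with row sums")
        object.__setattr__(self, "mass", m)
        object.__setattr__(self, "absorption", a)

    @property
    def n_states(self) -> int:
        return self.mass.shape[0]

    def is_irreducible(self) -> bool:
        """Strong connectivity of the positive-entry digraph of ``mass``."""
        graph = csr_matrix(self.mass > 0)
        n_comp, _ = connected_components(graph, directed=True,
                                         connection="strong")
        return n_comp == 1

    # -- text I/O ----------------------------------------------------------

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SubMarkovKernel":
        """Read a delimited text matrix (tab, comma or whitespace).

        Accepts either the bare ``n x n`` live-state matrix ``K`` or the
        full ``(n+1) x (n+1)`` extension whose row/column 0 is the absorbing
        state (detected by row 0 being ``(1, 0, ..., 0)``); the latter is
        stripped to ``K``.
        """
        text = Path(path).read_text()
        delim = "," if ("," in text.splitlines()[-1] or
                        "," in text.splitlines()[0]) else None
        m = np.loadtxt(path, comments="#", delimiter=delim, ndmin=2)
        if (m.shape[0] >= 2 and m[0, 0] == 1.0 and np.all(m[0, 1:] == 0)
                and np.all(m.sum(axis=1) <= 1 + _ROW_SUM_TOL)
                and m[1:, 1:].sum(axis=1).max() < 1 + _ROW_SUM_TOL
                and np.allclose(m.sum(axis=1), 1.0, atol=1e-9)):
            m = m[1:, 1:]
        return cls(m)

    def save(self, path: Union[str, Path], delimiter: str = "\t") -> None:
        np.savetxt(path, self.mass, delimiter=delimiter,
                   header=f"states={self.n_states}")


@dataclass(frozen=True)
class RegenerativeKernel:
    """The Markovian kernel ``K_alpha`` restarting from ``regen`` on absorption."""

    base: SubMarkovKernel
    regen: Distribution
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if np.any(m < -_ROW_SUM_TOL):
            raise ValueError("regenerative kernel has negative entries")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError("regenerative kernel rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


def make_regenerative(K: SubMarkovKernel, alpha: Distribution) -> RegenerativeKernel:
    """Build ``K_alpha(x, y) = K(x, y) + a(x) * alpha(y)``."""
    if alpha.n_states != K.n_states:
        raise ValueError(
            f"dimension mismatch: kernel has {K.n_states} states, "
            f"distribution has {alpha.n_states}")
    matrix = K.mass + np.outer(K.absorption, alpha.probs)
    return RegenerativeKernel(base=K, regen=alpha, matrix=matrix)


def one_step_distribution(alpha: Distribution, K: SubMarkovKernel) -> Distribution:
    """One step of the regenerative chain: ``beta = alpha @ K_alpha``.

    Expanded, ``beta(y) = (alpha @ K)(y) + s * alpha(y)`` with
    ``s = sum_x alpha(x) a(x)`` the per-step absorption mass.
    """
    if alpha.n_states != K.n_states:
        raise ValueError("dimension mismatch between alpha and K")
    a = alpha.probs
    s = float(a @ K.absorption)
    beta = a @ K.mass + s * a
    beta = beta / beta.sum()
    return Distribution(beta)


def exact_qsd(K: SubMarkovKernel,
              check_irreducible: bool = True) -> tuple[Distribution, float]:
    """Principal left eigenpair of ``K``: the QSD and its survival eigenvalue.

    Returns ``(alpha, lam)`` with ``alpha @ K = lam * alpha``,
    ``sum(alpha) = 1`` and ``lam in (0, 1)``.  Uses a dense left
    eigendecomposition and selects the eigenvalue of maximal modulus,
    whose eigenvector is sign-normalisable to a nonnegative vector by
    Perron-Frobenius when ``K`` is irreducible.
    """
    if check_irreducible and not K.is_irreducible():
        warnings.warn("kernel is not irreducible; QSD may not be unique",
                      RuntimeWarning, stacklevel=2)
    vals, vecs = np.linalg.eig(K.mass.T)
    # periodic chains (e.g. birth-death) carry -lam alongside lam at maximal
    # modulus; the Perron root is the one with the largest real part
    mods = np.abs(vals)
    near_max = np.flatnonzero(mods >= mods.max() - 1e-9)
    idx = int(near_max[np.argmax(vals[near_max].real)])
    lam = vals[idx]
    if abs(lam.imag) > 1e-10:
        raise ReducibleKernelError(
            f"principal eigenvalue {lam!r} is not real; kernel may be "
            "reducible or periodic in a degenerate way")
    lam = float(lam.real)
    v = vecs[:, idx].real
    v = v * np.sign(v.sum())
    if np.any(v < -1e-8 * max(1.0, np.abs(v).max())):
        raise ReducibleKernelError("principal eigenvector is not "
                                   "sign-definite; kernel likely reducible")
    v = np.clip(v, 0.0, None)
    alpha = Distribution(v / v.sum())
    resid = np.abs(alpha.probs @ K.mass - lam * alpha.probs).max()
    if resid > _RESIDUAL_TOL:
        raise ArithmeticError(f"eigen residual {resid:.3e} exceeds tolerance")
    # absorption can be exponentially rare, leaving lam within machine
    # epsilon of 1; tolerate that but reject genuinely Markovian spectra
    if not (0.0 < lam < 1.0 + 1e-9):
        raise ValueError(f"survival eigenvalue {lam!r} outside (0, 1)")
    return alpha, min(lam, 1.0)


def exact_stationary(P: RegenerativeKernel) -> Distribution:
    """Stationary distribution ``mu`` of a regenerative kernel: ``mu P = mu``.

    Solves the linear system ``(P^T - I) mu = 0`` with one equation replaced
    by the normalisation ``sum(mu) = 1``; falls back to the dense eigensolver
    if the direct solve is ill-conditioned.
    """
    n = P.n_states
    A = P.matrix.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        mu = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        mu = None
    if mu is None or np.any(mu < -1e-9) or not np.isfinite(mu).all():
        vals, vecs = np.linalg.eig(P.matrix.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        mu = vecs[:, idx].real
        mu = mu * np.sign(mu.sum())
    mu = np.clip(mu, 0.0, None)
    mu = mu / mu.sum()
    resid = np.abs(mu @ P.matrix - mu).max()
    if resid > _RESIDUAL_TOL:
        raise ArithmeticError(
            f"stationary residual {resid:.3e} exceeds tolerance; "
            "kernel may not be ergodic")
    return Distribution(mu)


def sample_transition(P: RegenerativeKernel, x: int,
                      rng: np.random.Generator) -> int:
    """One two-stage draw from row ``x`` of ``K_alpha``.

    First propose from the extended kernel (absorb with probability
    ``a(x)``); on absorption, redraw from the regeneration distribution.
    The marginal law of the output is row ``x`` of ``P.matrix``.
    """
    n = P.n_states
    if not (0 <= x < n):
        raise ValueError(f"state {x} out of range [0, {n})")
    row = P.base.mass[x]
    u = rng.random()
    cum = np.cumsum(row)
    if u < cum[-1]:
        return int(np.searchsorted(cum, u, side="right"))
    # absorbed: regenerate
    return int(np.searchsorted(np.cumsum(P.regen.probs), rng.random(),
                               side="right"))


def kl_rate_exact(K: SubMarkovKernel, alpha: Distribution) -> float:
    """Per-step KL divergence rate between the paths of ``K_alpha`` and ``K_beta``.

    With ``beta = alpha @ K_alpha`` and ``mu`` stationary for ``K_alpha``,
    returns ``sum_{x,y} mu(x) K_alpha(x,y) ln(K_alpha(x,y) / K_beta(x,y))``.
    Zero exactly when ``alpha`` is the QSD; always nonnegative.
    """
    if alpha.n_states != K.n_states:
        raise ValueError("dimension mismatch between alpha and K")
    if not alpha.is_strictly_positive():
        raise ValueError("alpha must be strictly positive for a finite "
                         "KL rate")
    Pa = make_regenerative(K, alpha)
    beta = one_step_distribution(alpha, K)
    Pb = make_regenerative(K, beta)
    mu = exact_stationary(Pa)
    A, B = Pa.matrix, Pb.matrix
    mask = A > 0
    ratio = np.ones_like(A)
    ratio[mask] = A[mask] / B[mask]
    rate = float(np.sum(mu.probs[:, None] * A * np.log(ratio), where=mask))
    return max(rate, 0.0)
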