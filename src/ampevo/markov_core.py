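"""Generator and probability-matrix algebra for continuous-time Markov chains.

A substitution process on a finite alphabet is specified by an N x N
instantaneous rate matrix Q with nonnegative off-diagonal entries and rows
summing to zero; its transition probabilities are P(t) = exp(tQ).  This
module provides the algebra the rest of the package relies on:
normalization to one expected event per site per unit time, equilibrium
distributions, the matrix exponential, fractional matrix powers and the
probability-matrix-to-generator conversion needed to turn empirically
estimated probability matrices back into rate matrices.

All of these are computed from eigendecompositions.  Reversible
generators are symmetrized by the pi^(1/2) similarity transform so that a
single real orthogonal decomposition serves the exponential at every t;
this makes the exponential-family identity P(t)^e = P(t*e) exact to
rounding, which the fractional-power pipeline downstream depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "Generator",
    "ProbabilityMatrix",
    "DegenerateModelError",
    "ReducibleGeneratorError",
    "IllConditionedRootError",
    "NoValidGeneratorError",
    "make_generator",
    "normalize",
    "equilibrium",
    "transition_matrix",
    "fractional_power",
    "prob_to_generator",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


class DegenerateModelError(ValueError):
    """Raised when a generator has zero total rate and cannot be normalized."""


class ReducibleGeneratorError(ValueError):
    """Raised when a generator has no unique equilibrium distribution."""


class IllConditionedRootError(ValueError):
    """Raised when a fractional matrix power is not well defined.

    A probability matrix with an eigenvalue of non-negligible modulus and
    negative real part has no principal-branch real root; silently
    absorbing the resulting complex residue would hide genuine pathology
    in empirical matrices, so it is reported instead.
    """


class NoValidGeneratorError(ValueError):
    """Raised when a probability matrix has no principal real logarithm."""


@dataclass
class ProbabilityMatrix:
    """Row-stochastic transition-probability matrix over a labelled alphabet.

    ``time`` is the divergence (expected events per site) the matrix
    corresponds to, when known; empirical estimates carry ``time=None``.
    """

    probs: np.ndarray
    time: float | None = None
    state_space: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        n = self.probs.shape[0]
        if self.probs.shape != (n, n):
            raise ValueError("probability matrix must be square")
        rows = self.probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("rows of a probability matrix must sum to 1")

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass
class Generator:
    """Instantaneous rate matrix with its equilibrium distribution.

    ``rates`` has nonnegative off-diagonal entries and zero row sums;
    ``pi`` is the stationary distribution (``pi @ rates = 0``).  When
    ``normalized`` is true the equilibrium mean rate
    ``sum_i sum_{j != i} pi_i Q_ij`` is 1, so time is measured in
    expected substitutions per site.
    """

    rates: np.ndarray
    pi: np.ndarray
    normalized: bool = False
    state_space: tuple[str, ...] | None = None
    _decomp: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = self.rates.shape[0]
        if self.rates.shape != (n, n):
            raise ValueError("rate matrix must be square")
        off = self.rates - np.diag(np.diag(self.rates))
        if off.min() < -1e-12:
            raise ValueError("off-diagonal rates must be nonnegative")
        if not np.allclose(self.rates.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("generator rows must sum to zero")
        if self.pi.shape != (n,) or self.pi.min() < -1e-12 or not np.isclose(
            self.pi.sum(), 1.0
        ):
            raise ValueError("pi must be a distribution over the alphabet")

    @property
    def n(self) -> int:
        return self.rates.shape[0]

    @property
    def mean_rate(self) -> float:
        """Equilibrium mean substitution rate, sum_i sum_{j!=i} pi_i Q_ij."""
        return float(-np.dot(self.pi, np.diag(self.rates)))

    def is_reversible(self, tol: float = 1e-9) -> bool:
        flux = self.pi[:, None] * self.rates
        return bool(np.allclose(flux, flux.T, atol=tol * max(self.mean_rate, 1.0)))

    def _decomposition(self):
        # Reversible: eigh of diag(sqrt(pi)) Q diag(1/sqrt(pi)); otherwise
        # a general (possibly complex) eigendecomposition.
        if self._decomp is None:
            if self.pi.min() > 0 and self.is_reversible():
                d = np.sqrt(self.pi)
                sym = (d[:, None] * self.rates) / d[None, :]
                w, u = scipy.linalg.eigh((sym + sym.T) / 2.0)
                left = u / d[:, None]
                right = u.T * d[None, :]
                self._decomp = ("sym", w, left, right)
            else:
                w, v = scipy.linalg.eig(self.rates)
                self._decomp = ("gen", w, v, np.linalg.inv(v))
        return self._decomp

    def expm(self, t: float) -> np.ndarray:
        kind, w, left, right = self._decomposition()
        ew = np.exp(w * t)
        out = (left * ew[None, :]) @ right
        if kind == "gen":
            out = np.real_if_close(out, tol=1000)
            out = np.real(out)
        # rounding can leave tiny negatives at large t
        np.clip(out, 0.0, None, out=out)
        out /= out.sum(axis=1, keepdims=True)
        return out


def make_generator(
    rates: np.ndarray,
    pi: np.ndarray | None = None,
    state_space: Sequence[str] | None = None,
) -> Generator:
    """Assemble a :class:`Generator`, filling the diagonal and equilibrium.

    Off-diagonal entries of ``rates`` are used as given; the diagonal is
    recomputed as minus the row sums.  If ``pi`` is omitted it is obtained
    by solving ``pi Q = 0``.
    """
    Q = np.array(rates, dtype=float)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if pi is None:
        pi = equilibrium(Q)
    ss = tuple(state_space) if state_space is not None else None
    return Generator(rates=Q, pi=np.asarray(pi, dtype=float), state_space=ss)


def equilibrium(Q: Generator | np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Stationary distribution of a generator: the left null vector of Q.

    Raises :class:`ReducibleGeneratorError` when the null space of ``Q^T``
    is not one-dimensional (reducible or defective input).
    """
    A = Q.rates if isinstance(Q, Generator) else np.asarray(Q, dtype=float)
    ns = scipy.linalg.null_space(A.T, rcond=tol)
    if ns.shape[1] != 1:
        raise ReducibleGeneratorError(
            f"generator has a {ns.shape[1]}-dimensional stationary space; "
            "expected exactly one equilibrium distribution"
        )
    v = ns[:, 0]
    v = v * np.sign(v.sum())
    if v.min() < -tol:
        raise ReducibleGeneratorError("stationary vector has negative entries")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def normalize(gen: Generator) -> Generator:
    """Rescale a generator so the equilibrium mean rate is exactly 1.

    Only the overall scale changes: ratios between rates (the pattern of
    substitution) are untouched.  Times measured against the result are in
    expected substitutions per site.
    """
    mu = gen.mean_rate
    if mu <= 0.0:
        raise DegenerateModelError("total equilibrium rate is zero; cannot normalize")
    return Generator(
        rates=gen.rates / mu,
        pi=gen.pi,
        normalized=True,
        state_space=gen.state_space,
    )


def transition_matrix(gen: Generator, t: float) -> ProbabilityMatrix:
    """Transition probabilities P(t) = exp(tQ) via eigendecomposition."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    return ProbabilityMatrix(probs=gen.expm(t), time=t, state_space=gen.state_space)


def fractional_power(
    P: ProbabilityMatrix,
    e: float,
    *,
    eig_tol: float = 1e-8,
    imag_tol: float = 1e-8,
) -> ProbabilityMatrix:
    """Principal-branch matrix power P^e of a probability matrix.

    Diagonalizes ``P``, raises each eigenvalue to ``e`` on the principal
    branch and reconstructs.  The all-ones eigenvector with eigenvalue 1
    survives, so rows still sum to 1.  Eigenvalues of modulus below
    ``eig_tol`` are treated as zero; an eigenvalue of modulus >= ``eig_tol``
    with negative real part makes the real root ill defined and raises
    :class:`IllConditionedRootError`, as does an imaginary residue above
    ``imag_tol`` after reconstruction.
    """
    if e <= 0:
        raise ValueError(f"exponent must be positive, got {e}")
    t = None if P.time is None else P.time * e
    # Idempotent matrices (identity; the equilibrium projector a saturated
    # band matrix converges to) are their own power but are defective for
    # the eigenvector route, so short-circuit them.
    if np.allclose(P.probs @ P.probs, P.probs, atol=1e-10):
        return ProbabilityMatrix(probs=P.probs.copy(), time=t,
                                 state_space=P.state_space)
    w, v = scipy.linalg.eig(P.probs)
    bad = (np.abs(w) >= eig_tol) & (np.real(w) < 0) & (np.abs(np.imag(w)) <= eig_tol)
    if bad.any():
        raise IllConditionedRootError(
            f"eigenvalues {w[bad]} have negative real part; "
            "the principal-branch power is not a real matrix"
        )
    wp = np.where(np.abs(w) < eig_tol, 0.0, w.astype(complex) ** e)
    out = (v * wp[None, :]) @ np.linalg.inv(v)
    if np.abs(out.imag).max() > imag_tol:
        raise IllConditionedRootError(
            f"imaginary residue {np.abs(out.imag).max():.3e} exceeds "
            f"tolerance {imag_tol:.1e} in matrix power"
        )
    out = np.real(out)
    t = None if P.time is None else P.time * e
    return ProbabilityMatrix(probs=out, time=t, state_space=P.state_space)


def prob_to_generator(
    P: ProbabilityMatrix,
    t: float,
    *,
    eig_tol: float = 1e-8,
    clamp_tol: float = 1e-10,
) -> Generator:
    """Recover the generator Q = log(P)/t from a probability matrix.

    Uses the principal matrix logarithm through an eigendecomposition.
    Off-diagonal entries more negative than ``-clamp_tol`` (relative to
    the mean rate) indicate the matrix is not embeddable and raise
    :class:`NoValidGeneratorError`; smaller negatives are rounding noise,
    clamped to zero before the diagonal is recomputed.
    """
    if t <= 0:
        raise ValueError(f"time must be positive, got {t}")
    w, v = scipy.linalg.eig(P.probs)
    if np.any((np.real(w) <= eig_tol) & (np.abs(np.imag(w)) <= eig_tol)):
        raise NoValidGeneratorError(
            "probability matrix has an eigenvalue with non-positive real part; "
            "no principal real logarithm exists"
        )
    L = (v * np.log(w.astype(complex))[None, :]) @ np.linalg.inv(v)
    if np.abs(L.imag).max() > 1e-8:
        raise NoValidGeneratorError(
            f"imaginary residue {np.abs(L.imag).max():.3e} in matrix logarithm"
        )
    Q = np.real(L) / t
    off = Q - np.diag(np.diag(Q))
    scale = max(np.abs(off).mean() * Q.shape[0], 1e-300)
    if off.min() < -clamp_tol * scale:
        raise NoValidGeneratorError(
            f"negative off-diagonal rate {off.min():.3e} beyond clamp tolerance"
        )
    np.clip(off, 0.0, None, out=off)
    if off.max() == 0.0:  # log(I) = 0: no dynamics, equilibrium undetermined
        n = Q.shape[0]
        return Generator(
            rates=np.zeros((n, n)), pi=np.full(n, 1.0 / n), state_space=P.state_space
        )
    return make_generator(off, state_space=P.state_space)


def write_matrix_tsv(path, M: np.ndarray, labels: Sequence[str]) -> None:
    """Write a labelled square matrix as TSV (labels as header row/column)."""
    df = pd.DataFrame(np.asarray(M), index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t")  # default str() formatting round-trips exactly


def read_matrix_tsv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a labelled square matrix from TSV; returns (matrix, labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError("matrix TSV must have identical row and column labels")
    return df.to_numpy(dtype=float), tuple(str(x) for x in df.columns)
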