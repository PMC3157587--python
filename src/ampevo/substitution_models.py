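"""Codon and amino acid substitution models and among-site rate mixtures.

Three model families are provided:

* the M0 codon model, in which each single-nucleotide codon change gets a
  rate built from the target codon's frequency pi_j, the
  transition/transversion ratio kappa and the nonsynonymous/synonymous
  ratio omega, while multi-nucleotide changes are instantaneous-rate zero;
* empirical amino acid models read from the standard exchangeability text
  format (19 lower-triangular rows of exchangeabilities followed by 20
  equilibrium frequencies), with the Dayhoff model packaged as default;
* discrete rate mixtures — equal-probability discretized Gamma categories
  or an explicit list of relative rates — used to model among-site rate
  heterogeneity.  Mixtures always have mean rate 1 so divergence keeps
  its units of expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .genetic_code import AMINO_ACID_ORDER, CodonStateSpace, build_universal_code
from .markov_core import Generator, make_generator, normalize

__all__ = [
    "M0Params",
    "RateMixture",
    "build_m0",
    "uniform_codon_frequencies",
    "f1x4_codon_frequencies",
    "f3x4_codon_frequencies",
    "load_empirical_aa_model",
    "write_empirical_aa_model",
    "dayhoff_model",
    "discrete_gamma_rates",
    "eq10_rates",
    "alpha_mixture",
]

#: The twelve hand-specified relative rate categories (equal probability)
#: whose extreme spread — six orders of magnitude between the slowest and
#: the fastest sites — is what drives the strong divergence-dependence of
#: the aggregated amino acid process.
EQ10_RATES = (
    0.000001,
    0.00001,
    0.0001,
    0.001,
    0.01,
    0.1,
    0.15,
    0.2,
    0.3,
    0.5,
    2.0,
    8.738889,
)


@dataclass(frozen=True)
class M0Params:
    """Parameters of the M0 codon model.

    kappa : transition/transversion rate ratio (> 0)
    omega : nonsynonymous/synonymous rate ratio (> 0)
    codon_freqs : length-61 equilibrium codon distribution
    """

    kappa: float
    omega: float
    codon_freqs: np.ndarray

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        f = np.asarray(self.codon_freqs, dtype=float)
        object.__setattr__(self, "codon_freqs", f)
        if f.ndim != 1 or f.min() < 0 or not np.isclose(f.sum(), 1.0):
            raise ValueError("codon_freqs must be a nonnegative distribution")


def uniform_codon_frequencies(space: CodonStateSpace | None = None) -> np.ndarray:
    """Uniform distribution 1/61 over the sense codons."""
    if space is None:
        space = build_universal_code()
    return np.full(space.n_states, 1.0 / space.n_states)


def f1x4_codon_frequencies(
    nt_freqs: Sequence[float], space: CodonStateSpace | None = None
) -> np.ndarray:
    """Codon frequencies proportional to the product of one shared set of
    nucleotide frequencies (order A, C, G, T) across the three positions."""
    return f3x4_codon_frequencies([nt_freqs] * 3, space)


def f3x4_codon_frequencies(
    nt_freqs_by_pos: Sequence[Sequence[float]],
    space: CodonStateSpace | None = None,
) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies.

    ``nt_freqs_by_pos`` holds three length-4 distributions (A, C, G, T);
    products over the codon positions are renormalized over sense codons.
    """
    if space is None:
        space = build_universal_code()
    nts = "ACGT"
    pos = [np.asarray(f, dtype=float) for f in nt_freqs_by_pos]
    if len(pos) != 3 or any(p.shape != (4,) for p in pos):
        raise ValueError("need three length-4 nucleotide distributions")
    f = np.array(
        [pos[0][nts.index(c[0])] * pos[1][nts.index(c[1])] * pos[2][nts.index(c[2])]
         for c in space.states]
    )
    return f / f.sum()


def build_m0(
    params: M0Params, space: CodonStateSpace | None = None
) -> Generator:
    """Construct the (normalized) M0 codon generator.

    Off-diagonal rates: zero for changes needing more than one nucleotide
    substitution; otherwise pi_j times kappa for a transition, times omega
    for a nonsynonymous change.  The result is reversible with stationary
    distribution ``params.codon_freqs`` and is normalized to mean rate 1.
    """
    if space is None:
        space = build_universal_code()
    f = params.codon_freqs
    if f.shape != (space.n_states,):
        raise ValueError(
            f"codon_freqs has length {f.shape[0]}, expected {space.n_states}"
        )
    n = space.n_states
    codons = space.states
    agg = space.agg
    Q = np.zeros((n, n))
    purine = np.array([[c[p] in "AG" for p in range(3)] for c in codons])
    for i in range(n):
        ci = codons[i]
        for j in range(n):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != codons[j][p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            rate = f[j]
            if purine[i, p] == purine[j, p]:  # transition
                rate *= params.kappa
            if agg[i] != agg[j]:  # nonsynonymous
                rate *= params.omega
            Q[i, j] = rate
    gen = make_generator(Q, pi=f, state_space=codons)
    return normalize(gen)


# ---------------------------------------------------------------------------
# Empirical amino acid models (exchangeability text format)
# ---------------------------------------------------------------------------

def load_empirical_aa_model(source) -> Generator:
    """Load an empirical amino acid model from the exchangeability dialect.

    ``source`` is a path or a string of the file contents: 190
    whitespace-separated lower-triangular exchangeabilities s_xy (19 rows)
    followed by 20 equilibrium frequencies, amino acids ordered
    ``A R N D C Q E G H I L K M F P S T W Y V``.  The generator
    Q_xy = s_xy * pi_y is reversible by construction and returned
    normalized to mean rate 1.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source:
        try:
            is_file = Path(source).exists()
        except OSError:  # e.g. a one-line content string too long for a path
            is_file = False
        text = Path(source).read_text() if is_file else source
    else:
        text = str(source)
    tokens = []
    for line in text.splitlines():
        line = line.split("#")[0]
        tokens.extend(line.split())
    try:
        values = [float(tok) for tok in tokens]
    except ValueError as exc:
        raise ValueError(f"non-numeric token in model file: {exc}") from None
    if len(values) < 210:
        raise ValueError(
            f"expected 190 exchangeabilities + 20 frequencies, got {len(values)} values"
        )
    ex, freqs = values[:190], np.array(values[190:210])
    if min(ex) < 0 or freqs.min() < 0:
        raise ValueError("exchangeabilities and frequencies must be nonnegative")
    if not np.isclose(freqs.sum(), 1.0, atol=1e-4):
        raise ValueError(f"frequencies sum to {freqs.sum():.6f}, expected ~1")
    freqs = freqs / freqs.sum()
    S = np.zeros((20, 20))
    k = 0
    for row in range(1, 20):
        for col in range(row):
            S[row, col] = S[col, row] = ex[k]
            k += 1
    Q = S * freqs[None, :]
    gen = make_generator(Q, pi=freqs, state_space=AMINO_ACID_ORDER)
    return normalize(gen)


def write_empirical_aa_model(path, gen: Generator) -> None:
    """Write a reversible amino acid generator in the exchangeability dialect.

    Inverse of :func:`load_empirical_aa_model` up to the model's overall
    scale (which the loader renormalizes away).
    """
    pi = gen.pi
    S = gen.rates / pi[None, :]
    lines = []
    for row in range(1, 20):
        lines.append(" ".join(f"{S[row, col]:.17g}" for col in range(row)))
    lines.append("")
    lines.append(" ".join(f"{p:.17g}" for p in pi))
    Path(path).write_text("\n".join(lines) + "\n")


def dayhoff_model() -> Generator:
    """The packaged Dayhoff amino acid model (PAM exchangeabilities)."""
    text = resources.files("ampevo.data").joinpath("dayhoff.dat").read_text()
    return load_empirical_aa_model(text)


# ---------------------------------------------------------------------------
# Rate mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateMixture:
    """Discrete relative-rate categories scaling one base generator.

    ``rates[k]`` multiplies time for the sites in category ``k``, which a
    site occupies with probability ``probs[k]`` (and keeps forever: this
    is among-site, not among-time, variation).  The mixture mean is 1 so
    the base model's time units are preserved.
    """

    rates: tuple[float, ...]
    probs: tuple[float, ...]
    alpha: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if r.shape != p.shape or r.ndim != 1 or len(r) == 0:
            raise ValueError("rates and probs must be matching nonempty vectors")
        if r.min() < 0 or p.min() < 0:
            raise ValueError("rates and probabilities must be nonnegative")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("category probabilities must sum to 1")
        if not np.isclose(float(p @ r), 1.0, atol=1e-9):
            raise ValueError(f"mixture mean rate is {float(p @ r):.6g}, expected 1")

    @property
    def k(self) -> int:
        return len(self.rates)

    @property
    def mean(self) -> float:
        return float(np.dot(self.probs, self.rates))

    @classmethod
    def single(cls) -> "RateMixture":
        """The trivial mixture: one category with rate 1 (rate homogeneity)."""
        return cls(rates=(1.0,), probs=(1.0,))


def discrete_gamma_rates(alpha: float, k: int) -> RateMixture:
    """Discretized Gamma(alpha, alpha) rate mixture with k equal-probability
    categories, each category rate being the mean of its quantile bin.

    The Gamma is parametrized to have mean 1; after discretization the
    mixture mean is renormalized to exactly 1.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if k < 1 or int(k) != k:
        raise ValueError(f"k must be a positive integer, got {k}")
    k = int(k)
    if k == 1:
        return RateMixture(rates=(1.0,), probs=(1.0,), alpha=float(alpha))
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    # mean of Gamma(a, rate a) over a quantile bin: k * [I(a+1, a*upper) - I(a+1, a*lower)]
    cum = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * edges), [1.0]])
    rates = k * np.diff(cum)
    rates = rates / rates.mean()
    return RateMixture(
        rates=tuple(rates), probs=tuple(np.full(k, 1.0 / k)), alpha=float(alpha)
    )


def eq10_rates() -> RateMixture:
    """The twelve hand-specified relative rates, each with probability 1/12.

    The list spans r = 1e-6 up to r = 8.738889 and averages exactly 1; the
    heavy mass of nearly invariant sites (far heavier-tailed toward zero
    than any Gamma) is what a Gamma mixture cannot deliver.
    """
    return RateMixture(rates=EQ10_RATES, probs=tuple([1.0 / 12] * 12))


#: Synthetic stand-in for an empirical distribution of Gamma shape values
#: across globular proteins (the published per-protein estimates are not
#: available).  Log-spaced over the range typically reported for
#: among-site rate variation, 0.2 (strong heterogeneity) to 3 (mild);
#: any user-supplied list can be passed to :func:`alpha_mixture` instead.
PLACEHOLDER_ALPHAS: tuple[float, ...] = tuple(
    float(f"{a:.4g}") for a in np.geomspace(0.2, 3.0, 21)
)


def alpha_mixture(alphas: Sequence[float], k: int = 8) -> list[RateMixture]:
    """One discretized-Gamma mixture per shape value.

    Downstream experiments average joint frequencies over the returned
    list with equal weight, emulating a collection of proteins each with
    its own degree of among-site rate heterogeneity.
    """
    alphas = list(alphas)
    if not alphas:
        raise ValueError("need at least one alpha value")
    return [discrete_gamma_rates(a, k) for a in alphas]
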