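"""Aggregated Markov process: codon dynamics observed as amino acids.

An :class:`AMPModel` couples a codon-level generator (usually M0), an
optional among-site rate mixture, and the genetic-code aggregation map.
The observable amino acid process Y(t) = f(X(t)) is generally
non-Markovian even though X(t) is Markov — the central phenomenon this
package studies.

The sufficient statistic for every pairwise experiment is the 20 x 20
joint frequency table of observing amino acid x in one sequence and y in
the other, F_xy(t) = sum over categories k of p_k times
sum_{i in C_x} sum_{j in C_y} pi_i P_ij(r_k t).  Exact tables, seeded
multinomial finite-sample versions of them, and the symmetrized
count/total matrices (T, N) of the log-odds pipeline are all produced
here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import Aggregation, build_universal_code
from .markov_core import Generator
from .substitution_models import RateMixture

__all__ = [
    "AMPModel",
    "PairFrequencyTable",
    "joint_frequencies",
    "aa_marginals",
    "aa_conditional",
    "sample_counts",
    "to_counts",
]


@dataclass
class PairFrequencyTable:
    """Joint table over aggregate-symbol pairs for one sequence comparison.

    ``F[x, y]`` is the joint frequency (or count, if ``counts_flag``) of
    symbol x in one sequence and y in the other.  ``divergence_true``
    records the codon-level time t* that generated a simulated table;
    empirical tables carry ``None``.
    """

    F: np.ndarray
    labels: tuple[str, ...]
    divergence_true: float | None = None
    counts_flag: bool = False

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        n = len(self.labels)
        if self.F.shape != (n, n):
            raise ValueError("table shape must match the label alphabet")
        if self.F.min() < -1e-15:
            raise ValueError("table entries must be nonnegative")
        if not self.counts_flag and not np.isclose(self.F.sum(), 1.0, atol=1e-8):
            raise ValueError(f"frequencies sum to {self.F.sum():.6g}, expected 1")

    @property
    def total(self) -> float:
        return float(self.F.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.F, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path) -> None:
        fmt = "%d" if self.counts_flag else None  # default round-trips exactly
        self.to_frame().to_csv(path, sep="\t", float_format=fmt)

    @classmethod
    def from_tsv(cls, path, counts: bool = False) -> "PairFrequencyTable":
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        return cls(
            F=df.to_numpy(dtype=float),
            labels=tuple(str(c) for c in df.columns),
            counts_flag=counts,
        )


@dataclass
class AMPModel:
    """A hidden Markov substitution process observed through aggregation.

    ``base`` is the full-state generator (normalized, so times are in
    expected substitutions per full-state site), ``code`` the aggregation
    map (the universal genetic code by default) and ``mixture`` the
    among-site relative-rate categories (rate homogeneity by default).
    """

    base: Generator
    code: Aggregation | None = None
    mixture: RateMixture | None = None

    def __post_init__(self) -> None:
        if self.code is None:
            self.code = build_universal_code()
        if self.mixture is None:
            self.mixture = RateMixture.single()
        if self.base.n != self.code.n_states:
            raise ValueError(
                f"generator has {self.base.n} states but the aggregation map "
                f"covers {self.code.n_states}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return self.code.groups

    def averaged_transition(self, t: float) -> np.ndarray:
        """Category-averaged full-state transition law sum_k p_k P(r_k t).

        This is the law of a site whose rate category is unknown — the
        relevant law when conditioning on an observation, since
        observations do not reveal the category.
        """
        if t < 0:
            raise ValueError(f"time must be nonnegative, got {t}")
        out = np.zeros((self.base.n, self.base.n))
        for r, p in zip(self.mixture.rates, self.mixture.probs):
            out += p * self.base.expm(r * t)
        return out


def joint_frequencies(model: AMPModel, t: float) -> PairFrequencyTable:
    """Exact joint aggregate-pair frequencies at full-state divergence t.

    Sites keep their rate category forever, so the mixture is averaged at
    the level of the joint table: F = sum_k p_k A^T diag(pi) P(r_k t) A,
    with A the state->group indicator.  For a reversible base the result
    is symmetric.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    A = model.code.indicator()
    pi = model.base.pi
    F = np.zeros((model.code.n_groups, model.code.n_groups))
    for r, p in zip(model.mixture.rates, model.mixture.probs):
        joint = pi[:, None] * model.base.expm(r * t)
        F += p * (A.T @ joint @ A)
    F /= F.sum()
    return PairFrequencyTable(F=F, labels=model.labels, divergence_true=t)


def joint_frequencies_mixture(
    models: "Sequence[AMPModel]", t: float
) -> PairFrequencyTable:
    """Equal-weight average of the joint tables of several models.

    Emulates pooling pairwise data across a collection of proteins, each
    evolving under its own model (e.g. one rate mixture per protein).
    All models must share the same observed alphabet.
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    labels = models[0].labels
    if any(m.labels != labels for m in models):
        raise ValueError("models must share one observed alphabet")
    F = sum(joint_frequencies(m, t).F for m in models) / len(models)
    return PairFrequencyTable(F=F, labels=labels, divergence_true=t)


def aa_marginals(model: AMPModel) -> np.ndarray:
    """Aggregate-symbol equilibrium frequencies f_x = sum_{i in C_x} pi_i."""
    return model.code.indicator().T @ model.base.pi


def aa_conditional(model: AMPModel, x: str, t: float) -> np.ndarray:
    """Law of the observed symbol after time t, given symbol x now.

    The hidden state is started from the within-aggregate equilibrium of
    x's states (equilibrium restricted and renormalized to C_x — all the
    observation "x" reveals at stationarity), evolved by the
    category-averaged law, and aggregated.  Returns a length-20 (in
    general, n_groups) distribution.
    """
    code = model.code
    g = code.group_index(x)
    pi = model.base.pi
    mask = np.asarray(code.agg) == g
    w = pi[mask].sum()
    if w <= 0:
        raise ValueError(f"aggregate {x!r} has zero equilibrium mass")
    v0 = np.where(mask, pi, 0.0) / w
    v = v0 @ model.averaged_transition(t)
    out = code.indicator().T @ v
    return out / out.sum()


def sample_counts(
    F: PairFrequencyTable, n_sites: int, seed: int
) -> PairFrequencyTable:
    """One multinomial draw of n_sites site-pairs from a frequency table.

    Reproducible for a given seed; used for finite-sample noise checks.
    """
    if F.counts_flag:
        raise ValueError("expected a frequency table, got counts")
    if n_sites <= 0:
        raise ValueError(f"n_sites must be positive, got {n_sites}")
    rng = np.random.default_rng(seed)
    p = (F.F / F.F.sum()).ravel()
    draw = rng.multinomial(n_sites, p).reshape(F.F.shape)
    return PairFrequencyTable(
        F=draw.astype(float),
        labels=F.labels,
        divergence_true=F.divergence_true,
        counts_flag=True,
    )


def to_counts(
    F: PairFrequencyTable, n_sites: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrized substitution counts T and per-symbol totals N.

    A pairwise comparison cannot orient a substitution, so half of each
    off-diagonal observation is counted in either direction:
    T = (C + C^T)/2.  ``N_x`` is the row total of T (the number of sites
    showing symbol x).  Frequencies are scaled by ``n_sites`` when given,
    otherwise left as frequencies, which is equivalent for every
    downstream ratio.
    """
    C = F.F.copy()
    if n_sites is not None:
        if F.counts_flag:
            raise ValueError("n_sites applies only to frequency tables")
        C = C * n_sites
    T = (C + C.T) / 2.0
    N = T.sum(axis=1)
    return T, N
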