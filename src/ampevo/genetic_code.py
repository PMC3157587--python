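"""Codon and amino acid state spaces and the genetic-code aggregation map.

The universal genetic code defines a deterministic many-to-one function
from the 61 sense codons to the 20 amino acids.  A Markov substitution
process on codons observed only through this function is an aggregated
Markov process (AMP); everything downstream in this package is built on
the state spaces and the aggregation map defined here.

Orderings are fixed conventions shared by all matrix I/O in the package:
codons are sorted alphabetically over A < C < G < T with stop codons
removed, and amino acids follow the standard empirical-matrix order
``A R N D C Q E G H I L K M F P S T W Y V``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AMINO_ACID_ORDER",
    "Aggregation",
    "CodonStateSpace",
    "SingleChange",
    "build_universal_code",
    "classify_change",
    "min_nt_changes",
    "delta1_set",
]

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")

#: Canonical amino acid ordering of the empirical-matrix exchange format.
AMINO_ACID_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

# The universal (standard) genetic code, codon -> single-letter amino acid,
# '*' marking stops.  Data-driven so alternative tables could be plugged in.
UNIVERSAL_CODE_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class Aggregation:
    """A many-to-one map from a state alphabet to a group alphabet.

    Parameters
    ----------
    states
        Ordered labels of the full (hidden) state space.
    groups
        Ordered labels of the observed (aggregate) alphabet.
    agg
        ``agg[i]`` is the group index of state ``i``; the map must be
        total and surjective.
    """

    states: tuple[str, ...]
    groups: tuple[str, ...]
    agg: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.agg) != len(self.states):
            raise ValueError("aggregation map must cover every state")
        if set(self.agg) != set(range(len(self.groups))):
            raise ValueError("aggregation map must be surjective onto the groups")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def state_index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}") from None

    def group_index(self, label: str) -> int:
        try:
            return self.groups.index(label)
        except ValueError:
            raise KeyError(f"unknown group label {label!r}") from None

    def group_of(self, state: str) -> str:
        return self.groups[self.agg[self.state_index(state)]]

    def states_of(self, group: str) -> tuple[str, ...]:
        g = self.group_index(group)
        return tuple(s for s, a in zip(self.states, self.agg) if a == g)

    def indicator(self) -> np.ndarray:
        """0/1 matrix ``A`` of shape (n_states, n_groups) with ``A[i, agg[i]] = 1``.

        Right-multiplying a row distribution over states by ``A`` marginalizes
        it onto groups.
        """
        A = np.zeros((self.n_states, self.n_groups))
        A[np.arange(self.n_states), self.agg] = 1.0
        return A


class CodonStateSpace(Aggregation):
    """Sense-codon state space aggregated to amino acids by a genetic code."""

    @property
    def codons(self) -> tuple[str, ...]:
        return self.states

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return self.groups

    def amino_acid_of(self, codon: str) -> str:
        return self.group_of(codon)

    def codons_of(self, amino_acid: str) -> tuple[str, ...]:
        return self.states_of(amino_acid)


def build_universal_code(table: dict[str, str] | None = None) -> CodonStateSpace:
    """Build the codon state space of the universal genetic code.

    Stop codons are discarded, leaving 61 sense codons ordered
    alphabetically; amino acids follow :data:`AMINO_ACID_ORDER`.  An
    alternative codon->amino-acid ``table`` (with ``'*'`` for stops) may
    be supplied.
    """
    if table is None:
        table = UNIVERSAL_CODE_TABLE
    codons = tuple(
        c
        for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
        if table[c] != "*"
    )
    used = {table[c] for c in codons}
    groups = tuple(a for a in AMINO_ACID_ORDER if a in used)
    gidx = {a: k for k, a in enumerate(groups)}
    agg = tuple(gidx[table[c]] for c in codons)
    return CodonStateSpace(states=codons, groups=groups, agg=agg)


@dataclass(frozen=True)
class SingleChange:
    """Descriptor of a single-nucleotide codon change."""

    position: int  # 1-based codon position of the differing nucleotide
    transition: bool  # A<->G or C<->T
    synonymous: bool

    @property
    def transversion(self) -> bool:
        return not self.transition


def _check_codon(space: CodonStateSpace, codon: str) -> None:
    if codon not in space.states:
        raise KeyError(f"unknown sense codon {codon!r}")


def classify_change(
    i: str, j: str, space: CodonStateSpace | None = None
) -> str | SingleChange:
    """Classify the codon pair ``i -> j``.

    Returns ``"identical"``, ``"multiple"`` (more than one nucleotide
    differs) or a :class:`SingleChange` describing the position, the
    transition/transversion type and synonymy of a one-nucleotide change.
    """
    if space is None:
        space = build_universal_code()
    _check_codon(space, i)
    _check_codon(space, j)
    diffs = [p for p in range(3) if i[p] != j[p]]
    if not diffs:
        return "identical"
    if len(diffs) > 1:
        return "multiple"
    p = diffs[0]
    transition = (i[p] in PURINES) == (j[p] in PURINES)
    synonymous = space.group_of(i) == space.group_of(j)
    return SingleChange(position=p + 1, transition=transition, synonymous=synonymous)


def min_nt_changes(x: str, y: str, space: CodonStateSpace | None = None) -> int:
    """Minimum Hamming distance between any codon of ``x`` and any codon of ``y``.

    A codon-pair property: intermediate codons (including stops) play no
    role.  Zero iff ``x == y``; at most 3.
    """
    if space is None:
        space = build_universal_code()
    ci = space.states_of(x)
    cj = space.states_of(y)
    return min(sum(a != b for a, b in zip(u, v)) for u in ci for v in cj)


def delta1_set(space: CodonStateSpace | None = None) -> frozenset[tuple[str, str]]:
    """Ordered pairs of distinct amino acids one nucleotide change apart.

    This is the set Delta_1 used by the single-base-change diagnostic: the
    amino acid replacements achievable by a single nucleotide substitution
    under the genetic code.  Both orientations of each pair are included.
    """
    if space is None:
        space = build_universal_code()
    pairs = set()
    for x in space.groups:
        for y in space.groups:
            if x != y and min_nt_changes(x, y, space) == 1:
                pairs.add((x, y))
    return frozenset(pairs)
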