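# Methods

## Model

Sequence evolution is modeled site-independently by a continuous-time,
time-homogeneous Markov chain on a finite alphabet with instantaneous
rate matrix Q: off-diagonal entries are nonnegative rates, the diagonal
is Qᵢᵢ = −∑_{j≠i} Qᵢⱼ, and transition probabilities are P(t) = e^{tQ}.
The equilibrium distribution π solves πQ = 0. Every generator the
package constructs is normalized so that the equilibrium mean rate
∑ᵢ∑_{j≠i} πᵢQᵢⱼ equals 1, making time equal to the expected number of
substitutions per site; a PAM distance is 100× that quantity.

Two alphabets are used. Amino acid models (20 states) are reversible
empirical models, Q_xy = s_xy·π_y with symmetric exchangeabilities; the
packaged default is Dayhoff. Codon models (61 sense codons, universal
genetic code, stops discarded) use M0: for a change i→j requiring
exactly one nucleotide substitution,

    Q_ij = π_j · κ^[transition] · ω^[nonsynonymous],

zero for multi-nucleotide changes, where κ is the transition/transversion
rate ratio and ω the nonsynonymous/synonymous rate ratio. M0 is
reversible with stationary distribution equal to the codon frequencies.

### Aggregation

An aggregated Markov process (AMP) observes the codon chain X(t) only
through the genetic code, Y(t) = f(X(t)). AMPs are the deterministic
subclass of hidden Markov models: unless the partition satisfies
lumpability, Y(t) is non-Markovian. The sufficient statistic for all
pairwise experiments is the joint table

    F_xy(t) = Σ_k p_k Σ_{i∈C_x} Σ_{j∈C_y} π_i P_ij(r_k t),

where C_x is the codon class of amino acid x and (r_k, p_k) an optional
among-site relative-rate mixture. Rates scale *time* and sites keep
their category forever (among-site, not among-time, variation), so the
mixture is averaged at the level of joint tables. Conditional amino acid
laws start the hidden state from the within-aggregate equilibrium
υ₀ ∝ π restricted to C_x — exactly what a stationary observation of "x"
reveals — and, under a mixture, evolve by the category-averaged law
Σ_k p_k P(r_k t), because an observation does not reveal the category.

### Rate mixtures

Discretized Gamma mixtures use k equal-probability categories with each
rate the mean of its Gamma(α, α) quantile bin, renormalized to mean
exactly 1; k defaults to 8 (the choice is conventional; results are
insensitive for k ≥ 4). The 12-category hand-specified mixture
(10⁻⁶, 10⁻⁵, 10⁻⁴, 10⁻³, 0.01, 0.1, 0.15, 0.2, 0.3, 0.5, 2.0, 8.738889;
probabilities 1/12; mean exactly 1) places far more mass on nearly
invariant sites than any Gamma can — that heavy slow tail is what
produces strong divergence dependence in the experiments.
`PLACEHOLDER_ALPHAS` is a synthetic log-spaced stand-in (0.2–3.0, 21
values) for a distribution of per-protein Gamma shapes; any user list is
accepted, and conclusions drawn with it are qualitative only.

## Diagnostics

**Chapman–Kolmogorov profile.** For a Markov process,
P(Y(t₁)=y|Y(t₀)=x) = Σ_z P(Y(t₁)=y|Y(τ)=z)·P(Y(τ)=z|Y(t₀)=x) for every
τ ∈ [t₀, t₁]. The profile evaluates this composition two ways: on the
hidden codon chain (carried through τ intact, aggregated only at the
endpoints — constant in τ to rounding, the Markov baseline) and from
aggregated amino acid laws with a within-aggregate-equilibrium restart
at τ. The aggregated composition equals the direct probability at
τ = t₀ and τ = t₁ and bows away from it in between. Deviations are
reported both absolutely (range over the τ grid) and relative to the
direct probability; on the relative scale the violation is strongest for
amino acid pairs far apart in the genetic code (C→M, three nucleotide
changes: ≈23%; C→R, one change: ≈0.8%, with the default M0 at
t₀ = 0, t₁ = 5). The default τ grid is 11 evenly spaced points.

**Single-base-change fraction.** The share of off-diagonal mass on Δ₁,
the amino acid pairs one nucleotide change apart:
Σ_{(x→y)∈Δ₁} M_xy / Σ_{x≠y} M_xy. The input may be a conditional
probability matrix (the literal unweighted sum) or a joint pair table
(equivalently, frequency-weighted rows); both are exposed because the
two readings coincide only up to row weights. The ratio is invariant to
global scaling of the off-diagonal cells and undefined for diagonal
tables. Curves plot this fraction against the divergence *re-estimated*
from the amino acid data under a rate-homogeneous amino acid model —
deliberately misspecified for heterogeneous data, as any empirical
analysis of protein alignments would be.

**Banded log-odds pipeline.** Counts from a divergence band are
symmetrized (half of each undirected substitution counted each way,
T = (C+Cᵀ)/2, N the row totals — with this definition T·N⁻¹ is row
normalization and yields a proper stochastic matrix, diagonal included),
converted to P(t_k) = T·N⁻¹, extrapolated to 1 PAM by the principal
fractional power P(t_k)^{1/t_k} with t_k the *inferred* PAM distance,
and standardized to L_xy(250) = 10·log₁₀([P(0.01)²⁵⁰]_xy / f_y) with
f_y = N_y/ΣN taken from the data. The diagonal of L is computed but
non-normative (the standardization is defined for x ≠ y). The default
simulated band grid is 15 log-spaced generating divergences in
[0.03, 3.0] replacements/site, spanning roughly 1–30 inferred PAM after
heterogeneity-induced compression.

## Estimation

Pairwise divergence is estimated by maximizing the expected
log-likelihood ℓ(t) = Σ_xy T_xy log(f_x P_xy(t)) by bounded scalar
search on [10⁻⁸, 10] replacements/site (absolute tolerance 10⁻⁸);
zero-count cells contribute nothing, diagonal-only tables return t̂ = 0,
and an optimum at the upper bound is flagged as saturated rather than
fatal — by then the likelihood is flat and the downstream log-odds are
insensitive to the bound. Model frequencies are fixed at the amino acid
model's equilibrium. The M0 fit maximizes the same objective over
(log κ, log ω, log t) by Nelder–Mead simplex from two starts
((κ,ω) = (1,1) and (2,0.5)), with codon frequencies fixed at the
symmetrized table's marginals; on exact tables it recovers generating
parameters to <10⁻⁴.

## Numerical choices

Everything runs through eigendecompositions, not scaling-and-squaring:
fractional powers and logarithms of *estimated* probability matrices are
needed, and the exponential-family identity P(t)^e = P(te) is exact only
when one decomposition is shared. Reversible generators are symmetrized
by the π^{1/2} similarity transform and decomposed with a real
orthogonal eigensolver; non-reversible inputs (e.g. toy chains) fall
back to a general eigendecomposition. In fractional powers, eigenvalues
of modulus < 10⁻⁸ are treated as zero; an eigenvalue of modulus ≥ 10⁻⁸
with negative real part, or an imaginary residue above 10⁻⁸ after
reconstruction, raises an error rather than being silently absorbed —
near-singular roots of empirical matrices are pathology worth surfacing.
Idempotent matrices (identity; the equilibrium projector that saturated
band matrices converge to) are their own power and are short-circuited
exactly, since they are defective for the eigenvector route. In the
probability-matrix → generator conversion, off-diagonal entries more
negative than 10⁻¹⁰ relative to the mean rate abort; smaller negatives
are clamped to zero and the diagonal recomputed. All tolerances are
keyword-configurable with these defaults.

The saturation limit of the log-odds pipeline deserves note: once the
generating divergence is large enough that every subdominant eigenvalue
of the band matrix falls below the 10⁻⁸ tolerance (t* ≳ 140 for the
uniform-frequency M0 AMP, whose slowest eigenvalue is ≈ −0.13), the band
matrix is numerically the equilibrium projector, its fractional powers
are itself, and every off-diagonal L(250) collapses to zero. At merely
large divergences (t* ≈ 20) the subdominant eigenvalue is still ≈ 0.07
and the extrapolated log-odds are far from zero; the zero limit is a
statement about true saturation, and the tests probe it at t* = 200.

## Synthetic data

All experiments run on exact model-implied joint frequencies or seeded
multinomial samples of them; site-pair counts are a sufficient statistic
for every pairwise analysis here, so no alignments are simulated. The
generator defaults are the study conditions: M0 with κ = 2.5, ω = 0.2
(moderate purifying selection), uniform codon frequencies (the specific
frequency vector affects none of the qualitative behavior; F1×4, F3×4
and explicit vectors are available), the 12-category mixture for
heterogeneous runs, and Chapman–Kolmogorov windows [0, 5]. What the
synthetic data do *not* emulate: alignment error, compositional drift,
selection variation among sites (ω is shared), instantaneous
multi-nucleotide changes, and phylogenetic correlation among more than
two sequences. Passing tests therefore demonstrate properties of the
models and the inference pipeline, not goodness of fit to any real
protein family.

## Known limitations

- Only pairwise comparisons; no trees, no multi-sequence ML.
- The amino acid distance estimator is deliberately rate-homogeneous;
  the induced underestimation on heterogeneous data is the object of
  study, not a defect, but it means the package does not provide a
  corrected heterogeneous amino acid distance.
- Empirical count tables with strongly negative eigenvalues cannot be
  extrapolated (the fractional-power error above); the classical remedy
  of pooling more data is outside the package's scope.
- The universal genetic code ships; alternative codes can be supplied as
  tables but none are bundled.
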