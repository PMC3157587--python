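"""Chapman-Kolmogorov consistency and single-base-change diagnostics."""

import numpy as np
import pytest

import ampevo as av
from ampevo.cli import toy_bijective_model, toy_lumped_model


class TestCKLhs:
    def test_zero_window_is_certain(self, amp_hom):
        assert av.ck_lhs(amp_hom, "C", "C", 1.0, 1.0) == pytest.approx(1.0)

    def test_irreducibility_gives_positive_mass(self, amp_hom):
        assert av.ck_lhs(amp_hom, "C", "M", 0.0, 5.0) > 0

    def test_normalization_over_targets(self, amp_hom, code):
        total = sum(av.ck_lhs(amp_hom, "C", y, 0.0, 5.0) for y in code.groups)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_reversed_window_rejected(self, amp_hom):
        with pytest.raises(ValueError):
            av.ck_lhs(amp_hom, "C", "M", 5.0, 0.0)


class TestCKRhs:
    def test_codon_level_constant_and_equal_to_lhs(self, amp_hom):
        """On the hidden chain the composition law holds exactly for every
        intermediate time: the Markov baseline."""
        lhs = av.ck_lhs(amp_hom, "C", "M", 0.0, 5.0)
        for tau in (0.0, 1.25, 2.5, 3.75, 5.0):
            rhs = av.ck_rhs(amp_hom, "C", "M", 0.0, tau, 5.0, level="codon")
            assert abs(rhs - lhs) < 1e-10

    def test_amino_acid_level_degenerate_at_endpoints(self, amp_hom):
        lhs = av.ck_lhs(amp_hom, "C", "M", 0.0, 5.0)
        for tau in (0.0, 5.0):
            rhs = av.ck_rhs(amp_hom, "C", "M", 0.0, tau, 5.0, level="amino-acid")
            assert rhs == pytest.approx(lhs, abs=1e-12)

    def test_amino_acid_level_varies_in_interior(self, amp_hom):
        vals = [
            av.ck_rhs(amp_hom, "C", "M", 0.0, tau, 5.0, level="amino-acid")
            for tau in np.linspace(0, 5, 11)
        ]
        assert max(vals) - min(vals) > 0

    def test_tau_outside_window_rejected(self, amp_hom):
        with pytest.raises(ValueError):
            av.ck_rhs(amp_hom, "C", "M", 0.0, 6.0, 5.0)


class TestCKProfile:
    def test_codon_row_flat_amp_row_curved(self, amp_hom):
        prof = av.ck_profile(amp_hom, "C", "M", 0.0, 5.0, 11)
        assert np.abs(prof.rhs_codon - prof.lhs).max() < 1e-10
        assert prof.amp_deviation > 0

    def test_code_distant_pair_deviates_more(self, amp_hom):
        """The violation is strongest for amino acids far apart in the
        genetic code: C-M (three changes) vs C-R (one change), on the scale
        of each pair's own transition probability."""
        cm = av.ck_profile(amp_hom, "C", "M", 0.0, 5.0, 11)
        cr = av.ck_profile(amp_hom, "C", "R", 0.0, 5.0, 11)
        assert cr.amp_relative_deviation < cm.amp_relative_deviation

    def test_endpoints_match_lhs(self, amp_hom):
        prof = av.ck_profile(amp_hom, "C", "M", 0.0, 5.0, 11)
        assert prof.rhs_amp[0] == pytest.approx(prof.lhs, abs=1e-12)
        assert prof.rhs_amp[-1] == pytest.approx(prof.lhs, abs=1e-12)

    def test_tsv_shape(self, amp_hom, tmp_path):
        prof = av.ck_profile(amp_hom, "C", "M", 0.0, 5.0, 11)
        path = tmp_path / "ck.tsv"
        prof.to_tsv(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 12  # header + 11 tau rows
        assert lines[0].split("\t") == ["tau", "lhs", "rhs_codon", "rhs_amp"]


class TestToyLumping:
    """A 4-state chain observed through a 2-group map isolates aggregation
    as the only source of non-Markov behavior."""

    def test_bijective_aggregation_is_markov(self):
        prof = av.ck_profile(toy_bijective_model(), "s0", "s2", 0.0, 3.0, 9)
        assert prof.amp_deviation < 1e-12

    def test_lumped_aggregation_is_not(self):
        prof = av.ck_profile(toy_lumped_model(), "A", "B", 0.0, 3.0, 9)
        assert prof.amp_deviation > 1e-6

    def test_lumped_deviation_matches_brute_force(self):
        """Independent oracle: enumerate the composition by hand from the
        4-state transition matrices."""
        model = toy_lumped_model()
        base, agg = model.base, model.code
        tau, t1 = 1.0, 3.0
        pi = base.pi
        A = agg.indicator()

        def cond(group, t):
            mask = np.asarray(agg.agg) == agg.group_index(group)
            v0 = np.where(mask, pi, 0.0) / pi[mask].sum()
            return (v0 @ base.expm(t)) @ A

        by_hand = sum(
            cond("A", tau)[g] * cond(z, t1 - tau)[agg.group_index("B")]
            for g, z in enumerate(agg.groups)
        )
        rhs = av.ck_rhs(model, "A", "B", 0.0, tau, t1, level="amino-acid")
        assert rhs == pytest.approx(by_hand, abs=1e-14)


class TestSingleChangeFraction:
    def test_delta1_only_mass(self):
        M = np.zeros((20, 20))
        labels = av.AMINO_ACID_ORDER
        M[labels.index("C"), labels.index("W")] = 0.3
        np.fill_diagonal(M, 0.035)
        assert av.single_change_fraction(M, labels) == pytest.approx(1.0)

    def test_non_delta1_only_mass(self):
        M = np.zeros((20, 20))
        labels = av.AMINO_ACID_ORDER
        M[labels.index("C"), labels.index("M")] = 0.3
        np.fill_diagonal(M, 0.035)
        assert av.single_change_fraction(M, labels) == pytest.approx(0.0)

    def test_scaling_invariance(self, amp_het):
        F = av.joint_frequencies(amp_het, 0.5)
        base = av.single_change_fraction(F)
        scaled = F.F.copy()
        off = ~np.eye(20, dtype=bool)
        scaled[off] *= 5.0
        assert av.single_change_fraction(scaled, F.labels) == pytest.approx(base)

    def test_instantaneous_changes_are_single_base(self, amp_hom, m0_uniform):
        """At t -> 0 nearly all replacement mass is one nucleotide deep:
        double hits are second order in t (series oracle on the codon
        generator confirms the mass budget)."""
        t = 1e-4
        F = av.joint_frequencies(amp_hom, t)
        assert av.single_change_fraction(F) > 0.999
        # oracle: off-diagonal mass ~ t * mean rate + O(t^2)
        off = F.F.sum() - np.trace(F.F)
        # changes are nonsynonymous with prob = sum pi_i Q_ij over nonsyn
        assert off == pytest.approx(
            t * _nonsyn_rate(m0_uniform, amp_hom.code), rel=1e-3
        )

    def test_zero_off_diagonal_undefined(self, amp_hom):
        F = av.joint_frequencies(amp_hom, 0.0)
        with pytest.raises(ZeroDivisionError):
            av.single_change_fraction(F)


def _nonsyn_rate(gen, code):
    agg = np.asarray(code.agg)
    nonsyn = agg[:, None] != agg[None, :]
    return float((gen.pi[:, None] * gen.rates * nonsyn).sum())


@pytest.fixture(scope="module")
def curves(dayhoff, amp_hom, amp_het):
    grid = [0.01, 0.05, 0.1, 0.3, 0.5, 1.0, 2.0]
    df = av.md_curve(
        [("aa_markov", dayhoff), ("amp_hom", amp_hom), ("amp_het", amp_het)],
        grid,
        dayhoff,
    )
    return {name: g.sort_values("pam") for name, g in df.groupby("model")}


class TestMDCurve:
    def test_fractions_are_probabilities(self, curves):
        for g in curves.values():
            assert ((g.fraction >= 0) & (g.fraction <= 1)).all()

    def test_amino_acid_markov_declines_near_linearly(self, curves):
        g = curves["aa_markov"]
        slopes = np.diff(g.fraction) / np.diff(g.pam)
        assert (slopes < 0).all()
        # near-linear: slope varies gently compared to the AMP's collapse
        assert slopes.max() / slopes.min() > 0.25

    def test_amp_starts_above_any_amino_acid_markov(self, curves):
        """Aggregation of single-nucleotide codon changes captures the high
        single-base fraction at very low divergence."""
        assert curves["amp_hom"].fraction.iloc[0] > curves["aa_markov"].fraction.max()

    def test_heterogeneity_steepens_the_fall(self, curves):
        """Per unit of inferred PAM, the rate-heterogeneous aggregated
        process loses single-base mass much faster at small divergence."""
        def initial_slope(g):
            return (g.fraction.iloc[2] - g.fraction.iloc[0]) / (
                g.pam.iloc[2] - g.pam.iloc[0]
            )

        assert initial_slope(curves["amp_het"]) < initial_slope(curves["amp_hom"])

    def test_alpha_mixture_of_amino_acid_models(self, dayhoff, identity20):
        """A pooled collection of Gamma-heterogeneous amino acid processes
        still declines far more gently than the aggregated codon process."""
        mixes = av.alpha_mixture([0.3, 0.7, 1.5], 4)
        pool = [
            av.AMPModel(base=dayhoff, code=identity20, mixture=m) for m in mixes
        ]
        df = av.md_curve([("aa_pool", pool)], [0.05, 0.5], dayhoff)
        assert ((df.fraction > 0.5) & (df.fraction < 0.9)).all()
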