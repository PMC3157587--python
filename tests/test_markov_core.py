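"""Generator algebra: normalization, equilibrium, exponentials, powers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ampevo as av
from ampevo.markov_core import (
    DegenerateModelError,
    NoValidGeneratorError,
    ReducibleGeneratorError,
)


def truncated_series_expm(Q, t, terms=60):
    """Independent oracle: the power series I + tQ + (tQ)^2/2! + ..."""
    out = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms):
        term = term @ (t * Q) / k
        out = out + term
    return out


class TestNormalize:
    def test_m0_mean_rate_one(self, m0_uniform):
        assert m0_uniform.normalized
        assert m0_uniform.mean_rate == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, m0_uniform):
        scaled = av.Generator(rates=m0_uniform.rates * 7.0, pi=m0_uniform.pi)
        renorm = av.normalize(scaled)
        np.testing.assert_allclose(renorm.rates, m0_uniform.rates, atol=1e-12)

    def test_row_sums_stay_zero(self, m0_uniform):
        assert np.abs(m0_uniform.rates.sum(axis=1)).max() < 1e-12

    def test_zero_rate_is_degenerate(self):
        zero = av.Generator(rates=np.zeros((3, 3)), pi=np.full(3, 1 / 3))
        with pytest.raises(DegenerateModelError):
            av.normalize(zero)


class TestEquilibrium:
    def test_m0_returns_codon_frequencies(self, m0_uniform):
        pi = av.equilibrium(m0_uniform)
        np.testing.assert_allclose(pi, m0_uniform.pi, atol=1e-10)

    def test_two_state_symmetric(self):
        gen = av.make_generator(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(gen.pi, [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_stationarity_under_exponential(self, dayhoff, t):
        P = av.transition_matrix(dayhoff, t)
        np.testing.assert_allclose(dayhoff.pi @ P.probs, dayhoff.pi, atol=1e-12)

    def test_reducible_is_rejected(self):
        # two disconnected 2-state blocks: stationary space is 2-dimensional
        Q = np.zeros((4, 4))
        Q[0, 1] = Q[1, 0] = Q[2, 3] = Q[3, 2] = 1.0
        with pytest.raises(ReducibleGeneratorError):
            av.make_generator(Q)


class TestTransitionMatrix:
    def test_time_zero_is_identity(self, m0_uniform):
        P = av.transition_matrix(m0_uniform, 0.0)
        np.testing.assert_allclose(P.probs, np.eye(61), atol=1e-12)

    def test_matches_power_series_oracle(self, dayhoff):
        P = av.transition_matrix(dayhoff, 0.7)
        oracle = truncated_series_expm(dayhoff.rates, 0.7)
        np.testing.assert_allclose(P.probs, oracle, atol=1e-12)

    def test_semigroup(self, m0_uniform):
        Ps = av.transition_matrix(m0_uniform, 0.3).probs
        Pt = av.transition_matrix(m0_uniform, 0.7).probs
        Pst = av.transition_matrix(m0_uniform, 1.0).probs
        np.testing.assert_allclose(Ps @ Pt, Pst, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        s=st.floats(1e-3, 5.0, allow_nan=False),
        t=st.floats(1e-3, 5.0, allow_nan=False),
    )
    def test_chapman_kolmogorov_full_state(self, dayhoff, s, t):
        """The hidden-level composition law holds to 1e-10 everywhere: the
        baseline against which aggregation failure is measured."""
        Ps = dayhoff.expm(s)
        Pt = dayhoff.expm(t)
        Pst = dayhoff.expm(s + t)
        assert np.abs(Ps @ Pt - Pst).max() < 1e-10

    def test_equilibrium_limit(self, m0_uniform):
        P = av.transition_matrix(m0_uniform, 1e6)
        np.testing.assert_allclose(P.probs, np.tile(m0_uniform.pi, (61, 1)),
                                   atol=1e-9)

    def test_negative_time_rejected(self, m0_uniform):
        with pytest.raises(ValueError):
            av.transition_matrix(m0_uniform, -0.1)


class TestReversibility:
    @pytest.mark.parametrize("model", ["m0_uniform", "dayhoff"])
    def test_detailed_balance(self, model, request):
        gen = request.getfixturevalue(model)
        flux = gen.pi[:, None] * gen.rates
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)


class TestFractionalPower:
    def test_unit_exponent(self, dayhoff):
        P = av.transition_matrix(dayhoff, 0.5)
        np.testing.assert_allclose(av.fractional_power(P, 1.0).probs, P.probs,
                                   atol=1e-10)

    def test_square_root_of_square(self, m0_uniform):
        P = av.transition_matrix(m0_uniform, 0.5)
        P2 = av.ProbabilityMatrix(probs=P.probs @ P.probs, time=1.0)
        root = av.fractional_power(P2, 0.5)
        np.testing.assert_allclose(root.probs, P.probs, atol=1e-9)

    @pytest.mark.parametrize("e", [0.5, 2.0, 250.0])
    def test_exponential_family_property(self, dayhoff, e):
        """P(t)^e = P(t*e): membership in one exponential family."""
        P = av.transition_matrix(dayhoff, 0.02)
        direct = av.transition_matrix(dayhoff, 0.02 * e)
        np.testing.assert_allclose(av.fractional_power(P, e).probs, direct.probs,
                                   atol=1e-8)

    def test_rows_sum_to_one(self, dayhoff):
        P = av.transition_matrix(dayhoff, 1.3)
        out = av.fractional_power(P, 1.0 / 3.7)
        np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-10)

    def test_idempotent_projector(self, dayhoff):
        proj = np.tile(dayhoff.pi, (20, 1))
        P = av.ProbabilityMatrix(probs=proj)
        np.testing.assert_allclose(av.fractional_power(P, 0.25).probs, proj,
                                   atol=1e-12)

    def test_negative_real_eigenvalue_reported(self):
        # a period-2 style matrix: eigenvalue -0.8 has no real root
        P = av.ProbabilityMatrix(probs=np.array([[0.1, 0.9], [0.9, 0.1]]))
        with pytest.raises(av.markov_core.IllConditionedRootError):
            av.fractional_power(P, 0.5)


class TestProbToGenerator:
    def test_round_trip_dayhoff(self, dayhoff):
        P = av.transition_matrix(dayhoff, 0.01)
        back = av.prob_to_generator(P, 0.01)
        assert np.abs(back.rates - dayhoff.rates).max() < 1e-8

    def test_identity_gives_zero_generator(self):
        P = av.ProbabilityMatrix(probs=np.eye(5))
        gen = av.prob_to_generator(P, 3.0)
        assert np.abs(gen.rates).max() == 0.0

    def test_rows_sum_to_zero(self, m0_uniform):
        P = av.transition_matrix(m0_uniform, 0.2)
        back = av.prob_to_generator(P, 0.2)
        assert np.abs(back.rates.sum(axis=1)).max() < 1e-10

    def test_non_embeddable_rejected(self):
        P = av.ProbabilityMatrix(probs=np.array([[0.05, 0.95], [0.95, 0.05]]))
        with pytest.raises(NoValidGeneratorError):
            av.prob_to_generator(P, 1.0)


def test_matrix_tsv_round_trip(tmp_path, dayhoff):
    path = tmp_path / "q.tsv"
    av.markov_core.write_matrix_tsv(path, dayhoff.rates, av.AMINO_ACID_ORDER)
    M, labels = av.markov_core.read_matrix_tsv(path)
    assert labels == tuple(av.AMINO_ACID_ORDER)
    np.testing.assert_allclose(M, dayhoff.rates, rtol=1e-15)
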