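import numpy as np
import pytest

import ampevo as av


@pytest.fixture(scope="session")
def code():
    return av.build_universal_code()


@pytest.fixture(scope="session")
def m0_uniform(code):
    params = av.M0Params(kappa=2.5, omega=0.2,
                         codon_freqs=av.uniform_codon_frequencies(code))
    return av.build_m0(params, code)


@pytest.fixture(scope="session")
def dayhoff():
    return av.dayhoff_model()


@pytest.fixture(scope="session")
def amp_hom(m0_uniform, code):
    """Aggregated M0 process without rate heterogeneity."""
    return av.AMPModel(base=m0_uniform, code=code)


@pytest.fixture(scope="session")
def amp_het(m0_uniform, code):
    """Aggregated M0 process with the 12 hand-specified rate categories."""
    return av.AMPModel(base=m0_uniform, code=code, mixture=av.eq10_rates())


@pytest.fixture(scope="session")
def identity20():
    """Bijective aggregation over the amino acid alphabet (no lumping)."""
    aas = tuple(av.AMINO_ACID_ORDER)
    return av.Aggregation(states=aas, groups=aas, agg=tuple(range(20)))


@pytest.fixture(scope="session")
def dayhoff_joint(dayhoff):
    """Exact Dayhoff joint frequency table factory."""

    def make(t):
        F = dayhoff.pi[:, None] * dayhoff.expm(t)
        return av.PairFrequencyTable(F=F / F.sum(),
                                     labels=tuple(av.AMINO_ACID_ORDER),
                                     divergence_true=t)

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
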