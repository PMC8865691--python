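import numpy as np
import pytest
from hypothesis import settings

from ddtasep import build_uniform_gene, uniform_rates

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gene_20kbp():
    return build_uniform_gene(20_000)


@pytest.fixture(scope="session")
def gene_2kbp():
    return build_uniform_gene(2_000)


@pytest.fixture(scope="session")
def gene_tiny():
    # single nucleosome unit: 4 sites
    return build_uniform_gene(200)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def bare_dna_params(gene_20kbp):
    return uniform_rates(gene_20kbp, alpha=1.0, beta=1.0, q=1.0, h_c=0.0, h_o=1.0)
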