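import numpy as np
import pytest

from idphydro import GeneratorParams, generate, get_builtin_scale


@pytest.fixture(scope="session")
def small_corpus():
    """A quick 30+30 synthetic corpus with the default planted structure."""
    return generate(GeneratorParams(n_disordered=30, n_ordered=30, seed=7))


@pytest.fixture(scope="session")
def kd_scale():
    return get_builtin_scale("kyte_doolittle")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
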