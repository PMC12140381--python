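import numpy as np
import pytest

from stgcl import SimSpec, preprocess, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_section():
    """A small, easy laminar section: 16x20 grid, 4 domains, 80 genes."""
    spec = SimSpec(n_rows=16, n_cols=20, C=4, G=80, n_program_genes=8, seed=1)
    return simulate(spec)


@pytest.fixture(scope="session")
def small_preprocessed(small_section):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, _ = preprocess(small_section)
    return ds
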