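import numpy as np
import pytest

from poolscreen.codebook import CodebookSpec, build_codebook


@pytest.fixture(scope="session")
def codebook85():
    """The standard library codebook: 85 codewords, 7 rounds, 4 colours,
    minimum pairwise distance 3."""
    return build_codebook(CodebookSpec(seed=11))


@pytest.fixture(scope="session")
def codebook_small():
    """A small codebook for fast decode tests."""
    return build_codebook(CodebookSpec(n_codes=10, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
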