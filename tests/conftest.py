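import string

import numpy as np
import pytest

from sylva.similarity_search import ScoringParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def params():
    return ScoringParams()


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


@pytest.fixture
def labels10():
    return list(string.ascii_lowercase[:10])
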