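import numpy as np
import pytest

from termistd.types import GenomeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_sequence(rng, n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def random_genome(rng):
    return GenomeRecord("rand", random_sequence(rng, 10_000), circular_hint=True)
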