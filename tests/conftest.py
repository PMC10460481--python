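import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n, p_n=0.0):
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=n)
    if p_n:
        seq[rng.random(n) < p_n] = "N"
    return "".join(seq)
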