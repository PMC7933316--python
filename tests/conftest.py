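import numpy as np
import pytest

from cleavedrive.seqio import default_scheme


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20210304)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
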