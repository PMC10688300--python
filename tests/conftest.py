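import numpy as np
import pytest

from genescout.seqcore import blosum62_scheme, genetic_code


@pytest.fixture(scope="session")
def scheme():
    return blosum62_scheme()


@pytest.fixture(scope="session")
def code1():
    return genetic_code(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_nt(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def random_aa(rng, n):
    return "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(0, 20, n)])
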