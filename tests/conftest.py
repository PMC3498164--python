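import numpy as np
import pytest

import bondfluct as bf


@pytest.fixture(scope="session")
def h3_seq():
    return bf.h3_1_sequence()


@pytest.fixture(scope="session")
def zero_matrix():
    return bf.make_matrix("zero")


@pytest.fixture(scope="session")
def attract_matrix():
    return bf.make_matrix("uniform", value=-1.0)


@pytest.fixture(scope="session")
def random_matrix():
    return bf.make_matrix("random-symmetric", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def homopolymer(n, residue=7):
    """Poly-A chain (alphabet index 7) of length n."""
    return bf.ProteinSequence(tuple([residue] * n))


@pytest.fixture(scope="session")
def qgrid():
    return np.geomspace(0.2, 1.2, 30)
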