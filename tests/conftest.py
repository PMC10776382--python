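import numpy as np
import pytest

from nafold.fixtures import (gen_basecontact_complex, gen_bform_dna,
                             gen_toy_protein)


@pytest.fixture
def rng():
    return np.random.default_rng(20251)


@pytest.fixture(scope="session")
def gc_duplex():
    return gen_bform_dna("GCGCGCGCGC")


@pytest.fixture(scope="session")
def mixed_duplex():
    return gen_bform_dna("ACGTTGCA")


@pytest.fixture(scope="session")
def toy_helix():
    return gen_toy_protein("ADKLMNQRSTVWYEFGHIPC")


@pytest.fixture(scope="session")
def basecontact_record():
    return gen_basecontact_complex(np.random.default_rng(11))


def random_rigid(rng):
    """Random proper rotation + translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    Q = Q * np.sign(np.linalg.det(Q))
    return Q, rng.normal(scale=8.0, size=3)
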