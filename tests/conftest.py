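import numpy as np
import pytest

from rnadiff import structure as S
from rnadiff import synthetic as syn


@pytest.fixture(scope="session")
def hairpin():
    """Stem-4 / loop-4 hairpin with its ground-truth pair set."""
    return syn.make_hairpin(4, 4)


@pytest.fixture(scope="session")
def helix8():
    return syn.make_helix("GGCAUGGC")


@pytest.fixture(scope="session")
def strand30():
    """Single 30-residue chain (one duplex strand, full atom set)."""
    st, _ = syn.make_helix("GCAU" * 8)
    return S.RnaStructure([st.chains[0][:30]], name="strand30")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng) -> np.ndarray:
    a, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(a) < 0:
        a[:, 0] *= -1
    return a
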