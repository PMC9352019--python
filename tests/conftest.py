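import numpy as np
import pytest

from entromem import (
    AMRGrid,
    FixtureSpec,
    default_glyph_spec,
    make_feature_corpus,
    make_glyph_corpus,
)

# The two-function 4x7 worked example: functions (1,2,4,7) and (3,2,6,7)
# superpose into a grid with column counts (2,1,2,1); strict recognition
# then also accepts the two collateral functions (1,2,6,7) and (3,2,4,7).
F1 = (1, 2, 4, 7)
F2 = (3, 2, 6, 7)
COLLATERALS = ((1, 2, 6, 7), (3, 2, 4, 7))


@pytest.fixture
def two_function_amr() -> AMRGrid:
    return AMRGrid(4, 7).register(F1).register(F2)


@pytest.fixture(scope="session")
def small_corpus():
    """A small separable feature corpus for sweep tests."""
    return make_feature_corpus(
        FixtureSpec(c=8, n=32, m=64, n_per_class=60, seed=7)
    )


@pytest.fixture(scope="session")
def default_corpus():
    """The default study corpus: 36 classes, 64 features, 300/class."""
    return make_feature_corpus(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def glyph_corpus():
    return make_glyph_corpus(default_glyph_spec(seed=0))


def random_nonempty_amr(rng: np.random.Generator, n_max=5, m_max=5) -> AMRGrid:
    """Random register built by storing 1-4 random functions (no empty column)."""
    n = int(rng.integers(1, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    amr = AMRGrid(n, m)
    for _ in range(int(rng.integers(1, 5))):
        amr.register(rng.integers(1, m + 1, size=n))
    return amr
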