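import numpy as np
import pytest
from hypothesis import strategies as st

from densid.data import FILAMENT_MOTIF
from densid.pattern import AMINO_ACIDS, AmbiguityPattern, BackgroundModel, parse_pattern


@pytest.fixture(scope="session")
def motif() -> AmbiguityPattern:
    """The 11-residue density-derived filament motif."""
    return parse_pattern(FILAMENT_MOTIF)


@pytest.fixture(scope="session")
def uniform_bg() -> BackgroundModel:
    return BackgroundModel.uniform()


def random_pattern(rng: np.random.Generator, m: int) -> AmbiguityPattern:
    """Seeded random pattern mixing fixed, class and wildcard positions."""
    positions = []
    for _ in range(m):
        kind = rng.integers(0, 4)
        if kind == 0:
            positions.append(frozenset(AMINO_ACIDS))
        else:
            k = int(rng.integers(1, 7))
            letters = rng.choice(list(AMINO_ACIDS), size=k, replace=False)
            positions.append(frozenset(letters))
    return AmbiguityPattern(tuple(positions))


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


# hypothesis strategies shared between modules
aa_class = st.frozensets(st.sampled_from(AMINO_ACIDS), min_size=1, max_size=20)
patterns = st.builds(
    lambda classes: AmbiguityPattern(tuple(classes)),
    st.lists(aa_class, min_size=1, max_size=12),
)
sequences = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=80)
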