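import numpy as np
import pytest

from strandscape import Grammar, SecondaryStructure


@pytest.fixture
def grammar() -> Grammar:
    return Grammar()


@pytest.fixture
def hairpin12() -> SecondaryStructure:
    """((((....)))) on a 12-mer."""
    return SecondaryStructure.from_dot_bracket("((((....))))")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
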