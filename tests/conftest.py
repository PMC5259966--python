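import numpy as np
import pytest

from protlm import (
    Corpus,
    ProteinSequence,
    SmoothingConfig,
    random_chain_spec,
    well_separated_pair,
)

ALPHABET4 = "ACDE"


def make_corpus(strings, label="test", prefix="s"):
    return Corpus(
        label=label,
        sequences=tuple(
            ProteinSequence(id=f"{prefix}{i}", residues=s) for i, s in enumerate(strings, 1)
        ),
    )


@pytest.fixture
def corpus4():
    """Small fixed corpus over the 4-letter reduced alphabet."""
    return make_corpus(["ACDEACDE", "CCAADDEE", "ADADADAD", "ECDCECDC"])


@pytest.fixture
def smoothing4():
    return SmoothingConfig(method="add-k", k=0.01, alphabet_size=4)


@pytest.fixture
def mle4():
    return SmoothingConfig(method="none", alphabet_size=4)


@pytest.fixture
def chain_pair4():
    """Two well-separated order-2 chains over the reduced alphabet."""
    return well_separated_pair(ALPHABET4, order=2, seed=0)


@pytest.fixture
def order2_spec4():
    return random_chain_spec(ALPHABET4, order=2, seed=7, concentration=1.0)


def random_small_corpus(rng: np.random.Generator, alphabet=ALPHABET4,
                        max_seqs=5, max_len=8, min_len=1, label="rand"):
    """A random tiny corpus for oracle-equivalence checks."""
    n = int(rng.integers(1, max_seqs + 1))
    strings = []
    for _ in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        strings.append("".join(alphabet[i] for i in rng.integers(0, len(alphabet), L)))
    return make_corpus(strings, label=label)
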