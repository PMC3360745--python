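import numpy as np
import pytest

from motifstream import (EncodedSequence, encode_sequence,
                         fit_markov_background, uniform_background)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_sequences(rng):
    """50 random 200 bp sequences with a fitted third-order background."""
    seqs = [EncodedSequence(f"s{i:03d}", rng.integers(1, 5, 200).astype(np.int8))
            for i in range(50)]
    bg = fit_markov_background(seqs, order=3, pseudocount=1.0)
    return seqs, bg


@pytest.fixture
def uniform_bg():
    return uniform_background(order=0)


@pytest.fixture
def toy_sequences():
    return [encode_sequence("ACGTACGTACGTACG", f"t{i}") for i in range(4)]
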