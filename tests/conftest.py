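import numpy as np
import pytest

from ppikernel.io_formats import ProteinRecord, ScoreTable
from ppikernel.synthetic import MINI_SCORE_TABLE

from helpers import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def score_table():
    return ScoreTable(MINI_SCORE_TABLE)


@pytest.fixture
def small_proteome(rng):
    """40 mutually unrelated proteins of 60-100 residues (fast to align)."""
    return [
        ProteinRecord(f"q{i:03d}", random_sequence(rng, int(rng.integers(60, 101))))
        for i in range(40)
    ]
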