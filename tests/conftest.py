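import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import matplotlib

matplotlib.use("Agg")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def banana_pair():
    from kpeakdist import SequencePair

    return SequencePair("banana", "ananas", id1="banana", id2="ananas", alphabet="text")
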