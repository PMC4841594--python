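import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20160422)


def random_dna(rng, n, with_n=False):
    alphabet = list("ACGTN") if with_n else list("ACGT")
    p = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(alphabet, size=n, p=p))
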