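import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20140)


def random_protein(rng, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def random_cds(rng, n_codons: int) -> str:
    from ctldcp.codons import SENSE_CODONS

    return "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=n_codons))
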