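import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from recold import Repertoire


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_pair():
    """Two small handmade repertoires sharing one sequence."""
    a = Repertoire.from_counts("A", {"CAAS": 3, "CAAT": 2, "CARW": 1})
    b = Repertoire.from_counts("B", {"CAAS": 1, "CWWT": 4})
    return a, b


def random_peptides(rng, n, lengths=(8, 16), alphabet="ACDEFGHIKLMNPQRSTVWY"):
    """Distinct random amino-acid strings."""
    out = set()
    while len(out) < n:
        k = int(rng.integers(lengths[0], lengths[1] + 1))
        out.add("".join(alphabet[i] for i in rng.integers(0, len(alphabet), k)))
    return sorted(out)
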