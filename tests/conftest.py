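import numpy as np
import pytest

from aglscan.blup import Pedigree


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_pedigree(rng, n_founders, n_total):
    """Random valid pedigree: founders first, then animals with random
    earlier parents (possibly unknown)."""
    records = [(i, 0, 0) for i in range(1, n_founders + 1)]
    for i in range(n_founders + 1, n_total + 1):
        s = int(rng.integers(1, i))
        d = int(rng.integers(1, i))
        if d == s:
            d = 0
        records.append((i, s, d))
    return Pedigree.from_records(records)


@pytest.fixture
def make_random_pedigree(rng):
    return lambda n_founders, n_total: random_pedigree(rng, n_founders, n_total)
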