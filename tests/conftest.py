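import numpy as np
import pytest

from classdiv import CANONICAL_AA, Repertoire

ALPHABET = list(CANONICAL_AA)


def random_repertoire(
    rng: np.random.Generator,
    n_unique: int,
    min_len: int = 8,
    max_len: int = 18,
    max_count: int = 50,
) -> Repertoire:
    """Random repertoire with unique sequences and skewed integer counts."""
    seqs = set()
    while len(seqs) < n_unique:
        length = int(rng.integers(min_len, max_len + 1))
        seqs.add("".join(rng.choice(ALPHABET, size=length)))
    counts = rng.integers(1, max_count + 1, size=n_unique)
    return Repertoire(sorted(seqs), counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def make_repertoire(rng):
    def _make(n_unique=30, **kwargs):
        return random_repertoire(rng, n_unique, **kwargs)

    return _make


@pytest.fixture
def path_p3():
    """Three sequences forming a distance-1 path A-B-C (d(A,C)=2)."""
    return Repertoire(["CAAAAA", "CAAAAG", "CAAAGG"], [1, 1, 1])
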