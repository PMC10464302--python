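import numpy as np
import pytest

from parse2.scales import CANONICAL_RESIDUES

AA = "".join(CANONICAL_RESIDUES)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def random_labels(rng: np.random.Generator, length: int, stay: float = 0.9):
    """Markov label string over F/P/D with sticky runs (so that regions
    of realistic length actually occur)."""
    labels = ["FPD"[rng.integers(3)]]
    for _ in range(length - 1):
        if rng.random() < stay:
            labels.append(labels[-1])
        else:
            labels.append("FPD"[rng.integers(3)])
    return "".join(labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def make_protein(rng):
    def _make(length: int) -> str:
        return random_protein(rng, length)

    return _make
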