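import numpy as np
import pytest

from bfoamsa.alignment import Bacterium, cuadra
from bfoamsa.families import load_bundled_family

PROTEIN = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"


def random_bacterium(
    rng: np.random.Generator,
    n: int,
    m: int,
    gap_frac: float = 0.25,
    alphabet: str = "protein",
) -> Bacterium:
    """A random rectangular alignment with roughly gap_frac gaps."""
    letters = np.array(list(PROTEIN if alphabet == "protein" else DNA))
    rows = []
    for _ in range(n):
        chars = rng.choice(letters, size=m)
        gaps = rng.random(m) < gap_frac
        row = "".join("-" if g else c for c, g in zip(chars, gaps))
        # keep at least one residue per row so the bacterium stays a valid alignment
        if row.count("-") == m:
            row = str(rng.choice(letters)) + row[1:]
        rows.append(row)
    return cuadra(Bacterium(rows))


@pytest.fixture(scope="session")
def protein_family():
    return load_bundled_family("protein_small")


@pytest.fixture(scope="session")
def dna_family():
    return load_bundled_family("dna_small")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
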