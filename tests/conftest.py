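import numpy as np
import pytest

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def mutate_snps(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in np.flatnonzero(rng.random(len(chars)) < rate):
        chars[i] = BASES[(BASES.index(chars[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
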