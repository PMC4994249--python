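import numpy as np
import pytest

ALPHABET = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def brute_kmer_counts(s: str, k: int) -> dict[str, int]:
    """Exhaustive substring-scan oracle for k-mer occurrence counts."""
    counts: dict[str, int] = {}
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160822)
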