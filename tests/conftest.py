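import numpy as np
import pytest
from hypothesis import settings

from biobit import GenomeSequence, generate_random_genome

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def tiny() -> GenomeSequence:
    return GenomeSequence.from_text("acgtacgt")


@pytest.fixture
def random_1e4() -> GenomeSequence:
    return generate_random_genome(10_000, 123)


@pytest.fixture(scope="session")
def random_1e6() -> GenomeSequence:
    return generate_random_genome(1_000_000, 123)


def brute_mrl(s: str) -> int:
    """Longest repeated-substring length by exhaustive window hashing."""
    for L in range(len(s) - 1, 0, -1):
        seen = set()
        for i in range(len(s) - L + 1):
            w = s[i:i + L]
            if w in seen:
                return L
            seen.add(w)
    return 0


def brute_counts(genome: GenomeSequence, k: int) -> dict:
    """Naive per-run k-mer dictionary with multiplicities."""
    counts: dict = {}
    for run in genome.runs:
        for i in range(len(run) - k + 1):
            w = run[i:i + k]
            counts[w] = counts.get(w, 0) + 1
    return counts


def random_text(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("acgt"), size=n))
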