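"""Seeded Bernoullian genomes and repeat-length statistics.

A Bernoullian genome draws each base iid uniformly from {a, c, g, t}. In
such genomes the expected maximal repeat length satisfies
avg(mrl + 1) ~ lg2(n): balancing the chance that a k-mer occurs,
(n - k + 1) / 4^k, against the chance it occurs exactly once,
1 / (n - k + 1), gives 2^k ~ n - k + 1 as the shortest all-hapax length.
``mrl_trials`` reproduces that experiment: repeated random genomes per
length, aggregating min / max / sd / avg of mrl + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kmer import mrl
from .sequence_io import GenomeSequence

__all__ = [
    "RandomTrialStats",
    "generate_random_genome",
    "expected_hapax_length",
    "mrl_trials",
]

_BASES = np.frombuffer(b"acgt", dtype=np.uint8)

# refuse absurd lengths unless the caller raises the cap explicitly
DEFAULT_LENGTH_CAP = 200_000_000


def generate_random_genome(n: int, seed) -> GenomeSequence:
    """Single-run random genome of length n, reproducible for a given seed.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 4, size=n, dtype=np.uint8)
    run = _BASES[arr].tobytes().decode("ascii")
    label = seed if isinstance(seed, int) else "seedseq"
    return GenomeSequence((run,), source_label=f"random(n={n},seed={label})")


def expected_hapax_length(n: int) -> int:
    """Smallest integer k with 2^k >= n - k + 1: the estimated minimum word
    length at which a random genome of length n is all-hapax, i.e. an
    estimate of mrl + 1 (close to ceil(lg2 n))."""
    if n < 16:
        raise ValueError("n must be >= 16")
    k = 1
    while (1 << k) < n - k + 1:
        k += 1
    return k


@dataclass(frozen=True)
class RandomTrialStats:
    """min / max / sd / avg of mrl + 1 over repeated random genomes of one
    length, alongside lg2(length) for comparison."""

    length: int
    trials: int
    min: int
    max: int
    sd: float
    avg: float
    lg2n: float

    def table_row(self) -> dict:
        return {
            "length": self.length, "min": self.min, "max": self.max,
            "sd": round(self.sd, 2), "avg": round(self.avg, 2),
            "lg2": round(self.lg2n, 2),
        }


def mrl_trials(lengths: Sequence[int], trials: int, seed: int,
               *, length_cap: int = DEFAULT_LENGTH_CAP) -> list[RandomTrialStats]:
    """For each length, generate ``trials`` independent random genomes and
    aggregate mrl + 1.

    Per-trial seeds are spawned deterministically from the master seed
    (counter-based), so the whole table is reproducible and any trial can
    be regenerated in isolation.
    """
    if trials < 2:
        raise ValueError("need at least 2 trials for a standard deviation")
    for n in lengths:
        if n <= 0:
            raise ValueError("lengths must be positive")
        if n > length_cap:
            raise ValueError(f"length {n} exceeds cap {length_cap}")
    master = np.random.SeedSequence(seed)
    children = iter(master.spawn(len(lengths) * trials))
    out = []
    for n in lengths:
        vals = np.array([mrl(generate_random_genome(n, next(children))) + 1
                         for _ in range(trials)], dtype=np.int64)
        out.append(RandomTrialStats(
            length=n, trials=trials,
            min=int(vals.min()), max=int(vals.max()),
            sd=float(vals.std(ddof=1)), avg=float(vals.mean()),
            lg2n=math.log2(n),
        ))
    return out
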