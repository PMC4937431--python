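"""Empirical k-entropies and their theoretical bounds.

The empirical k-entropy of a genome is the Shannon entropy of the k-mer
frequency distribution, E_k = -sum_w f(w) lg2 f(w) with f(w) =
mult(w) / W_k, where W_k is the total number of k-mer occurrences. Only
words actually occurring contribute; no distributional model is assumed.

Random (Bernoullian) genomes of length n reach their entropy maximum at
word length lg2(n) — the double logarithmic length — where essentially all
words are hapaxes. E_{2LG} denotes the linear interpolation of E_k between
the integers bracketing lg2(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

from .kmer import KmerSpectrum, kmer_spectrum
from .sequence_io import GenomeSequence

__all__ = [
    "EntropyProfile",
    "empirical_entropy",
    "entropy_profile",
    "interpolated_e2lg",
    "bracketing_k",
    "max_entropy_bound",
    "global_entropy_bound",
    "random_entropy_gap_bound",
]


def empirical_entropy(spectrum: KmerSpectrum) -> float:
    """Shannon entropy (bits) of the k-mer frequency distribution.

    Computed from the multiplicity histogram: words sharing a multiplicity
    m contribute identical terms, so
    E = lg2(W) - (1/W) * sum_m count(m) * m * lg2(m).
    """
    w = spectrum.occurrences
    if w < 1:
        raise ValueError("empty spectrum")
    s = sum(c * m * math.log2(m) for m, c in spectrum.mult_histogram.items() if m > 1)
    return math.log2(w) - s / w


def bracketing_k(n: int) -> tuple[int, int]:
    """Integers k1 <= 2LG <= k2 used for interpolation at 2LG = lg2(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    two_lg = math.log2(n)
    k1 = math.floor(two_lg)
    k2 = math.ceil(two_lg)
    return k1, k2


@dataclass
class EntropyProfile:
    """E_k over a k range, plus the interpolated entropy at 2LG."""

    genome_label: str
    n: int
    points: Dict[int, float]
    e_2lg: Optional[float]
    k1: int
    k2: int


def entropy_profile(genome: GenomeSequence, k_min: int, k_max: int) -> EntropyProfile:
    """Compute E_k for every k in [k_min, k_max].

    ``e_2lg`` is populated when both bracketing integers of lg2(n) fall in
    the range (and fit in some run); otherwise it is None.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max > genome.max_run_length:
        raise ValueError("k_max exceeds the longest unambiguous run")
    points = {k: empirical_entropy(kmer_spectrum(genome, k))
              for k in range(k_min, k_max + 1)}
    k1, k2 = bracketing_k(genome.n)
    prof = EntropyProfile(genome.source_label, genome.n, points, None, k1, k2)
    if k1 in points and k2 in points:
        prof.e_2lg = interpolated_e2lg(prof, genome.n)
    return prof


def interpolated_e2lg(profile: EntropyProfile, n: int) -> float:
    """Linear interpolation of E_k at 2LG = lg2(n).

    For integer lg2(n) this is E_{2LG} itself; otherwise
    E_{k1} + (2LG - k1) * (E_{k2} - E_{k1}).
    """
    k1, k2 = bracketing_k(n)
    if k1 not in profile.points or k2 not in profile.points:
        raise ValueError(f"profile lacks E_{k1} / E_{k2}")
    e1 = profile.points[k1]
    if k1 == k2:
        return e1
    e2 = profile.points[k2]
    return e1 + (math.log2(n) - k1) * (e2 - e1)


def max_entropy_bound(n: int, k: int) -> float:
    """Maximum of E_k over genomes of length n: lg2(n - k + 1).

    Attained when all k-mers are hapaxes (equipartition over n - k + 1
    words); always <= the global bound lg2(n).
    """
    if not 1 <= k < n:
        raise ValueError("need 1 <= k < n")
    return math.log2(n - k + 1)


def global_entropy_bound(n: int) -> float:
    """lg2(n): upper bound of every E_k over genomes of length n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.log2(n)


def random_entropy_gap_bound(n: int) -> float:
    """Bound on lg2(n) - E_k for random genomes at k = ceil(lg2 n).

    Equals lg2(n / (n - ceil(lg2 n) + 1)); tends to 0 as n grows, which is
    why the entropy of a random genome at the double logarithmic length can
    be taken as lg2(n) itself.
    """
    k = math.ceil(math.log2(n))
    if n <= k:
        raise ValueError("n too small for the bound")
    return math.log2(n / (n - k + 1))
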