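import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biobit import (
    GenomeSequence,
    empirical_entropy,
    entropy_profile,
    generate_random_genome,
    global_entropy_bound,
    interpolated_e2lg,
    kmer_spectrum,
    max_entropy_bound,
    mrl,
    random_entropy_gap_bound,
)
from biobit.entropy import EntropyProfile, bracketing_k

from conftest import brute_counts

dna = st.text(alphabet="acgt", min_size=2, max_size=200)


@pytest.mark.parametrize("text, k, expected", [
    ("aaaa", 1, 0.0),
    ("acgt", 1, 2.0),
    ("acgtacgt", 2, (6 / 7) * math.log2(7 / 2) + (1 / 7) * math.log2(7)),
])
def test_entropy_examples(text, k, expected):
    e = empirical_entropy(kmer_spectrum(GenomeSequence.from_text(text), k))
    assert e == pytest.approx(expected, abs=1e-12)


@given(dna, st.integers(1, 6))
@settings(max_examples=120, deadline=None)
def test_entropy_matches_wordwise_oracle(text, k):
    g = GenomeSequence.from_text(text)
    if k > g.max_run_length:
        return
    counts = brute_counts(g, k)
    w = sum(counts.values())
    expected = -sum((c / w) * math.log2(c / w) for c in counts.values())
    got = empirical_entropy(kmer_spectrum(g, k))
    assert got == pytest.approx(expected, abs=1e-10)
    # equipartition: never above lg2 of the occurrence total
    assert got <= math.log2(w) + 1e-12


def test_entropy_profile_increasing_for_random_genome():
    g = generate_random_genome(4096, 7)
    prof = entropy_profile(g, 1, 12)
    es = [prof.points[k] for k in range(1, 13)]
    assert all(b > a for a, b in zip(es, es[1:]))
    assert prof.e_2lg == pytest.approx(prof.points[12])  # lg2(4096) = 12


def test_profile_plateau_above_mrl():
    # beyond the maximal repeat length all words are hapaxes: E_k = lg2(W_k)
    g = generate_random_genome(2000, 3)
    m = mrl(g)
    for k in (m + 1, m + 2):
        sp = kmer_spectrum(g, k)
        assert sp.repeat_count == 0
        e = empirical_entropy(sp)
        assert e == pytest.approx(math.log2(sp.occurrences), abs=1e-12)


def test_profile_range_validation(tiny):
    with pytest.raises(ValueError):
        entropy_profile(tiny, 3, 2)
    with pytest.raises(ValueError):
        entropy_profile(tiny, 1, 9)
    prof = entropy_profile(tiny, 1, 2)
    assert prof.e_2lg is None  # 2LG = 3 outside the computed range


def test_interpolation_weights():
    prof = EntropyProfile("x", 0, {10: 10.0, 11: 11.0}, None, 10, 11)
    n = round(2 ** 10.25)
    k1, k2 = bracketing_k(n)
    assert (k1, k2) == (10, 11)
    got = interpolated_e2lg(prof, n)
    assert got == pytest.approx(10 + (math.log2(n) - 10), abs=1e-12)


def test_interpolation_integer_case():
    prof = EntropyProfile("x", 1024, {10: 9.5}, None, 10, 10)
    assert interpolated_e2lg(prof, 1024) == 9.5
    with pytest.raises(ValueError):
        interpolated_e2lg(prof, 2000)  # needs E_11 too


def test_human_scale_bracketing():
    k1, k2 = bracketing_k(3_200_000_000)
    assert (k1, k2) == (31, 32)


def test_max_entropy_bound_values():
    assert max_entropy_bound(1000, 10) == pytest.approx(math.log2(991))
    assert max_entropy_bound(4, 1) == 2.0
    for n, k in [(100, 3), (10**6, 20)]:
        assert max_entropy_bound(n, k) <= global_entropy_bound(n)
    with pytest.raises(ValueError):
        max_entropy_bound(10, 10)


def test_random_entropy_gap_bound_values():
    assert random_entropy_gap_bound(1024) == pytest.approx(math.log2(1024 / 1015))
    assert random_entropy_gap_bound(10**6) == pytest.approx(2.9e-5, rel=0.1)
    # decreasing in n along doublings (within a dyadic block the bound also
    # falls, but it jumps up whenever ceil(lg2 n) increments)
    bounds = [random_entropy_gap_bound(2 ** m) for m in range(5, 24)]
    assert all(b < a for a, b in zip(bounds, bounds[1:]))
    assert all(random_entropy_gap_bound(2 * n) < random_entropy_gap_bound(n)
               for n in (100, 999, 12345))


@pytest.mark.parametrize("n", [10_000, 100_000, 1_000_000])
def test_random_genome_entropy_gap_near_bound(n):
    """Random genomes attain the lg2(n) entropy ceiling at k = ceil(lg2 n)
    up to a gap of the order of the theoretical balance bound.

    The gap can never drop below the bound (equipartition gives
    E_k <= lg2(n - k + 1), with equality in the all-hapax case); stray
    repeats push it slightly above, so twice the bound is the honest
    envelope.
    """
    k = math.ceil(math.log2(n))
    bound = random_entropy_gap_bound(n)
    for seed in range(20):
        g = generate_random_genome(n, 1000 + seed)
        gap = math.log2(n) - empirical_entropy(kmer_spectrum(g, k))
        assert bound - 1e-12 <= gap <= 2 * bound
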