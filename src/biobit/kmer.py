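"""k-mer dictionaries, multiplicity spectra and the maximal repeat length.

Words are extracted within unambiguous runs only, overlapping occurrences
count, and the occurrence total for word length k is
``W_k = sum over runs of max(0, |run| - k + 1)`` (the single-run ``n - k + 1``
generalized to split genomes).

Two backends implement the same contracts:

* packed 2-bit integer codes (one ``uint64`` per word up to k = 32, a pair
  up to k = 64) sorted with numpy — the default for spectra and for the
  maximal-repeat fast path;
* a prefix-doubling suffix array with Kasai LCP over the sentinel-joined
  runs (:class:`SuffixStructure`) — the general path, used when a repeat of
  length >= 32 exists or the run structure defeats the packed codes.

Both are exact; their agreement is part of the test contract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict

import numpy as np

from .sequence_io import GenomeSequence

__all__ = [
    "KmerSpectrum",
    "SuffixStructure",
    "EmptySpectrumError",
    "kmer_spectrum",
    "mrl",
    "build_suffix_structure",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

# covered-window length of the packed fast path (32 bases fill a uint64)
_FAST_K = 32
# above this many uncovered tail windows, the suffix-array path is cheaper
_TAIL_BUDGET = 200_000


class EmptySpectrumError(ValueError):
    """k exceeds the length of every run: no k-mer exists."""


def encode_run(run: str) -> np.ndarray:
    """Map a run over {a,c,g,t} to a uint8 array of 2-bit codes."""
    arr = _CODE[np.frombuffer(run.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError("run contains non-acgt symbols")
    return arr


def _combine(a_codes: np.ndarray, a: int, b_codes: np.ndarray, b: int,
             n: int) -> np.ndarray:
    """Codes of width a+b from width-a codes followed by width-b codes."""
    m = n - a - b + 1
    return (a_codes[:m] << np.uint64(2 * b)) | b_codes[a:a + m]


def _pack_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """uint64 codes of all k-mers of ``arr`` (k <= 32), left-to-right packed.

    Built by binary doubling of code widths: O(log k) vectorized passes.
    """
    n = len(arr)
    base = arr.astype(np.uint64)
    acc: np.ndarray | None = None
    width = 0
    for bit in reversed(range(k.bit_length())):
        if acc is not None:
            acc = _combine(acc, width, acc, width, n)
            width *= 2
        if (k >> bit) & 1:
            if acc is None:
                acc, width = base, 1
            else:
                acc = _combine(acc, width, base, 1, n)
                width += 1
    return acc


@dataclass(frozen=True)
class KmerSpectrum:
    """Multiplicity spectrum of the k-mer dictionary D_k of one genome.

    ``occurrences`` is W_k; ``mult_histogram`` maps a multiplicity value to
    the number of distinct words having it, so
    ``sum(m * c for m, c in mult_histogram.items()) == occurrences``.
    """

    k: int
    distinct: int
    occurrences: int
    mult_histogram: Dict[int, int]
    hapax_count: int
    repeat_count: int

    def __post_init__(self) -> None:
        assert self.hapax_count + self.repeat_count == self.distinct
        assert sum(m * c for m, c in self.mult_histogram.items()) == self.occurrences


def _spectrum_from_counts(k: int, counts: np.ndarray) -> KmerSpectrum:
    mults, ncounts = np.unique(counts, return_counts=True)
    hist = {int(m): int(c) for m, c in zip(mults, ncounts)}
    distinct = int(counts.size)
    hapax = hist.get(1, 0)
    return KmerSpectrum(
        k=k,
        distinct=distinct,
        occurrences=int(counts.sum()),
        mult_histogram=hist,
        hapax_count=hapax,
        repeat_count=distinct - hapax,
    )


def kmer_spectrum(genome: GenomeSequence, k: int) -> KmerSpectrum:
    """Count the distinct k-mers of a genome and their multiplicities.

    Raises :class:`EmptySpectrumError` when no run is long enough to hold a
    single k-mer.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    runs = [r for r in genome.runs if len(r) >= k]
    if not runs:
        raise EmptySpectrumError(f"no run of length >= {k}")

    if k <= _FAST_K:
        codes = np.concatenate([_pack_codes(encode_run(r), k) for r in runs])
        codes.sort()
        counts = np.diff(np.flatnonzero(
            np.r_[True, codes[1:] != codes[:-1], True]))
    elif k <= 2 * _FAST_K:
        his, los = [], []
        for r in runs:
            arr = encode_run(r)
            m = len(arr) - k + 1
            his.append(_pack_codes(arr, _FAST_K)[:m])
            los.append(_pack_codes(arr[_FAST_K:], k - _FAST_K)[:m])
        hi = np.concatenate(his)
        lo = np.concatenate(los)
        order = np.lexsort((lo, hi))
        hi, lo = hi[order], lo[order]
        new = np.r_[True, (hi[1:] != hi[:-1]) | (lo[1:] != lo[:-1]), True]
        counts = np.diff(np.flatnonzero(new))
    else:
        ctr: Counter = Counter()
        for r in runs:
            for i in range(len(r) - k + 1):
                ctr[r[i:i + k]] += 1
        counts = np.fromiter(ctr.values(), dtype=np.int64)
    return _spectrum_from_counts(k, counts)


# ---------------------------------------------------------------------------
# Suffix structure: prefix-doubling suffix array + Kasai LCP


def _suffix_array(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Suffix array and rank (position -> rank) by prefix doubling."""
    n = len(t)
    rank = np.unique(t, return_inverse=True)[1].astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    if n == 1:
        return sa, rank
    step = 1
    tmp = np.empty(n, dtype=np.int64)
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[:n - step] = rank[step:]
        sa = np.lexsort((second, rank))
        r1, r2 = rank[sa], second[sa]
        changed = np.r_[False, (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])]
        tmp[sa] = np.cumsum(changed)
        rank = tmp.copy()
        if rank[sa[-1]] == n - 1:
            return sa, rank
        step *= 2


def _kasai_lcp(t: np.ndarray, sa: np.ndarray, rank: np.ndarray) -> np.ndarray:
    """lcp[r] = longest common prefix of suffixes sa[r-1] and sa[r]."""
    n = len(t)
    lcp = np.zeros(n, dtype=np.int64)
    tl, sal, rl = t.tolist(), sa.tolist(), rank.tolist()
    h = 0
    for i in range(n):
        r = rl[i]
        if r > 0:
            j = sal[r - 1]
            while i + h < n and j + h < n and tl[i + h] == tl[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


class SuffixStructure:
    """Suffix array + LCP over the sentinel-joined runs of a genome.

    Runs are concatenated with pairwise-distinct sentinel values, so no
    common prefix (hence no k-mer group and no repeat) ever spans a run
    boundary.
    """

    def __init__(self, genome: GenomeSequence):
        parts = []
        valid = []  # per position: distance to the next sentinel / end
        for i, run in enumerate(genome.runs):
            arr = encode_run(run).astype(np.int64)
            parts.append(arr)
            valid.append(np.arange(len(arr), 0, -1, dtype=np.int64))
            if i < len(genome.runs) - 1:
                parts.append(np.array([4 + i], dtype=np.int64))
                valid.append(np.zeros(1, dtype=np.int64))
        self._t = np.concatenate(parts)
        self._valid = np.concatenate(valid)
        self.sa, self._rank = _suffix_array(self._t)
        self.lcp = _kasai_lcp(self._t, self.sa, self._rank)

    def longest_repeat_length(self) -> int:
        """Length of the longest substring occurring >= 2 times (0 if none)."""
        return int(self.lcp.max(initial=0))

    def kmer_multiplicities(self, k: int) -> np.ndarray:
        """Multiplicity of every distinct k-mer, from suffix-array groups.

        A k-mer group is a maximal block of suffix-array-adjacent suffixes
        (with >= k unambiguous characters) sharing an LCP >= k.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        keep = self._valid[self.sa] >= k
        counts = []
        current = 0
        prev_kept = False
        for r in range(len(self.sa)):
            if not keep[r]:
                prev_kept = False
                continue
            if prev_kept and self.lcp[r] >= k:
                current += 1
            else:
                if current:
                    counts.append(current)
                current = 1
            prev_kept = True
        if current:
            counts.append(current)
        return np.asarray(counts, dtype=np.int64)

    def spectrum(self, k: int) -> KmerSpectrum:
        counts = self.kmer_multiplicities(k)
        if counts.size == 0:
            raise EmptySpectrumError(f"no run of length >= {k}")
        return _spectrum_from_counts(k, counts)


def build_suffix_structure(genome: GenomeSequence) -> SuffixStructure:
    return SuffixStructure(genome)


# ---------------------------------------------------------------------------
# Maximal repeat length


def _adjacent_prefix_max(codes: np.ndarray) -> int:
    """Max common-prefix length (bases) among sorted full-width codes.

    Returns _FAST_K when two codes are identical. The pair with the most
    leading zero bits in the XOR of adjacent sorted codes is the pair with
    the smallest XOR, and codes are 2-bit aligned across the full word.
    """
    if codes.size < 2:
        return 0
    codes.sort()
    x = codes[1:] ^ codes[:-1]
    mn = int(x.min())
    if mn == 0:
        return _FAST_K
    return (64 - mn.bit_length()) // 2


def _tail_windows(genome: GenomeSequence, lo: int):
    """Windows of length in (lo, 32) not covered by a full 32-base code.

    Yields (length, run_index, start, word) in globally descending length
    order. A window starting at p in a run is covered by the packed fast
    path iff p + 32 <= |run|.
    """
    top = min(_FAST_K - 1, genome.max_run_length)
    for L in range(top, lo, -1):
        for ri, run in enumerate(genome.runs):
            if len(run) < L:
                continue
            first_uncovered = max(0, len(run) - _FAST_K + 1)
            for p in range(first_uncovered, len(run) - L + 1):
                yield L, ri, p, run[p:p + L]


def _count_tail_windows(genome: GenomeSequence) -> int:
    total = 0
    for run in genome.runs:
        u = min(len(run), _FAST_K - 1)
        total += u * (u + 1) // 2
    return total


def mrl(genome: GenomeSequence) -> int:
    """Maximal repeat length: the largest L such that some word of length L
    occurs at least twice (overlaps count); 0 for a repeat-free genome.

    Every k-mer with k > mrl is a hapax, and at k = mrl some repeat exists.
    """
    if genome.n < 2:
        return 0
    covered = [r for r in genome.runs if len(r) >= _FAST_K]
    if not covered or _count_tail_windows(genome) > _TAIL_BUDGET:
        return build_suffix_structure(genome).longest_repeat_length()

    codes = np.concatenate([_pack_codes(encode_run(r), _FAST_K) for r in covered])
    core = _adjacent_prefix_max(codes)
    if core >= _FAST_K:
        # a repeat of length >= 32 exists; only the suffix structure can size it
        return build_suffix_structure(genome).longest_repeat_length()

    # windows shorter than 32 near run ends are not covered by the packed
    # codes; check whether any of them beats the core estimate
    best = core
    seen: dict[str, tuple[int, int]] = {}
    cur_len = None
    for L, ri, p, w in _tail_windows(genome, core):
        if L <= best:
            break
        if L != cur_len:
            seen.clear()
            cur_len = L
        other = seen.get(w)
        if other is not None and other != (ri, p):
            best = L
            break
        seen[w] = (ri, p)
        # match against a covered window: covered 32-mers with prefix w form
        # a contiguous code range
        shift = 2 * (_FAST_K - L)
        lo_code = np.uint64(w_code(w) << shift)
        hi_code = np.uint64((w_code(w) << shift) | ((1 << shift) - 1))
        a = int(np.searchsorted(codes, lo_code, side="left"))
        b = int(np.searchsorted(codes, hi_code, side="right"))
        if b > a:
            best = L
            break
    return best


def w_code(word: str) -> int:
    """2-bit packed integer code of a word (for words up to 32 bases)."""
    c = 0
    for ch in word:
        c = (c << 2) | int(_CODE[ord(ch)])
    return c
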