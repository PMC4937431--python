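"""Deterministic synthetic genomes spanning the order/randomness spectrum.

Four kinds:

* ``random`` — Bernoullian genome (AF ~ 0, the disorder end);
* ``periodic`` — a short motif tiled to length n (maximal order for the
  length; AF near its maximum, BB collapses);
* ``block-mixture`` — a periodic block of ``ordered_fraction * n`` bases
  followed by a random block (interpolates AC between the two ends; the
  fraction is a generator knob, not a biological quantity);
* ``literal`` — an explicit hand-checkable string.

These are the "ideal genomes": mathematically convenient strings with no
biological meaning, used to probe the informational indexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .random_sim import generate_random_genome
from .sequence_io import GenomeSequence

__all__ = ["FixtureSpec", "make_fixture"]

KINDS = ("random", "periodic", "block-mixture", "literal")


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n: int = 0
    seed: int = 0
    period: str = "acgt"
    ordered_fraction: float = 0.0
    literal: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.kind == "literal":
            if not self.literal:
                raise ValueError("literal fixture needs text")
        elif self.n < 1:
            raise ValueError("n must be >= 1")
        if self.kind == "block-mixture" and not 0 <= self.ordered_fraction <= 1:
            raise ValueError("ordered_fraction must be in [0, 1]")
        if self.kind in ("periodic", "block-mixture") and not self.period:
            raise ValueError("period must be non-empty")


def _periodic(period: str, n: int) -> str:
    reps = -(-n // len(period))
    return (period * reps)[:n]


def make_fixture(spec: FixtureSpec) -> GenomeSequence:
    """Build the genome a spec describes; deterministic for (spec, seed)."""
    if spec.kind == "literal":
        return GenomeSequence.from_text(spec.literal, source_label="literal")
    if spec.kind == "random":
        return generate_random_genome(spec.n, spec.seed)
    if spec.kind == "periodic":
        return GenomeSequence((_periodic(spec.period.lower(), spec.n),),
                              source_label=f"periodic({spec.period},n={spec.n})")
    # block-mixture: ordered prefix + random remainder, one run
    n_ord = round(spec.ordered_fraction * spec.n)
    parts = []
    if n_ord:
        parts.append(_periodic(spec.period.lower(), n_ord))
    if spec.n - n_ord:
        parts.append(generate_random_genome(spec.n - n_ord, spec.seed).runs[0])
    label = f"mixture(f={spec.ordered_fraction},n={spec.n},seed={spec.seed})"
    return GenomeSequence(("".join(parts),), source_label=label)
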