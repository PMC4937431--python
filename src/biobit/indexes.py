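"""Informational genomic indexes and the biobit complexity measure.

A genome of effective length n splits its logarithmic length
LG = lg4(n) into an entropic and an anti-entropic component:

    EC = E_2LG - LG        AC = 2LG - E_2LG        EC + AC = LG

where E_2LG is the empirical entropy interpolated at the double logarithmic
length 2LG = lg2(n). AC measures the informational distance of the genome
from random genomes of the same length (which have AC ~ 0); EC measures the
randomness the genome retains. Derived quantities:

    LX = W_2LG / |D_2LG|   (lexical index, 1 in the random limit)
    AF = AC / LG           (anti-entropic fraction)
    EH = (EC - AC) / LG = 1 - 2 AF   (horizontal eccentricity)
    BB = scale * AF**gamma * (1 - 2 AF)**delta   (biobit)

BB is a generalized logistic balance of order (AC) and randomness (EC): it
vanishes both for random genomes (AF = 0) and for totally ordered ones
(AF = 1/2) and peaks at AF* = gamma / (2 gamma + 2 delta).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Optional

from .entropy import bracketing_k, empirical_entropy
from .kmer import kmer_spectrum
from .sequence_io import GenomeSequence

__all__ = [
    "BBParams",
    "Components",
    "InformationalIndexes",
    "logarithmic_length",
    "double_logarithmic_length",
    "components",
    "lexical_index",
    "biobit",
    "biobit_argmax",
    "compute_indexes",
]

TABLE_COLUMNS = ("LG", "EC", "AC", "LX", "AF", "EH", "BB")


def logarithmic_length(n: int) -> float:
    """LG = lg4(n) = lg2(n) / 2."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return math.log2(n) / 2


def double_logarithmic_length(n: int) -> float:
    """2LG = lg2(n), the word length of maximal entropy in random genomes."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return math.log2(n)


@dataclass(frozen=True)
class BBParams:
    """Exponents and scale of the biobit function BB = scale * x^gamma (1-2x)^delta.

    ``scale=None`` means "use the genome's LG", keeping BB commensurate
    with logarithmic length.
    """

    gamma: float = 0.5
    delta: float = 3.0
    scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.delta <= 0:
            raise ValueError("gamma and delta must be positive")


class Components(NamedTuple):
    ec: float
    ac: float
    law_ok: bool  # True iff LG < E_2LG < 2LG


def components(e_2lg: float, n: int) -> Components:
    """Entropic / anti-entropic decomposition of LG.

    ``law_ok`` is False when E_2LG falls outside the open interval
    (LG, 2LG) — possible for perturbed or degenerate genomes — rather than
    raising, so law checks can report the violation.
    """
    lg = logarithmic_length(n)
    two_lg = 2 * lg
    ec = e_2lg - lg
    ac = two_lg - e_2lg
    return Components(ec, ac, lg < e_2lg < two_lg)


def _lx_ratio(genome: GenomeSequence, k: int):
    sp = kmer_spectrum(genome, k)
    return sp.occurrences / sp.distinct, sp


def lexical_index(genome: GenomeSequence, *, at_rounded_k: bool = False) -> float:
    """LX: possible 2LG-mer occurrences over distinct 2LG-mers.

    In a random genome every 2LG-mer is (essentially) a hapax, so LX = 1;
    repetitive structure raises it. For non-integer 2LG the ratio is
    interpolated between k1 and k2 with the same weight as the entropy
    interpolation, unless ``at_rounded_k`` requests evaluation at
    round(2LG).
    """
    n = genome.n
    k1, k2 = bracketing_k(n)
    if at_rounded_k:
        return _lx_ratio(genome, round(math.log2(n)))[0]
    r1 = _lx_ratio(genome, k1)[0]
    if k1 == k2:
        return r1
    r2 = _lx_ratio(genome, k2)[0]
    return r1 + (math.log2(n) - k1) * (r2 - r1)


def biobit(af: float, lg: float, params: BBParams = BBParams()) -> float:
    """Biobit value scale * af^gamma * (1 - 2 af)^delta.

    ``af >= 0.5`` yields a non-positive value (super-ordered genome); for
    non-integer delta the sign of (1 - 2 af) is carried onto the magnitude.
    """
    if af < 0:
        raise ValueError("anti-entropic fraction must be >= 0")
    scale = lg if params.scale is None else params.scale
    base = 1.0 - 2.0 * af
    signed_pow = math.copysign(abs(base) ** params.delta, base) if base != 0 else 0.0
    return scale * af ** params.gamma * signed_pow


def biobit_argmax(params: BBParams = BBParams()) -> float:
    """AF value maximizing x^gamma (1-2x)^delta on [0, 1/2]:
    gamma / (2 gamma + 2 delta)."""
    return params.gamma / (2 * params.gamma + 2 * params.delta)


@dataclass(frozen=True)
class InformationalIndexes:
    """The seven informational indexes of one genome, plus the integer-k
    diagnostics used by the law checks."""

    label: str
    n: int
    lg: float
    two_lg: float
    e_2lg: float
    ec: float
    ac: float
    lx: float
    af: float
    eh: float
    bb: float
    k1: int
    k2: int
    k_int: int          # round(2LG): integer word length for law L5
    e_k_int: float      # E_k at k_int
    lx_k_int: float     # W_k / |D_k| at k_int
    law_ok: bool        # LG < E_2LG < 2LG held during computation

    def to_dict(self) -> dict:
        return asdict(self)

    def table_row(self) -> dict:
        """Values in the canonical column order LG, EC, AC, LX, AF, EH, BB."""
        vals = (self.lg, self.ec, self.ac, self.lx, self.af, self.eh, self.bb)
        return dict(zip(TABLE_COLUMNS, vals))

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_tsv(self, precision: int = 4) -> str:
        head = "\t".join(TABLE_COLUMNS)
        row = "\t".join(f"{v:.{precision}f}" for v in self.table_row().values())
        return f"{head}\n{row}\n"


def compute_indexes(genome: GenomeSequence,
                    params: BBParams = BBParams(),
                    *, lx_at_rounded_k: bool = False) -> InformationalIndexes:
    """One-shot pipeline: spectra at k1, k2 -> E_2LG -> EC/AC -> LX -> AF,
    EH -> BB.

    Degenerate inputs (E_2LG outside the critical interval) set
    ``law_ok=False`` instead of raising, so perturbation scans can record
    law violations.
    """
    n = genome.n
    if n < 4:
        raise ValueError("genome too short for informational indexes")
    lg = logarithmic_length(n)
    two_lg = 2 * lg
    k1, k2 = bracketing_k(n)
    if k2 > genome.max_run_length:
        raise ValueError("double logarithmic length exceeds the longest run")

    r1, sp1 = _lx_ratio(genome, k1)
    e1 = empirical_entropy(sp1)
    if k1 == k2:
        e_2lg, lx = e1, r1
        e_int, lx_int, k_int = e1, r1, k1
    else:
        r2, sp2 = _lx_ratio(genome, k2)
        e2 = empirical_entropy(sp2)
        w = math.log2(n) - k1
        e_2lg = e1 + w * (e2 - e1)
        lx = r1 + w * (r2 - r1)
        k_int = k1 if w < 0.5 else k2
        e_int = e1 if k_int == k1 else e2
        lx_int = r1 if k_int == k1 else r2
    if lx_at_rounded_k:
        lx = lx_int
    ec, ac, law_ok = components(e_2lg, n)
    af = ac / lg
    eh = (ec - ac) / lg
    bb = biobit(max(af, 0.0), lg, params)
    return InformationalIndexes(
        label=genome.source_label, n=n, lg=lg, two_lg=two_lg, e_2lg=e_2lg,
        ec=ec, ac=ac, lx=lx, af=af, eh=eh, bb=bb,
        k1=k1, k2=k2, k_int=k_int, e_k_int=e_int, lx_k_int=lx_int,
        law_ok=law_ok,
    )
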