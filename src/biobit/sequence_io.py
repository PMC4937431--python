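"""Genome I/O and alphabet normalization.

A genome is modelled as an ordered list of *runs*: maximal stretches of
unambiguous nucleotides (lowercase ``a c g t``). Ambiguity codes (``n``,
IUPAC degeneracies, gaps) and FASTA record boundaries terminate runs, so
downstream k-mer extraction never produces words spanning unknown bases or
chromosome junctions. The effective length ``n`` counts only a/c/g/t.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = ["GenomeSequence", "FastaFormatError", "EmptyGenomeError", "read_fasta", "write_fasta"]

_VALID = frozenset("acgt")
_RUN_RE = re.compile(r"[acgt]+")


class FastaFormatError(ValueError):
    """Input is not a usable FASTA file (empty, or no records)."""


class EmptyGenomeError(ValueError):
    """Genome contains no unambiguous nucleotides."""


@dataclass(frozen=True)
class GenomeSequence:
    """Normalized nucleotide text partitioned into unambiguous runs.

    Parameters
    ----------
    runs
        Maximal segments over ``{a, c, g, t}``, in input order. k-mers are
        extracted within runs only.
    source_label
        Free-text identifier (file name, fixture spec, ...).
    """

    runs: tuple[str, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.runs:
            raise EmptyGenomeError("genome has no unambiguous nucleotides")
        object.__setattr__(self, "runs", tuple(self.runs))
        for r in self.runs:
            if not r:
                raise ValueError("empty run")
            if not _VALID.issuperset(r):
                bad = set(r) - _VALID
                raise ValueError(f"invalid symbols in run: {sorted(bad)!r}")

    @property
    def n(self) -> int:
        """Effective length: total count of a/c/g/t symbols."""
        return sum(len(r) for r in self.runs)

    @property
    def max_run_length(self) -> int:
        return max(len(r) for r in self.runs)

    @classmethod
    def from_text(cls, text: str, source_label: str = "") -> "GenomeSequence":
        """Build from raw sequence text; non-acgt symbols split runs."""
        runs = _RUN_RE.findall(text.lower())
        if not runs:
            raise EmptyGenomeError("no a/c/g/t symbols in input")
        return cls(tuple(runs), source_label)


def _runs_from_records(records: Iterable) -> list[str]:
    runs: list[str] = []
    seen = False
    for rec in records:
        seen = True
        runs.extend(_RUN_RE.findall(str(rec.seq).lower()))
    if not seen:
        raise FastaFormatError("no FASTA records found")
    return runs


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-record) FASTA file into a :class:`GenomeSequence`.

    Records are concatenated in file order. Symbols are lowercased; every
    maximal a/c/g/t stretch within a record becomes one run. Non-acgt
    symbols and record boundaries terminate runs and never contribute to
    the effective length.
    """
    path = Path(path)
    with open(path) as fh:
        runs = _runs_from_records(SeqIO.parse(fh, "fasta"))
    if not runs:
        raise EmptyGenomeError(f"{path}: zero unambiguous nucleotides")
    return GenomeSequence(tuple(runs), source_label=path.name)


def write_fasta(genome: GenomeSequence, path: str | Path, *,
                single_record: bool = False, width: int = 60) -> Path:
    """Write a genome as FASTA, one record per run (default).

    With ``single_record=True`` the runs are joined into one record with a
    single ``n`` separating consecutive runs, so a read-back recovers the
    same run structure.
    """
    path = Path(path)
    label = genome.source_label or "genome"
    with open(path, "w") as fh:
        if single_record:
            seq = "n".join(genome.runs)
            _write_record(fh, f"{label}", seq, width)
        else:
            for i, run in enumerate(genome.runs):
                _write_record(fh, f"{label}|run{i}", run, width)
    return path


def _write_record(fh, header: str, seq: str, width: int) -> None:
    fh.write(f">{header}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i:i + width] + "\n")
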