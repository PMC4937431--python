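"""Informational law verification and genome-perturbation scans.

The law set evaluated on a genome's indexes:

* L1 — LG < E_2LG < 2LG (the critical-interval inequality);
* L2 — EC > 0 and AC > 0 (the decomposition is strictly positive);
* L3 — EC > AC, equivalently AF < 1/2 and EH > 0 (needed for BB > 0);
* L4 — LX >= 1, with equality only in the random limit;
* L5 — lg2(LX_k) <= AC_k at the integer word length k = round(2LG),
  where AC_k = lg2(n) - E_k. This one is a theorem (E_k <= lg2|D_k| and
  W_k <= n), so a failure indicates a computation bug, not an odd genome.

Additional laws can be registered as predicates. Perturbation experiments
apply deletion / window-shuffle edits and re-check the laws on the edited
genome: removing or disordering parts of a genome can break laws that all
natural genomes satisfy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .indexes import BBParams, InformationalIndexes, compute_indexes
from .sequence_io import EmptyGenomeError, GenomeSequence

__all__ = [
    "LawResult",
    "LawReport",
    "Edit",
    "EditPlan",
    "LAWS",
    "verify_laws",
    "apply_edits",
    "law_survival_scan",
]

_EPS = 1e-9


@dataclass(frozen=True)
class LawResult:
    law: str
    passed: bool
    lhs: float
    rhs: float
    margin: float


@dataclass(frozen=True)
class LawReport:
    results: tuple[LawResult, ...]

    @property
    def overall(self) -> bool:
        return all(r.passed for r in self.results)

    def __getitem__(self, law: str) -> LawResult:
        for r in self.results:
            if r.law == law:
                return r
        raise KeyError(law)

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "laws": [r.__dict__ for r in self.results],
        }


# each predicate returns (passed, lhs, rhs, margin)
LawPredicate = Callable[[InformationalIndexes], tuple[bool, float, float, float]]


def _l1(ix):
    margin = min(ix.e_2lg - ix.lg, ix.two_lg - ix.e_2lg)
    return margin > 0, ix.lg, ix.two_lg, margin


def _l2(ix):
    margin = min(ix.ec, ix.ac)
    return ix.ec > 0 and ix.ac > 0, ix.ec, ix.ac, margin


def _l3(ix):
    return ix.ec > ix.ac, ix.ec, ix.ac, ix.ec - ix.ac


def _l4(ix):
    return ix.lx >= 1.0 - _EPS, ix.lx, 1.0, ix.lx - 1.0


def _l5(ix):
    lhs = math.log2(ix.lx_k_int)
    rhs = math.log2(ix.n) - ix.e_k_int
    return lhs <= rhs + _EPS, lhs, rhs, rhs - lhs


LAWS: Dict[str, LawPredicate] = {
    "L1": _l1, "L2": _l2, "L3": _l3, "L4": _l4, "L5": _l5,
}


def verify_laws(ix: InformationalIndexes,
                extra_laws: Optional[Dict[str, LawPredicate]] = None) -> LawReport:
    """Evaluate the law set on computed indexes; failures are data."""
    laws = dict(LAWS)
    if extra_laws:
        laws.update(extra_laws)
    results = []
    for name, pred in laws.items():
        passed, lhs, rhs, margin = pred(ix)
        results.append(LawResult(name, bool(passed), float(lhs),
                                 float(rhs), float(margin)))
    return LawReport(tuple(results))


# ---------------------------------------------------------------------------
# Perturbation operators


@dataclass(frozen=True)
class Edit:
    """One edit in effective (run-space) coordinates, 0-based half-open."""

    kind: str  # "delete" | "shuffle-window"
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.kind not in ("delete", "shuffle-window"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.start < 0 or self.length < 1:
            raise ValueError("edit must have start >= 0 and length >= 1")

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class EditPlan:
    plan_id: str
    edits: tuple[Edit, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        spans = sorted((e.start, e.stop) for e in self.edits)
        for (a, b), (c, _) in zip(spans, spans[1:]):
            if c < b:
                raise ValueError("edits overlap")

    @classmethod
    def from_dict(cls, d: dict) -> "EditPlan":
        edits = tuple(Edit(e["kind"], e["start"], e["length"])
                      for e in d.get("edits", ()))
        return cls(d.get("plan_id", "plan"), edits, d.get("seed", 0))


def apply_edits(genome: GenomeSequence, plan: EditPlan) -> GenomeSequence:
    """Apply a plan's edits; coordinates refer to the unedited genome.

    Deletions remove bases; shuffle-windows permute the bases inside the
    span with the plan's seed. Run boundaries persist (a span crossing a
    boundary edits both runs but never merges them); emptied runs drop out.
    """
    arrs = [np.frombuffer(r.encode("ascii"), dtype=np.uint8).copy()
            for r in genome.runs]
    offsets = np.cumsum([0] + [len(a) for a in arrs])
    n = int(offsets[-1])
    keep = [np.ones(len(a), dtype=bool) for a in arrs]

    def per_run_spans(e: Edit):
        # (run index, local slice) pieces of an effective-coordinate span
        for ri, a in enumerate(arrs):
            lo = max(e.start, int(offsets[ri])) - int(offsets[ri])
            hi = min(e.stop, int(offsets[ri + 1])) - int(offsets[ri])
            if hi > lo:
                yield ri, slice(lo, hi)

    rng = np.random.default_rng(plan.seed)
    for e in plan.edits:
        if e.stop > n:
            raise IndexError(f"edit {e} out of bounds (n={n})")
        if e.kind == "delete":
            for ri, sl in per_run_spans(e):
                keep[ri][sl] = False
        else:  # shuffle-window: permute bases across the span, runs kept
            pieces = list(per_run_spans(e))
            vals = np.concatenate([arrs[ri][sl] for ri, sl in pieces])
            vals = vals[rng.permutation(len(vals))]
            at = 0
            for ri, sl in pieces:
                ln = sl.stop - sl.start
                arrs[ri][sl] = vals[at:at + ln]
                at += ln

    runs = tuple(a[k].tobytes().decode("ascii")
                 for a, k in zip(arrs, keep) if k.any())
    if not runs:
        raise EmptyGenomeError("edits removed the whole genome")
    return GenomeSequence(runs, source_label=f"{genome.source_label}+{plan.plan_id}")


def law_survival_scan(genome: GenomeSequence, plans: Sequence[EditPlan],
                      params: BBParams = BBParams()) -> List[dict]:
    """Apply each plan, recompute indexes, re-verify the laws.

    Returns one row per plan: indexes plus per-law pass flags; a plan whose
    edited genome cannot be indexed is recorded with an ``error`` field and
    the scan continues.
    """
    rows: List[dict] = []
    for plan in plans:
        row: dict = {"plan_id": plan.plan_id}
        try:
            edited = apply_edits(genome, plan)
            ix = compute_indexes(edited, params)
            report = verify_laws(ix)
        except (ValueError, IndexError, EmptyGenomeError) as exc:
            row["error"] = str(exc)
            rows.append(row)
            continue
        row.update(n=ix.n, **{k: v for k, v in ix.table_row().items()})
        for r in report.results:
            row[r.law] = r.passed
        row["overall"] = report.overall
        rows.append(row)
    return rows
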