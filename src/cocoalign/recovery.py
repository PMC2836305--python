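"""Two-pass recovery of cross-species homologs for complex subunits.

Pass 1 is a plain BLAST screen at a stringent cutoff (default E <= 0.001).
Pass 2 revisits only the subunits pass 1 missed, at a relaxed cutoff
(default E <= 1) but gated by co-complex network alignment: a candidate is
accepted only when its BLAST pair falls in the ALIGNED context category.
Complexes are summarized by whether all, some, or none of their subunits
found a homolog. Subcomplexes (complexes strictly contained in another) are
removed beforehand to limit double counting; dropping supercomplexes
instead is available as a mode flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .model_io import BlastPair, ComplexSet, ContextCategory
from .network import PairContext

__all__ = [
    "RecoveryMethod",
    "ComplexStatus",
    "SubunitResult",
    "CompletenessSummary",
    "remove_subcomplexes",
    "pass1_blast",
    "pass2_context",
    "completeness",
    "recover_subunits",
]

PASS1_CUTOFF_DEFAULT = 1e-3
PASS2_CUTOFF_DEFAULT = 1.0


class RecoveryMethod(Enum):
    BLAST_PASS1 = "BLAST_PASS1"
    CONTEXT_PASS2 = "CONTEXT_PASS2"
    NOT_FOUND = "NOT_FOUND"


class ComplexStatus(Enum):
    ALL = "ALL"
    SOME = "SOME"
    NONE = "NONE"


@dataclass(frozen=True)
class SubunitResult:
    """Outcome of homolog search for one subunit across both passes."""

    subunit_id: str
    complexes: frozenset[str]
    method: RecoveryMethod
    homolog_id: Optional[str] = None
    evalue: Optional[float] = None
    confirmation: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.homolog_id is None) != (self.method is RecoveryMethod.NOT_FOUND):
            raise ValueError("homolog_id present iff a homolog was found")

    def as_record(self) -> dict[str, object]:
        return {
            "subunit_id": self.subunit_id,
            "method": self.method.name,
            "homolog_id": self.homolog_id,
            "evalue": self.evalue,
            "complexes": self.complexes,
            "confirmation": self.confirmation,
        }


@dataclass(frozen=True)
class CompletenessSummary:
    """How many complexes have homologs for all / some / none of their subunits."""

    n_complexes: int
    n_all: int
    n_some: int
    n_none: int
    pct_all: float
    pct_some: float
    pct_none: float

    def __post_init__(self) -> None:
        if self.n_all + self.n_some + self.n_none != self.n_complexes:
            raise ValueError("status counts must partition the complex count")


def remove_subcomplexes(
    complex_sets: Sequence[ComplexSet], mode: str = "sub"
) -> list[ComplexSet]:
    """Drop nested complexes: subcomplexes (default) or supercomplexes.

    A subcomplex is a complex whose member set is a strict subset of another
    complex's. Exact-duplicate member sets keep only the lexicographically
    smallest complex id. The operation is idempotent.
    """
    if mode not in ("sub", "super"):
        raise ValueError(f"mode must be 'sub' or 'super', got {mode!r}")
    # collapse exact duplicates first, keeping the smallest id
    by_members: dict[frozenset[str], ComplexSet] = {}
    for c in sorted(complex_sets, key=lambda c: c.complex_id):
        by_members.setdefault(c.members, c)
    unique = sorted(by_members.values(), key=lambda c: c.complex_id)
    kept: list[ComplexSet] = []
    for c in unique:
        nested = any(
            (c.members < other.members if mode == "sub" else c.members > other.members)
            for other in unique
            if other.complex_id != c.complex_id
        )
        if not nested:
            kept.append(c)
    return kept


def _best_subject(
    candidates: Sequence[BlastPair],
) -> Optional[BlastPair]:
    """Lowest E-value; ties by higher bitscore, then lexicographic subject."""
    if not candidates:
        return None
    return min(candidates, key=lambda p: (p.evalue, -p.bitscore, p.subject_id))


def pass1_blast(
    subunits: Sequence[str],
    pairs: Sequence[BlastPair],
    cutoff: float = PASS1_CUTOFF_DEFAULT,
) -> dict[str, Optional[BlastPair]]:
    """Best homolog per subunit at the stringent cutoff (E <= cutoff)."""
    by_query: dict[str, list[BlastPair]] = {}
    for p in pairs:
        if p.evalue <= cutoff:
            by_query.setdefault(p.query_id, []).append(p)
    return {s: _best_subject(by_query.get(s, ())) for s in subunits}


def pass2_context(
    unresolved_subunits: Sequence[str],
    pairs: Sequence[BlastPair],
    contexts: Mapping[tuple[str, str], ContextCategory],
    cutoff: float = PASS2_CUTOFF_DEFAULT,
) -> dict[str, Optional[BlastPair]]:
    """Best ALIGNED-context candidate per unresolved subunit (E <= cutoff)."""
    unresolved = set(unresolved_subunits)
    by_query: dict[str, list[BlastPair]] = {}
    for p in pairs:
        if (
            p.query_id in unresolved
            and p.evalue <= cutoff
            and contexts.get((p.query_id, p.subject_id)) is ContextCategory.ALIGNED
        ):
            by_query.setdefault(p.query_id, []).append(p)
    return {s: _best_subject(by_query.get(s, ())) for s in unresolved_subunits}


def completeness(
    complex_sets: Sequence[ComplexSet],
    homolog_map: Mapping[str, bool],
) -> tuple[CompletenessSummary, list[dict[str, object]]]:
    """Per-complex ALL/SOME/NONE status and the overall partition.

    ``homolog_map`` must cover every subunit of every complex; a subunit
    shared by several complexes carries one verdict into each of them.
    Percentages are rounded to two decimals.
    """
    counts = {ComplexStatus.ALL: 0, ComplexStatus.SOME: 0, ComplexStatus.NONE: 0}
    detail: list[dict[str, object]] = []
    for c in sorted(complex_sets, key=lambda c: c.complex_id):
        missing = [m for m in c.members if m not in homolog_map]
        if missing:
            raise ValueError(
                f"homolog_map does not cover subunit(s) {sorted(missing)[:3]} of {c.complex_id}"
            )
        n_found = sum(1 for m in c.members if homolog_map[m])
        if n_found == len(c.members):
            status = ComplexStatus.ALL
        elif n_found == 0:
            status = ComplexStatus.NONE
        else:
            status = ComplexStatus.SOME
        counts[status] += 1
        detail.append(
            {
                "complex_id": c.complex_id,
                "status": status.name,
                "n_subunits": len(c.members),
                "n_found": n_found,
            }
        )
    total = counts[ComplexStatus.ALL] + counts[ComplexStatus.SOME] + counts[ComplexStatus.NONE]
    pct = lambda k: round(100.0 * counts[k] / total, 2) if total else 0.0  # noqa: E731
    summary = CompletenessSummary(
        n_complexes=total,
        n_all=counts[ComplexStatus.ALL],
        n_some=counts[ComplexStatus.SOME],
        n_none=counts[ComplexStatus.NONE],
        pct_all=pct(ComplexStatus.ALL),
        pct_some=pct(ComplexStatus.SOME),
        pct_none=pct(ComplexStatus.NONE),
    )
    return summary, detail


def recover_subunits(
    complex_sets: Sequence[ComplexSet],
    pairs: Sequence[BlastPair],
    contexts: Mapping[tuple[str, str], ContextCategory],
    pass1_cutoff: float = PASS1_CUTOFF_DEFAULT,
    pass2_cutoff: float = PASS2_CUTOFF_DEFAULT,
) -> list[SubunitResult]:
    """Run both passes over every subunit of the given complexes.

    Subunits in several complexes are evaluated once; pass 2 never overrides
    pass 1, so the method labels partition the subunit universe.
    """
    complexes_of: dict[str, set[str]] = {}
    for c in complex_sets:
        for m in c.members:
            complexes_of.setdefault(m, set()).add(c.complex_id)
    subunits = sorted(complexes_of)
    p1 = pass1_blast(subunits, pairs, pass1_cutoff)
    unresolved = [s for s in subunits if p1[s] is None]
    p2 = pass2_context(unresolved, pairs, contexts, pass2_cutoff)
    results: list[SubunitResult] = []
    for s in subunits:
        hit = p1[s]
        if hit is not None:
            method = RecoveryMethod.BLAST_PASS1
        else:
            hit = p2.get(s)
            method = (
                RecoveryMethod.CONTEXT_PASS2 if hit is not None else RecoveryMethod.NOT_FOUND
            )
        results.append(
            SubunitResult(
                subunit_id=s,
                complexes=frozenset(complexes_of[s]),
                method=method,
                homolog_id=None if hit is None else hit.subject_id,
                evalue=None if hit is None else hit.evalue,
            )
        )
    return results
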