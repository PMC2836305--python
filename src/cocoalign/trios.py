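"""Evolutionary classification of (query, close hit, distant hit) trios.

When a contextually rescued distant homolog's query also has a clearly
significant hit in the subject species, three histories can explain the
close/distant pattern: a gene fusion / fission / domain-recombination event
(the two subject-species proteins are unrelated and match different regions
of the query), an ancient duplication predating the speciation (the two
subject proteins are paralogs and the distant one has its own significant
partner back in the query species), or a recent duplication followed by
asymmetric divergence (paralogs, but the fast-evolving copy has no
significant partner in the query species). A fourth UNRESOLVED bucket
catches trios fitting none of the tests. For ancient paralogs the fate of
the duplicate pair within the subject species' complexes is recorded, and
an over-representation test asks whether queries of ancient paralogs sit in
multiple complexes more often than background subunits.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .evaluation import overlap_fraction
from .model_io import BlastPair, ComplexSet, DomainHit

__all__ = [
    "Scenario",
    "Fate",
    "Trio",
    "TrioEvidence",
    "TrioRecord",
    "EnrichmentResult",
    "build_trios",
    "yeast_pair_homologous",
    "hsp_regions_disjoint",
    "classify_trio",
    "duplicate_fate",
    "multi_complex_enrichment",
]

CLOSE_CUTOFF_DEFAULT = 1e-3


class Scenario(Enum):
    FUSION_RECOMB = "FUSION_RECOMB"
    ANCIENT_PARALOG = "ANCIENT_PARALOG"
    ASYMMETRIC_DIVERGENCE = "ASYMMETRIC_DIVERGENCE"
    UNRESOLVED = "UNRESOLVED"


class Fate(Enum):
    SAME_COMPLEX = "SAME_COMPLEX"
    OVERLAPPING = "OVERLAPPING"
    DIFFERENT = "DIFFERENT"
    ONE_NOT_IN_COMPLEX = "ONE_NOT_IN_COMPLEX"
    NA = "NA"


@dataclass(frozen=True)
class Trio:
    """A query with its best close subject and a rescued distant subject."""

    query_id: str
    close: BlastPair
    distant: BlastPair


@dataclass(frozen=True)
class TrioEvidence:
    """The four per-trio test outcomes feeding the scenario decision."""

    yy_blast_hit: bool
    yy_shared_clan: bool
    regions_disjoint: bool
    back_hit: bool

    @property
    def homologous(self) -> bool:
        return self.yy_blast_hit or self.yy_shared_clan


@dataclass(frozen=True)
class TrioRecord:
    """A classified trio; fate is NA except for ancient paralogs."""

    query_id: str
    close_id: str
    distant_id: str
    scenario: Scenario
    fate: Fate
    evidence: TrioEvidence

    def __post_init__(self) -> None:
        if (self.fate is not Fate.NA) and self.scenario is not Scenario.ANCIENT_PARALOG:
            raise ValueError("fate applies only to ancient paralogs")

    def as_record(self) -> dict[str, object]:
        return {
            "query_id": self.query_id,
            "close_id": self.close_id,
            "distant_id": self.distant_id,
            "scenario": self.scenario.name,
            "fate": self.fate.name,
            "yy_blast_hit": self.evidence.yy_blast_hit,
            "yy_shared_clan": self.evidence.yy_shared_clan,
            "regions_disjoint": self.evidence.regions_disjoint,
            "back_hit": self.evidence.back_hit,
        }


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts and p-value of the multi-complex over-representation test."""

    k_multi_in_subset: int
    n_subset: int
    k_multi_in_background: int
    n_background: int
    p_value: float

    def __post_init__(self) -> None:
        if self.k_multi_in_subset > self.n_subset:
            raise ValueError("k > n in subset")
        if self.k_multi_in_background > self.n_background:
            raise ValueError("k > n in background")


def build_trios(
    recovered_pairs: Sequence[BlastPair],
    all_pairs: Sequence[BlastPair],
    close_cutoff: float = CLOSE_CUTOFF_DEFAULT,
) -> list[Trio]:
    """Pair every rescued distant hit with its query's best close hit.

    ``recovered_pairs`` are the contextually rescued gray-zone pairs; a trio
    is emitted whenever the query has a *different* subject at E <=
    ``close_cutoff`` among ``all_pairs``, taking the best such subject
    (lowest E, then higher bitscore, then lexicographic id).
    """
    close_by_query: dict[str, list[BlastPair]] = {}
    for p in all_pairs:
        if p.evalue <= close_cutoff:
            close_by_query.setdefault(p.query_id, []).append(p)
    trios: list[Trio] = []
    for rec in sorted(recovered_pairs, key=lambda p: (p.query_id, p.subject_id)):
        candidates = [
            p
            for p in close_by_query.get(rec.query_id, ())
            if p.subject_id != rec.subject_id
        ]
        if not candidates:
            continue
        best = min(candidates, key=lambda p: (p.evalue, -p.bitscore, p.subject_id))
        trios.append(Trio(rec.query_id, best, rec))
    return trios


def _clans_of(protein_id: str, domains: Mapping[str, Sequence[DomainHit]]) -> set[str]:
    return {
        d.clan_acc for d in domains.get(protein_id, ()) if d.clan_acc is not None
    }


def yeast_pair_homologous(
    close_id: str,
    distant_id: str,
    same_species_pairs: Sequence[BlastPair],
    domains: Mapping[str, Sequence[DomainHit]],
    cutoff: float = CLOSE_CUTOFF_DEFAULT,
) -> TrioEvidence:
    """Are the two subject-species hits themselves homologous?

    True when a significant within-species BLAST hit links them (either
    orientation, E <= cutoff) or when they share a non-null Pfam clan on any
    domain — no overlap condition applies here, domain content alone counts.
    Returns partial evidence (disjointness and back-hit left False).
    """
    yy_blast = any(
        p.evalue <= cutoff
        and {p.query_id, p.subject_id} == {close_id, distant_id}
        for p in same_species_pairs
    )
    yy_clan = bool(_clans_of(close_id, domains) & _clans_of(distant_id, domains))
    return TrioEvidence(yy_blast, yy_clan, regions_disjoint=False, back_hit=False)


def hsp_regions_disjoint(
    close_pair: BlastPair,
    distant_pair: BlastPair,
    min_overlap: float = 0.0,
) -> bool:
    """Do the two hits match different regions of the query protein?

    Compares the query-side intervals of the two best HSPs; disjoint means
    their overlap fraction (over the shorter interval) does not exceed
    ``min_overlap`` (default 0: literally non-overlapping).
    """
    frac = overlap_fraction(
        close_pair.best_hsp.query_interval, distant_pair.best_hsp.query_interval
    )
    return frac <= min_overlap


def duplicate_fate(
    close_id: str,
    distant_id: str,
    complex_sets: Sequence[ComplexSet],
) -> Fate:
    """Where did the two paralogous subunits end up?

    SAME_COMPLEX if some complex contains both; else OVERLAPPING if a
    complex of one shares more than half of the smaller complex's subunits
    with a complex of the other; else ONE_NOT_IN_COMPLEX if either protein
    belongs to no complex; else DIFFERENT.
    """
    of_close = [c for c in complex_sets if close_id in c.members]
    of_distant = [c for c in complex_sets if distant_id in c.members]
    if any(distant_id in c.members for c in of_close):
        return Fate.SAME_COMPLEX
    for c in of_close:
        for d in of_distant:
            shared = len(c.members & d.members)
            if shared > 0.5 * min(len(c.members), len(d.members)):
                return Fate.OVERLAPPING
    if not of_close or not of_distant:
        return Fate.ONE_NOT_IN_COMPLEX
    return Fate.DIFFERENT


def classify_trio(
    trio: Trio,
    same_species_pairs: Sequence[BlastPair],
    back_pairs: Sequence[BlastPair],
    domains: Mapping[str, Sequence[DomainHit]],
    complex_sets_b: Sequence[ComplexSet] = (),
    close_cutoff: float = CLOSE_CUTOFF_DEFAULT,
    min_overlap: float = 0.0,
    exclude_self_family: bool = False,
) -> TrioRecord:
    """Decide the evolutionary scenario of one trio.

    FUSION_RECOMB: the two subject proteins are not homologous and their
    best HSPs cover disjoint regions of the query. ANCIENT_PARALOG: they
    are homologous and the distant one has a significant hit (E <=
    ``close_cutoff``) back in the query species (any protein, unless
    ``exclude_self_family`` requires it to differ from the query itself).
    ASYMMETRIC_DIVERGENCE: homologous without such a back-hit. Anything
    else is UNRESOLVED. Duplicate fate is attached for ancient paralogs.
    """
    partial = yeast_pair_homologous(
        trio.close.subject_id, trio.distant.subject_id, same_species_pairs, domains,
        cutoff=close_cutoff,
    )
    disjoint = hsp_regions_disjoint(trio.close, trio.distant, min_overlap)
    back = any(
        p.query_id == trio.distant.subject_id
        and p.evalue <= close_cutoff
        and not (exclude_self_family and p.subject_id == trio.query_id)
        for p in back_pairs
    )
    evidence = TrioEvidence(
        partial.yy_blast_hit, partial.yy_shared_clan, disjoint, back
    )
    if not evidence.homologous and disjoint:
        scenario = Scenario.FUSION_RECOMB
    elif evidence.homologous and back:
        scenario = Scenario.ANCIENT_PARALOG
    elif evidence.homologous:
        scenario = Scenario.ASYMMETRIC_DIVERGENCE
    else:
        scenario = Scenario.UNRESOLVED
    fate = (
        duplicate_fate(trio.close.subject_id, trio.distant.subject_id, complex_sets_b)
        if scenario is Scenario.ANCIENT_PARALOG
        else Fate.NA
    )
    return TrioRecord(
        query_id=trio.query_id,
        close_id=trio.close.subject_id,
        distant_id=trio.distant.subject_id,
        scenario=scenario,
        fate=fate,
        evidence=evidence,
    )


def multi_complex_enrichment(
    subset_ids: Iterable[str],
    background_ids: Iterable[str],
    membership: Mapping[str, frozenset[str]],
    test: str = "hypergeom",
) -> EnrichmentResult:
    """Over-representation of multi-complex proteins in a subset.

    Counts proteins belonging to >= 2 complexes in the subset and in the
    background it was drawn from, then computes a one-sided hypergeometric
    upper-tail p-value (or a two-sided Fisher exact p with test="fisher").
    """
    subset = set(subset_ids)
    background = set(background_ids)
    if not subset:
        raise ValueError("subset is empty")
    if not subset <= background:
        raise ValueError("subset must be contained in the background")
    is_multi = lambda pid: len(membership.get(pid, frozenset())) >= 2  # noqa: E731
    k = sum(1 for pid in subset if is_multi(pid))
    K = sum(1 for pid in background if is_multi(pid))
    n, N = len(subset), len(background)
    if test == "hypergeom":
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    elif test == "fisher":
        table = [[k, n - k], [K - k, (N - n) - (K - k)]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown test {test!r}; choose 'hypergeom' or 'fisher'")
    return EnrichmentResult(k, n, K, N, min(p, 1.0))
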