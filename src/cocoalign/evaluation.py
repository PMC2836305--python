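"""Gold-standard labeling and per-bin positive predictive value.

BLAST hits are deduplicated to their best HSP, binned by E-value into eight
bins spanning [0, 100], and judged against Pfam clans: a pair whose HSP
overlaps (by more than half of the shorter region) a domain on each side,
with the two domains in the same clan, is a true positive. Pairs where the
clan standard cannot be applied on one side are ignored rather than counted
as false positives. The per-bin fraction of true positives (PPV) is then
tabulated separately for each nested context category, which is how the
enrichment of real homologs among contextually supported insignificant hits
becomes visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model_io import (
    EVAL_BINS,
    EVALUE_CEILING,
    BlastHSP,
    BlastPair,
    ContextCategory,
    DomainHit,
    EvalBin,
    HomologyLabel,
)

__all__ = [
    "BinStats",
    "dedup_best_hsp",
    "assign_bin",
    "overlap_fraction",
    "label_pair",
    "label_pairs",
    "ppv_table",
    "ppv_table_query_normalized",
    "applicability_counts",
    "CATEGORY_ORDER",
    "ALL_CATEGORY",
]

#: Pseudo-category covering every pair regardless of context.
ALL_CATEGORY = "ALL"

#: Reporting order for the PPV table: each named category is the *nested
#: subset* of pairs at that rank or deeper.
CATEGORY_ORDER: tuple[str, ...] = (
    ALL_CATEGORY,
    ContextCategory.IN_NETWORKS.name,
    ContextCategory.ORTHO_NEIGHBORS.name,
    ContextCategory.ALIGNED.name,
)

#: Minimum per-cell support below which a warning is attached (not a filter).
MIN_PAIRS_PER_BIN = 60
MIN_QUERIES_PER_BIN = 50


@dataclass(frozen=True)
class BinStats:
    """Counts and PPV for one (E-value bin, context category) cell.

    ``ppv`` is n_tp / (n_tp + n_fp) over evaluable pairs (None when there
    are none); ``tp_fraction_all`` additionally divides by ignored pairs,
    so both denominator conventions can be read off. ``low_support`` flags
    cells below the minimum pair/query support.
    """

    bin: EvalBin
    category: str
    n_pairs: int
    n_queries: int
    n_tp: int
    n_fp: int
    n_ignored: int
    ppv: Optional[float]
    tp_fraction_all: Optional[float]
    low_support: bool

    def __post_init__(self) -> None:
        if self.n_tp + self.n_fp + self.n_ignored != self.n_pairs:
            raise ValueError("label counts must partition n_pairs")
        if self.ppv is not None and not (0.0 <= self.ppv <= 1.0):
            raise ValueError("ppv out of [0, 1]")

    def as_record(self) -> dict[str, object]:
        return {
            "category": self.category,
            "bin": self.bin.index,
            "lower": self.bin.lower,
            "upper": self.bin.upper,
            "n_pairs": self.n_pairs,
            "n_queries": self.n_queries,
            "n_tp": self.n_tp,
            "n_fp": self.n_fp,
            "n_ignored": self.n_ignored,
            "ppv": self.ppv,
            "tp_fraction_all": self.tp_fraction_all,
            "low_support": self.low_support,
        }


def dedup_best_hsp(hsps: Sequence[BlastHSP]) -> list[BlastPair]:
    """Keep the best HSP per ordered (query, subject) pair.

    Best = lowest E-value, ties broken by higher bitscore, then by smaller
    query start. Output order is sorted by (query, subject) for determinism.
    """
    best: dict[tuple[str, str], BlastHSP] = {}
    for h in hsps:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bitscore, h.qstart) < (
            cur.evalue,
            -cur.bitscore,
            cur.qstart,
        ):
            best[key] = h
    return [
        BlastPair(q, s, best[(q, s)]) for q, s in sorted(best)
    ]


def assign_bin(evalue: float) -> EvalBin:
    """Map an E-value to its bin; values above the reporting ceiling error."""
    if evalue < 0:
        raise ValueError(f"negative E-value: {evalue}")
    if evalue > EVALUE_CEILING:
        raise ValueError(f"E-value {evalue} exceeds the reporting ceiling {EVALUE_CEILING}")
    for b in EVAL_BINS:
        if evalue <= b.upper:
            return b
    raise AssertionError("unreachable: bins cover [0, 100]")


def overlap_fraction(
    interval_1: tuple[int, int], interval_2: tuple[int, int]
) -> float:
    """Overlap of two 1-based inclusive intervals over the shorter one."""
    (a1, a2), (b1, b2) = interval_1, interval_2
    if a1 > a2 or b1 > b2:
        raise ValueError("intervals must satisfy start <= end")
    inter = min(a2, b2) - max(a1, b1) + 1
    if inter <= 0:
        return 0.0
    shorter = min(a2 - a1 + 1, b2 - b1 + 1)
    return inter / shorter


def _clans_overlapping(
    hsp_interval: tuple[int, int],
    domains: Sequence[DomainHit],
    accept_family: bool,
) -> set[str]:
    """Clan (or family) keys of domains covering >50% of the shorter region."""
    keys: set[str] = set()
    for d in domains:
        if overlap_fraction(hsp_interval, d.interval) > 0.5:
            if d.clan_acc is not None:
                keys.add(("clan", d.clan_acc))
            if accept_family:
                keys.add(("family", d.domain_acc))
    return keys


def _has_overlapping_domain(
    hsp_interval: tuple[int, int], domains: Sequence[DomainHit]
) -> bool:
    return any(overlap_fraction(hsp_interval, d.interval) > 0.5 for d in domains)


def label_pair(
    pair: BlastPair,
    domains_query: Sequence[DomainHit],
    domains_subject: Sequence[DomainHit],
    accept_same_family: bool = False,
) -> HomologyLabel:
    """Judge one pair against the Pfam-clan gold standard.

    TP when a domain on each side overlaps its HSP region by more than half
    of the shorter of the two (domain, HSP region) and the two domains share
    a clan; IGNORED when either side has no domain with such overlap (the
    standard cannot be applied there — this includes proteins with no
    annotated domain at all); FP otherwise. Clanless domains never match;
    ``accept_same_family`` additionally lets identical family accessions
    match.
    """
    hsp = pair.best_hsp
    q_ok = _has_overlapping_domain(hsp.query_interval, domains_query)
    s_ok = _has_overlapping_domain(hsp.subject_interval, domains_subject)
    if not q_ok or not s_ok:
        return HomologyLabel.IGNORED
    q_keys = _clans_overlapping(hsp.query_interval, domains_query, accept_same_family)
    s_keys = _clans_overlapping(hsp.subject_interval, domains_subject, accept_same_family)
    return HomologyLabel.TP if q_keys & s_keys else HomologyLabel.FP


def label_pairs(
    pairs: Sequence[BlastPair],
    domains: Sequence[DomainHit],
    accept_same_family: bool = False,
) -> dict[tuple[str, str], HomologyLabel]:
    """Label every pair using a shared domain table (both species)."""
    by_protein: dict[str, list[DomainHit]] = {}
    for d in domains:
        by_protein.setdefault(d.protein_id, []).append(d)
    return {
        (p.query_id, p.subject_id): label_pair(
            p,
            by_protein.get(p.query_id, ()),
            by_protein.get(p.subject_id, ()),
            accept_same_family,
        )
        for p in pairs
    }


def _category_members(category: str) -> set[str]:
    """Context category names included in a (nested) reporting category."""
    if category == ALL_CATEGORY:
        return {c.name for c in ContextCategory}
    rank = ContextCategory[category].rank
    return {c.name for c in ContextCategory if c.rank >= rank}


def _cells(
    pairs: Sequence[BlastPair],
    contexts: Mapping[tuple[str, str], ContextCategory],
    categories: Sequence[str] = CATEGORY_ORDER,
) -> dict[tuple[str, int], list[BlastPair]]:
    cells: dict[tuple[str, int], list[BlastPair]] = {
        (cat, b.index): [] for cat in categories for b in EVAL_BINS
    }
    for p in pairs:
        b = assign_bin(p.evalue)
        cname = contexts[(p.query_id, p.subject_id)].name
        for cat in categories:
            if cname in _category_members(cat):
                cells[(cat, b.index)].append(p)
    return cells


def _warn_low_support(stat: BinStats) -> None:
    if stat.low_support and stat.n_pairs > 0:
        warnings.warn(
            f"bin {stat.bin.index} ({stat.category}): only {stat.n_pairs} pairs /"
            f" {stat.n_queries} queries (minimum {MIN_PAIRS_PER_BIN}/{MIN_QUERIES_PER_BIN})",
            stacklevel=3,
        )


def ppv_table(
    pairs: Sequence[BlastPair],
    contexts: Mapping[tuple[str, str], ContextCategory],
    labels: Mapping[tuple[str, str], HomologyLabel],
) -> list[BinStats]:
    """Per-bin, per-category counts and PPV (unweighted).

    Categories are the nested subsets ALL ⊇ IN_NETWORKS ⊇ ORTHO_NEIGHBORS ⊇
    ALIGNED. Ignored pairs count toward n_pairs/n_ignored but not toward the
    PPV ratio. Cells under the minimum support are flagged with a warning.
    """
    stats: list[BinStats] = []
    cells = _cells(pairs, contexts)
    for cat in CATEGORY_ORDER:
        for b in EVAL_BINS:
            cell = cells[(cat, b.index)]
            n_tp = sum(
                1 for p in cell if labels[(p.query_id, p.subject_id)] is HomologyLabel.TP
            )
            n_fp = sum(
                1 for p in cell if labels[(p.query_id, p.subject_id)] is HomologyLabel.FP
            )
            n_ignored = len(cell) - n_tp - n_fp
            n_queries = len({p.query_id for p in cell})
            evaluable = n_tp + n_fp
            stat = BinStats(
                bin=b,
                category=cat,
                n_pairs=len(cell),
                n_queries=n_queries,
                n_tp=n_tp,
                n_fp=n_fp,
                n_ignored=n_ignored,
                ppv=(n_tp / evaluable) if evaluable else None,
                tp_fraction_all=(n_tp / len(cell)) if cell else None,
                low_support=len(cell) < MIN_PAIRS_PER_BIN
                or n_queries < MIN_QUERIES_PER_BIN,
            )
            _warn_low_support(stat)
            stats.append(stat)
    return stats


def ppv_table_query_normalized(
    pairs: Sequence[BlastPair],
    contexts: Mapping[tuple[str, str], ContextCategory],
    labels: Mapping[tuple[str, str], HomologyLabel],
) -> list[BinStats]:
    """PPV normalized for family size: one vote per query protein.

    Within each cell, every query contributes total weight 1 split equally
    over its evaluable (non-ignored) pairs; the PPV is the TP weight share.
    Counts are reported unweighted, as in :func:`ppv_table`.
    """
    stats: list[BinStats] = []
    cells = _cells(pairs, contexts)
    for cat in CATEGORY_ORDER:
        for b in EVAL_BINS:
            cell = cells[(cat, b.index)]
            by_query: dict[str, list[BlastPair]] = {}
            n_tp = n_fp = 0
            for p in cell:
                lab = labels[(p.query_id, p.subject_id)]
                if lab is HomologyLabel.IGNORED:
                    continue
                by_query.setdefault(p.query_id, []).append(p)
                if lab is HomologyLabel.TP:
                    n_tp += 1
                else:
                    n_fp += 1
            w_tp = w_all = 0.0
            for q, qpairs in by_query.items():
                w = 1.0 / len(qpairs)
                for p in qpairs:
                    w_all += w
                    if labels[(p.query_id, p.subject_id)] is HomologyLabel.TP:
                        w_tp += w
            n_queries = len({p.query_id for p in cell})
            stat = BinStats(
                bin=b,
                category=cat,
                n_pairs=len(cell),
                n_queries=n_queries,
                n_tp=n_tp,
                n_fp=n_fp,
                n_ignored=len(cell) - n_tp - n_fp,
                ppv=(w_tp / w_all) if w_all else None,
                tp_fraction_all=(n_tp / len(cell)) if cell else None,
                low_support=len(cell) < MIN_PAIRS_PER_BIN
                or n_queries < MIN_QUERIES_PER_BIN,
            )
            _warn_low_support(stat)
            stats.append(stat)
    return stats


def applicability_counts(
    pairs: Sequence[BlastPair],
    contexts: Mapping[tuple[str, str], ContextCategory],
) -> list[dict[str, int]]:
    """Per-bin applicability: all pairs/queries vs aligned pairs/queries."""
    rows: list[dict[str, int]] = []
    cells = _cells(pairs, contexts, (ALL_CATEGORY, ContextCategory.ALIGNED.name))
    for b in EVAL_BINS:
        allc = cells[(ALL_CATEGORY, b.index)]
        alc = cells[(ContextCategory.ALIGNED.name, b.index)]
        rows.append(
            {
                "bin": b.index,
                "n_pairs_all": len(allc),
                "n_queries_all": len({p.query_id for p in allc}),
                "n_pairs_aligned": len(alc),
                "n_queries_aligned": len({p.query_id for p in alc}),
            }
        )
    return rows
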