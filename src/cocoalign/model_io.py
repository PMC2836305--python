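"""Domain types and tabular readers/writers.

The pipeline consumes five kinds of tabular input: cross-species BLAST hits
(tabular, outfmt-6-like), within-species complex membership tables, a
cross-species ortholog cluster table (Inparanoid-style), per-protein Pfam
domain/clan annotations, and optionally a FASTA file for protein lengths.
All coordinates are 1-based inclusive amino-acid positions, the convention
of both BLAST tabular output and HMMer domain tables; nothing converts them.

Species are opaque role tags ("A"/"B" by default) fixed per run; no code
path is specific to a particular organism pair.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO

__all__ = [
    "BIN_EDGES",
    "EVALUE_CEILING",
    "Protein",
    "BlastHSP",
    "BlastPair",
    "DomainHit",
    "ComplexSet",
    "OrthologClusterSet",
    "ContextCategory",
    "HomologyLabel",
    "EvalBin",
    "EVAL_BINS",
    "read_blast_table",
    "read_complexes",
    "read_ortholog_clusters",
    "read_domains",
    "read_fasta_lengths",
    "write_report",
    "read_report",
    "REPORT_KINDS",
]

#: Upper edges of the eight E-value bins; bin 1 is [0, 1e-5], bins 2..8 are
#: half-open intervals (lower, upper].
BIN_EDGES: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)

#: Maximum E-value the upstream search reports; larger values are rejected.
EVALUE_CEILING: float = 100.0


class ContextCategory(Enum):
    """Nested functional-context classes for a cross-species BLAST pair.

    ALIGNED < ORTHO_NEIGHBORS < IN_NETWORKS < NONE in specificity: a pair is
    IN_NETWORKS when both proteins have at least one co-complex partner,
    ORTHO_NEIGHBORS when additionally each has a partner with a clear
    cross-species ortholog, and ALIGNED when some partner of the query and
    some partner of the subject sit in the *same* ortholog cluster.
    """

    NONE = 0
    IN_NETWORKS = 1
    ORTHO_NEIGHBORS = 2
    ALIGNED = 3

    @property
    def rank(self) -> int:
        return self.value


class HomologyLabel(Enum):
    """Gold-standard verdict for a BLAST pair based on shared Pfam clans."""

    TP = "TP"
    FP = "FP"
    IGNORED = "IGNORED"


@dataclass(frozen=True)
class Protein:
    """A protein identified by id within one species; length in amino acids."""

    id: str
    species: str
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length is not None and self.length < 1:
            raise ValueError(f"protein {self.id}: length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class BlastHSP:
    """One high-scoring segment pair with coordinates on both sequences."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    qstart: int
    qend: int
    sstart: int
    send: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}/{self.subject_id}: negative E-value")
        if self.qstart > self.qend:
            raise ValueError(f"{self.query_id}/{self.subject_id}: qstart > qend")
        if self.sstart > self.send:
            raise ValueError(f"{self.query_id}/{self.subject_id}: sstart > send")
        if self.qstart < 1 or self.sstart < 1:
            raise ValueError(f"{self.query_id}/{self.subject_id}: coordinates are 1-based")

    @property
    def query_interval(self) -> tuple[int, int]:
        return (self.qstart, self.qend)

    @property
    def subject_interval(self) -> tuple[int, int]:
        return (self.sstart, self.send)


@dataclass(frozen=True)
class BlastPair:
    """A deduplicated query-subject pair represented by its best HSP."""

    query_id: str
    subject_id: str
    best_hsp: BlastHSP

    @property
    def evalue(self) -> float:
        return self.best_hsp.evalue

    @property
    def bitscore(self) -> float:
        return self.best_hsp.bitscore


@dataclass(frozen=True)
class DomainHit:
    """A Pfam domain match on a protein; clan_acc is None for clanless families."""

    protein_id: str
    domain_acc: str
    clan_acc: Optional[str]
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain {self.domain_acc} on {self.protein_id}: start > end")
        if self.start < 1:
            raise ValueError(f"domain {self.domain_acc} on {self.protein_id}: 1-based coordinates")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ComplexSet:
    """A named complex: a nonempty set of member protein ids in one species."""

    complex_id: str
    members: frozenset[str]
    species: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"complex {self.complex_id} has no members")


class OrthologClusterSet:
    """Cross-species ortholog clusters with a protein -> cluster index.

    Each cluster has at least one member in each species, and a protein
    belongs to at most one cluster (enforced at construction).
    """

    def __init__(self, clusters: Mapping[str, tuple[Iterable[str], Iterable[str]]]):
        self._clusters: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
        self._index: dict[str, str] = {}
        for cid in sorted(clusters):
            a, b = clusters[cid]
            fa, fb = frozenset(a), frozenset(b)
            if not fa or not fb:
                raise ValueError(f"cluster {cid} lacks members in one species")
            self._clusters[cid] = (fa, fb)
            for pid in fa | fb:
                if pid in self._index:
                    raise ValueError(
                        f"protein {pid} appears in clusters {self._index[pid]} and {cid}"
                    )
                self._index[pid] = cid

    def cluster_of(self, protein_id: str) -> Optional[str]:
        return self._index.get(protein_id)

    def members(self, cluster_id: str) -> tuple[frozenset[str], frozenset[str]]:
        return self._clusters[cluster_id]

    def all_members(self, cluster_id: str) -> frozenset[str]:
        a, b = self._clusters[cluster_id]
        return a | b

    @property
    def cluster_ids(self) -> list[str]:
        return list(self._clusters)

    def __len__(self) -> int:
        return len(self._clusters)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologClusterSet):
            return NotImplemented
        return self._clusters == other._clusters


@dataclass(frozen=True)
class EvalBin:
    """One of the eight E-value bins; (lower, upper] except bin 1 = [0, upper]."""

    index: int
    lower: float
    upper: float

    def __contains__(self, evalue: float) -> bool:
        if self.index == 1:
            return 0.0 <= evalue <= self.upper
        return self.lower < evalue <= self.upper


EVAL_BINS: tuple[EvalBin, ...] = tuple(
    EvalBin(i + 1, 0.0 if i == 0 else BIN_EDGES[i - 1], BIN_EDGES[i])
    for i in range(len(BIN_EDGES))
)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _data_lines(path: Union[str, Path]) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping blanks and '#'."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_error(path: Union[str, Path], lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


BLAST_DIALECTS = ("blast12", "minimal")


def read_blast_table(path: Union[str, Path], dialect: str = "blast12") -> list[BlastHSP]:
    """Read a tabular BLAST file into HSP records.

    Dialects: "blast12" is the standard 12-column tabular output
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore); "minimal" is a 7-column fixture format
    (query subject evalue qstart qend sstart send) with bitscore set to 0.
    """
    if dialect not in BLAST_DIALECTS:
        raise ValueError(f"unknown BLAST dialect {dialect!r}; choose from {BLAST_DIALECTS}")
    hsps: list[BlastHSP] = []
    for lineno, fields in _data_lines(path):
        try:
            if dialect == "blast12":
                if len(fields) < 12:
                    raise ValueError(f"expected 12 columns, got {len(fields)}")
                q, s = fields[0], fields[1]
                qstart, qend, sstart, send = (int(x) for x in fields[6:10])
                evalue, bitscore = float(fields[10]), float(fields[11])
            else:
                if len(fields) != 7:
                    raise ValueError(f"expected 7 columns, got {len(fields)}")
                q, s = fields[0], fields[1]
                evalue = float(fields[2])
                qstart, qend, sstart, send = (int(x) for x in fields[3:7])
                bitscore = 0.0
            hsps.append(
                BlastHSP(q, s, evalue, bitscore, qstart, qend, sstart, send)
            )
        except ValueError as exc:
            raise _parse_error(path, lineno, str(exc)) from None
    return hsps


def read_complexes(path: Union[str, Path], species: str) -> list[ComplexSet]:
    """Read a complex membership table.

    Accepts either one (complex_id, member) row per membership or one row
    per complex with the id followed by its members; duplicate memberships
    collapse under set semantics. Rows for the same complex id accumulate.
    """
    members: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise _parse_error(path, lineno, "complex row with zero members")
        cid = fields[0]
        row_members = [m for m in fields[1:] if m]
        if not row_members:
            raise _parse_error(path, lineno, f"complex {cid} row with zero members")
        members.setdefault(cid, set()).update(row_members)
    return [ComplexSet(cid, frozenset(members[cid]), species) for cid in sorted(members)]


def read_ortholog_clusters(
    path: Union[str, Path], species_a: str, species_b: str
) -> OrthologClusterSet:
    """Read a (cluster_id, species, protein_id) table into clusters.

    Clusters with members in only one species cannot align two networks and
    are dropped with a warning; a protein in two clusters is an error.
    """
    raw: dict[str, tuple[set[str], set[str]]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise _parse_error(path, lineno, f"expected 3 columns, got {len(fields)}")
        cid, sp, pid = fields
        if sp not in (species_a, species_b):
            raise _parse_error(path, lineno, f"unknown species tag {sp!r}")
        a, b = raw.setdefault(cid, (set(), set()))
        (a if sp == species_a else b).add(pid)
    usable: dict[str, tuple[set[str], set[str]]] = {}
    for cid in sorted(raw):
        a, b = raw[cid]
        if not a or not b:
            warnings.warn(
                f"cluster {cid} has members in only one species and was dropped",
                stacklevel=2,
            )
            continue
        usable[cid] = (a, b)
    return OrthologClusterSet(usable)


def read_domains(path: Union[str, Path]) -> list[DomainHit]:
    """Read a (protein, domain_acc, clan_acc-or-empty, start, end) table."""
    hits: list[DomainHit] = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 5:
            raise _parse_error(path, lineno, f"expected 5 columns, got {len(fields)}")
        pid, dom, clan, start, end = fields
        try:
            hits.append(DomainHit(pid, dom, clan or None, int(start), int(end)))
        except ValueError as exc:
            raise _parse_error(path, lineno, str(exc)) from None
    return hits


def read_fasta_lengths(path: Union[str, Path]) -> dict[str, int]:
    """Extract sequence lengths from a FASTA file (first token of header = id)."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# report writing / reading
# ---------------------------------------------------------------------------

def _opt_float(x: str) -> Optional[float]:
    return float(x) if x != "" else None


def _opt_str(x: str) -> Optional[str]:
    return x if x != "" else None


def _bool(x: str) -> bool:
    return bool(int(x))


def _idset(x: str) -> frozenset[str]:
    return frozenset(x.split(",")) if x else frozenset()


#: kind -> (ordered columns with reader converters, sort-key columns)
REPORT_KINDS: dict[str, tuple[dict[str, object], tuple[str, ...]]] = {
    "pairs": (
        {
            "query_id": str,
            "subject_id": str,
            "evalue": float,
            "category": str,
            "witness_a": _opt_str,
            "witness_b": _opt_str,
            "witness_cluster": _opt_str,
        },
        ("query_id", "subject_id"),
    ),
    "bins": (
        {
            "category": str,
            "bin": int,
            "lower": float,
            "upper": float,
            "n_pairs": int,
            "n_queries": int,
            "n_tp": int,
            "n_fp": int,
            "n_ignored": int,
            "ppv": _opt_float,
            "tp_fraction_all": _opt_float,
            "low_support": _bool,
        },
        ("category", "bin"),
    ),
    "subunits": (
        {
            "subunit_id": str,
            "method": str,
            "homolog_id": _opt_str,
            "evalue": _opt_float,
            "complexes": _idset,
            "confirmation": _opt_str,
        },
        ("subunit_id",),
    ),
    "complexes": (
        {
            "complex_id": str,
            "status": str,
            "n_subunits": int,
            "n_found": int,
        },
        ("complex_id",),
    ),
    "trios": (
        {
            "query_id": str,
            "close_id": str,
            "distant_id": str,
            "scenario": str,
            "fate": str,
            "yy_blast_hit": _bool,
            "yy_shared_clan": _bool,
            "regions_disjoint": _bool,
            "back_hit": _bool,
        },
        ("query_id", "distant_id"),
    ),
}


def _serialize(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, (frozenset, set)):
        return ",".join(sorted(value))
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, Enum):
        return str(value.name)
    return str(value)


def write_report(
    records: Sequence[Mapping[str, object]],
    path: Union[str, Path],
    kind: str,
    meta: Optional[Sequence[str]] = None,
) -> None:
    """Write records of one report kind as a sorted, headered TSV.

    Output is deterministic: fixed column order, stable sort on the kind's
    primary key, and round-trippable value formatting ('' encodes None,
    floats use shortest round-trip repr). ``meta`` lines are emitted as
    '#'-prefixed comments above the header.
    """
    if kind not in REPORT_KINDS:
        raise ValueError(f"unknown report kind {kind!r}; choose from {sorted(REPORT_KINDS)}")
    columns, key = REPORT_KINDS[kind]
    ordered = sorted(records, key=lambda r: tuple(_serialize(r[k]) for k in key))
    with open(path, "w") as fh:
        for line in meta or ():
            fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        for rec in ordered:
            fh.write("\t".join(_serialize(rec[c]) for c in columns) + "\n")


def read_report(path: Union[str, Path], kind: str) -> list[dict[str, object]]:
    """Read back a report written by :func:`write_report`."""
    if kind not in REPORT_KINDS:
        raise ValueError(f"unknown report kind {kind!r}; choose from {sorted(REPORT_KINDS)}")
    columns, _ = REPORT_KINDS[kind]
    records: list[dict[str, object]] = []
    header: Optional[list[str]] = None
    for lineno, fields in _data_lines(path):
        if header is None:
            header = fields
            if header != list(columns):
                raise _parse_error(path, lineno, f"unexpected header for kind {kind!r}")
            continue
        if len(fields) != len(columns):
            raise _parse_error(path, lineno, f"expected {len(columns)} columns")
        records.append(
            {col: conv(val) for (col, conv), val in zip(columns.items(), fields)}
        )
    return records


def file_md5(path: Union[str, Path]) -> str:
    """Hex MD5 of a file, for report provenance headers."""
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
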