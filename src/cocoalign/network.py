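"""Co-complex networks and context classification of cross-species BLAST pairs.

A co-complex network joins two proteins whenever they are annotated as
subunits of the same complex (every unordered member pair of every complex,
optionally augmented with externally supplied binary co-complex pairs).
Aligning the networks of two species through ortholog clusters lets a BLAST
pair inherit circumstantial evidence of homology from its neighborhood: if
the query sits next to a protein whose clear ortholog sits next to the
subject, the two proteins are subunits of homologous complexes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .model_io import (
    BlastHSP,
    BlastPair,
    ComplexSet,
    ContextCategory,
    OrthologClusterSet,
)

__all__ = [
    "CoComplexNetwork",
    "PairContext",
    "build_network",
    "classify_pair",
    "seed_ortholog_pairs",
]


@dataclass
class CoComplexNetwork:
    """Per-species undirected co-complex graph with complex membership."""

    species: str
    graph: nx.Graph
    membership: dict[str, frozenset[str]]

    def neighbors(self, protein_id: str) -> set[str]:
        """Co-complex partners of a protein; empty set if absent."""
        if protein_id not in self.graph:
            return set()
        return set(self.graph.neighbors(protein_id))

    def has_edge_partner(self, protein_id: str) -> bool:
        return protein_id in self.graph and self.graph.degree(protein_id) > 0

    def complexes_of(self, protein_id: str) -> frozenset[str]:
        return self.membership.get(protein_id, frozenset())

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class PairContext:
    """Context category of one BLAST pair, with an ALIGNED witness triple.

    The witness is the lexicographically smallest (neighbor of query,
    neighbor of subject, cluster id) triple proving alignment; it is present
    exactly when the category is ALIGNED.
    """

    query_id: str
    subject_id: str
    category: ContextCategory
    witness: Optional[tuple[str, str, str]] = None

    def __post_init__(self) -> None:
        if (self.witness is not None) != (self.category is ContextCategory.ALIGNED):
            raise ValueError("witness must be present iff category is ALIGNED")


def build_network(
    complex_sets: Sequence[ComplexSet],
    extra_pairs: Iterable[tuple[str, str]] = (),
    species: Optional[str] = None,
    species_of: Optional[Mapping[str, str]] = None,
) -> CoComplexNetwork:
    """Expand complexes into a union of unordered co-complex pairs.

    ``extra_pairs`` supplies standalone binary co-complex relations (e.g.
    "direct complex" pairs) merged into the same edge set; self-pairs are
    discarded. Singleton complexes contribute membership but no edges. When
    ``species_of`` is given, extra pairs spanning two species are rejected.
    """
    tags = {c.species for c in complex_sets}
    if len(tags) > 1:
        raise ValueError(f"complexes from multiple species: {sorted(tags)}")
    if species is None:
        if not tags:
            raise ValueError("species tag required when no complexes are given")
        species = next(iter(tags))
    elif tags and tags != {species}:
        raise ValueError(f"complex species {tags} do not match {species!r}")

    graph = nx.Graph()
    membership: dict[str, set[str]] = {}
    for cset in complex_sets:
        for pid in cset.members:
            membership.setdefault(pid, set()).add(cset.complex_id)
            graph.add_node(pid)
        for u, v in itertools.combinations(sorted(cset.members), 2):
            graph.add_edge(u, v)
    for u, v in extra_pairs:
        if u == v:
            continue
        if species_of is not None:
            su, sv = species_of.get(u), species_of.get(v)
            if su is not None and sv is not None and su != sv:
                raise ValueError(f"extra pair ({u}, {v}) spans two species")
        graph.add_edge(u, v)
    return CoComplexNetwork(
        species=species,
        graph=graph,
        membership={p: frozenset(cs) for p, cs in membership.items()},
    )


def classify_pair(
    pair: BlastPair,
    network_a: CoComplexNetwork,
    network_b: CoComplexNetwork,
    clusters: OrthologClusterSet,
    exclude_subject_cluster: bool = False,
) -> PairContext:
    """Assign one BLAST pair to its nested functional-context category.

    IN_NETWORKS requires both proteins to have at least one co-complex
    partner; ORTHO_NEIGHBORS additionally requires each to have a partner
    belonging to some cross-species ortholog cluster; ALIGNED requires a
    partner of the query and a partner of the subject in the *same* cluster.
    With ``exclude_subject_cluster`` a witness whose query-side neighbor is
    clustered with the subject itself is not accepted.
    """
    q, s = pair.query_id, pair.subject_id
    if not network_a.has_edge_partner(q) or not network_b.has_edge_partner(s):
        return PairContext(q, s, ContextCategory.NONE)
    neigh_a = network_a.neighbors(q)
    neigh_b = network_b.neighbors(s)
    clustered_a = sorted(n for n in neigh_a if n in clusters)
    clustered_b = sorted(n for n in neigh_b if n in clusters)
    if not clustered_a or not clustered_b:
        return PairContext(q, s, ContextCategory.IN_NETWORKS)
    cluster_by_b: dict[str, list[str]] = {}
    for nb in clustered_b:
        cluster_by_b.setdefault(clusters.cluster_of(nb), []).append(nb)
    for na in clustered_a:  # ascending: first match minimizes the triple
        cid = clusters.cluster_of(na)
        if exclude_subject_cluster and s in clusters.all_members(cid):
            continue
        partners = cluster_by_b.get(cid)
        if partners:
            return PairContext(q, s, ContextCategory.ALIGNED, (na, partners[0], cid))
    return PairContext(q, s, ContextCategory.ORTHO_NEIGHBORS)


def _best_hits(pairs: Sequence[BlastPair]) -> dict[str, BlastPair]:
    """Best subject per query: highest bitscore, then lower E, then lex id."""
    best: dict[str, BlastPair] = {}
    for p in pairs:
        cur = best.get(p.query_id)
        if cur is None or (
            (-p.bitscore, p.evalue, p.subject_id)
            < (-cur.bitscore, cur.evalue, cur.subject_id)
        ):
            best[p.query_id] = p
    return best


def seed_ortholog_pairs(
    blast_ab: Sequence[BlastPair],
    blast_ba: Sequence[BlastPair],
    lengths: Mapping[str, int],
    min_bitscore: float = 50.0,
    min_overlap: float = 0.5,
) -> OrthologClusterSet:
    """Bidirectional-best-hit ortholog seeding, Inparanoid's seed criterion.

    A reciprocal best pair becomes a singleton-singleton cluster when both
    directional hits reach ``min_bitscore`` and their query-side aligned
    length covers at least ``min_overlap`` of the shorter protein. This is a
    convenience substitute for a full Inparanoid run: seed pairs only, no
    inparalog expansion or bootstrap confidence.
    """
    import warnings

    best_ab = _best_hits(blast_ab)
    best_ba = _best_hits(blast_ba)
    clusters: dict[str, tuple[frozenset[str], frozenset[str]]] = {}
    n = 0
    for a in sorted(best_ab):
        fwd = best_ab[a]
        b = fwd.subject_id
        rev = best_ba.get(b)
        if rev is None or rev.subject_id != a:
            continue
        if fwd.bitscore < min_bitscore or rev.bitscore < min_bitscore:
            continue
        if a not in lengths or b not in lengths:
            warnings.warn(f"no length for {a} or {b}; seed pair skipped", stacklevel=2)
            continue
        shorter = min(lengths[a], lengths[b])
        fwd_cov = (fwd.best_hsp.qend - fwd.best_hsp.qstart + 1) / shorter
        rev_cov = (rev.best_hsp.qend - rev.best_hsp.qstart + 1) / shorter
        if fwd_cov < min_overlap or rev_cov < min_overlap:
            continue
        clusters[f"seed{n:05d}"] = (frozenset({a}), frozenset({b}))
        n += 1
    return OrthologClusterSet(clusters)
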