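"""Synthetic input bundles with known ground-truth homology.

The generator emits every table the pipeline consumes — proteomes with
lengths, complex memberships, ortholog clusters, domain annotations and
BLAST-like hit tables in three directions — for a world of protein families
whose divergence history is known. E-values are drawn parametrically per
divergence class (log10 E normal, clipped to the class range) rather than
simulated from alignments: the claims under test concern E-value strata and
functional context, not alignment mechanics, so a desk-scale parametric
model suffices.

Three family histories produce trio material: an ancient duplication before
the speciation (two ortholog pairs, cross pairs distant), a recent
duplication in species B with asymmetric divergence (one conserved copy,
one fast copy with no significant partner in species A), and a fusion in
species A (two unrelated species-B proteins matching disjoint regions of
one species-A protein). Remaining families are single ortholog pairs,
either readily detectable ("close") or gray-zone ("distant").

Context wiring realizes the conserved-neighborhood configuration: a wired
cross pair gets each of its proteins placed in a fresh two-member complex
together with one side of an anchor ortholog cluster. Every emitted cross
pair is wired with a small baseline probability (``p_context_spurious``);
*true* pairs are wired with ``p_context_conserved`` extra probability, so
setting that to zero makes context strictly independent of homology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .model_io import (
    BlastHSP,
    BlastPair,
    ComplexSet,
    DomainHit,
    OrthologClusterSet,
    Protein,
)
from .trios import Scenario

__all__ = [
    "WorldParams",
    "WorldBundle",
    "WorldTruth",
    "TrueTrio",
    "generate_world",
    "write_world",
    "worked_example_fixture",
    "WORKED_EXAMPLES",
]


@dataclass(frozen=True)
class WorldParams:
    """Knobs of the synthetic world; defaults are the study conditions.

    ``n_families`` single-copy-per-species families dominated by detectable
    orthologs, with ``p_distant_ortholog`` of the non-scenario families
    diverged into the gray zone; scenario probabilities carve out trio
    families. ``p_context_conserved`` is the extra wiring probability of
    true pairs over the ``p_context_spurious`` baseline applied to every
    emitted cross pair. E-value models are (mean, sd) of log10 E per class,
    clipped to the class range; the gray classes are confined to
    (0.02, 100].
    """

    seed: int = 0
    n_families: int = 400
    family_size_geom_p: float = 0.7
    p_distant_ortholog: float = 0.4
    p_ancient_duplication: float = 0.0
    p_recent_duplication: float = 0.0
    p_fusion: float = 0.0
    n_complexes: int = 40
    complex_size_geom_p: float = 0.5
    n_anchor_families: int = 30
    p_context_conserved: float = 0.8
    p_context_spurious: float = 0.05
    n_spurious_hits: int = 700
    p_domain_annotation: float = 0.9
    evalue_close_mu: float = -25.0
    evalue_close_sd: float = 8.0
    evalue_distant_mu: float = 0.0
    evalue_distant_sd: float = 1.3
    evalue_spurious_mu: float = 0.8
    evalue_spurious_sd: float = 1.0
    families_per_clan: int = 1
    length_min: int = 200
    length_max: int = 600
    species_a: str = "A"
    species_b: str = "B"

    def __post_init__(self) -> None:
        for name in (
            "family_size_geom_p",
            "p_distant_ortholog",
            "p_ancient_duplication",
            "p_recent_duplication",
            "p_fusion",
            "complex_size_geom_p",
            "p_context_conserved",
            "p_context_spurious",
            "p_domain_annotation",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if (
            self.p_ancient_duplication + self.p_recent_duplication + self.p_fusion
            > 1.0
        ):
            raise ValueError("scenario probabilities sum to more than 1")
        if self.n_anchor_families > self.n_families:
            raise ValueError("more anchor families than families")
        if self.length_min < 40 or self.length_max < self.length_min:
            raise ValueError("invalid length range")


@dataclass
class WorldBundle:
    """All pipeline inputs of one synthetic world, in memory."""

    species_a: str
    species_b: str
    proteins: dict[str, Protein]
    hsps_ab: list[BlastHSP]
    hsps_within_b: list[BlastHSP]
    hsps_ba: list[BlastHSP]
    complexes_a: list[ComplexSet]
    complexes_b: list[ComplexSet]
    clusters: OrthologClusterSet
    domains: list[DomainHit]

    @property
    def lengths(self) -> dict[str, int]:
        return {pid: p.length for pid, p in self.proteins.items()}


@dataclass(frozen=True)
class TrueTrio:
    query_id: str
    close_id: str
    distant_id: str
    scenario: Scenario


@dataclass
class WorldTruth:
    """Ground truth: homology per cross pair, scenario per trio family."""

    true_pairs: set[tuple[str, str]]
    pair_class: dict[tuple[str, str], str]
    trios: list[TrueTrio]
    family_of: dict[str, int]
    clan_of_family: dict[int, str]


_GRAY_LO_EXP = float(np.log10(0.02))
_GRAY_HI_EXP = 2.0


class _Builder:
    def __init__(self, params: WorldParams):
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        self.proteins: dict[str, Protein] = {}
        self.domains: list[DomainHit] = []
        self.hsps_ab: list[BlastHSP] = []
        self.hsps_within_b: list[BlastHSP] = []
        self.hsps_ba: list[BlastHSP] = []
        self.complexes_a: list[ComplexSet] = []
        self.complexes_b: list[ComplexSet] = []
        self.clusters: dict[int, tuple[str, str]] = {}
        self.latent_domain: dict[str, tuple[int, int]] = {}
        self.truth = WorldTruth(set(), {}, [], {}, {})
        self._wire_counter = 0

    # -- primitives --------------------------------------------------------

    def draw_evalue(self, klass: str) -> float:
        p = self.p
        if klass == "close":
            x = float(
                np.clip(self.rng.normal(p.evalue_close_mu, p.evalue_close_sd), -180.0, -4.0)
            )
        elif klass == "distant":
            x = float(
                np.clip(
                    self.rng.normal(p.evalue_distant_mu, p.evalue_distant_sd),
                    _GRAY_LO_EXP,
                    _GRAY_HI_EXP,
                )
            )
        elif klass == "spurious":
            x = float(
                np.clip(
                    self.rng.normal(p.evalue_spurious_mu, p.evalue_spurious_sd),
                    _GRAY_LO_EXP,
                    _GRAY_HI_EXP,
                )
            )
        elif klass == "within_dup":
            x = float(np.clip(self.rng.normal(-8.0, 3.0), -60.0, -3.2))
        else:
            raise ValueError(klass)
        return min(float(10.0**x), 100.0)

    def bitscore_for(self, evalue: float) -> float:
        x = np.log10(max(evalue, 1e-180))
        return float(max(25.0, round(55.0 - 1.8 * x + self.rng.normal(0.0, 2.0), 1)))

    def new_protein(
        self, species: str, fam: int, copy: int, clan: str, length: Optional[int] = None
    ) -> str:
        p = self.p
        prefix = "h" if species == p.species_a else "y"
        pid = f"{prefix}{fam:04d}_{copy}"
        if length is None:
            length = int(self.rng.integers(p.length_min, p.length_max + 1))
        self.proteins[pid] = Protein(pid, species, length)
        self.truth.family_of[pid] = fam
        dstart = max(1, int(0.12 * length))
        dend = max(dstart, int(0.88 * length))
        self.latent_domain[pid] = (dstart, dend)
        if self.rng.random() < p.p_domain_annotation:
            self.domains.append(DomainHit(pid, f"PF{fam:05d}", clan, dstart, dend))
        return pid

    def cross_hit(self, h: str, y: str, klass: str, q_interval=None, s_interval=None):
        """Emit an A->B hit plus its B->A mirror; record truth and wire."""
        e = self.draw_evalue(klass)
        bs = self.bitscore_for(e)
        qi = q_interval or self.latent_domain[h]
        si = s_interval or self.latent_domain[y]
        self.hsps_ab.append(BlastHSP(h, y, e, bs, qi[0], qi[1], si[0], si[1]))
        self.hsps_ba.append(BlastHSP(y, h, e, bs, si[0], si[1], qi[0], qi[1]))
        self.truth.pair_class[(h, y)] = klass
        if klass != "spurious":
            self.truth.true_pairs.add((h, y))
        wire_p = self.p.p_context_spurious + (
            self.p.p_context_conserved if klass != "spurious" else 0.0
        )
        if self.rng.random() < min(wire_p, 1.0):
            self.wire_pair(h, y)
        return e

    def within_b_hit(self, y1: str, y2: str, klass: str = "within_dup") -> None:
        e = self.draw_evalue(klass)
        bs = self.bitscore_for(e)
        i1, i2 = self.latent_domain[y1], self.latent_domain[y2]
        self.hsps_within_b.append(
            BlastHSP(y1, y2, e, bs, i1[0], i1[1], i2[0], i2[1])
        )

    def add_cluster(self, fam: int, h: str, y: str) -> None:
        self.clusters[len(self.clusters)] = (h, y)

    def wire_pair(self, h: str, y: str) -> None:
        """Place a pair in fresh complexes next to one anchor ortholog pair."""
        a = int(self.rng.integers(0, self.p.n_anchor_families))
        anchor_h, anchor_y = f"h{a:04d}_0", f"y{a:04d}_0"
        k = self._wire_counter
        self._wire_counter += 1
        if h != anchor_h:
            self.complexes_a.append(
                ComplexSet(f"WA{k:05d}", frozenset({h, anchor_h}), self.p.species_a)
            )
        if y != anchor_y:
            self.complexes_b.append(
                ComplexSet(f"WB{k:05d}", frozenset({y, anchor_y}), self.p.species_b)
            )

    # -- family construction ----------------------------------------------

    def clan_for(self, fam: int) -> str:
        clan = f"CL{fam // max(1, self.p.families_per_clan):05d}"
        self.truth.clan_of_family[fam] = clan
        return clan

    def build_family(self, fam: int, kind: str) -> None:
        p = self.p
        clan = self.clan_for(fam)
        if kind in ("close", "distant"):
            h = self.new_protein(p.species_a, fam, 0, clan)
            y = self.new_protein(p.species_b, fam, 0, clan)
            self.cross_hit(h, y, kind)
            if kind == "close":
                self.add_cluster(fam, h, y)
            self._extra_copies(fam, clan)
        elif kind == "ancient":
            h_a = self.new_protein(p.species_a, fam, 0, clan)
            y_a = self.new_protein(p.species_b, fam, 0, clan)
            h_b = self.new_protein(p.species_a, fam, 1, clan)
            y_b = self.new_protein(p.species_b, fam, 1, clan)
            self.cross_hit(h_a, y_a, "close")
            self.cross_hit(h_b, y_b, "close")
            self.cross_hit(h_a, y_b, "distant")
            self.cross_hit(h_b, y_a, "distant")
            self.add_cluster(fam, h_a, y_a)
            self.add_cluster(fam, h_b, y_b)
            self.within_b_hit(y_a, y_b)
            self.truth.trios.append(TrueTrio(h_a, y_a, y_b, Scenario.ANCIENT_PARALOG))
        elif kind == "recent":
            h = self.new_protein(p.species_a, fam, 0, clan)
            y1 = self.new_protein(p.species_b, fam, 0, clan)
            y2 = self.new_protein(p.species_b, fam, 1, clan)
            self.cross_hit(h, y1, "close")
            self.cross_hit(h, y2, "distant")
            self.add_cluster(fam, h, y1)
            self.within_b_hit(y1, y2)
            self.truth.trios.append(
                TrueTrio(h, y1, y2, Scenario.ASYMMETRIC_DIVERGENCE)
            )
        elif kind == "fusion":
            length = int(self.rng.integers(max(300, p.length_min), p.length_max + 1))
            clan2 = f"{clan}b"
            h = self.new_protein(p.species_a, fam, 0, clan, length=length)
            # replace the single latent domain with two disjoint regions
            self.domains = [d for d in self.domains if d.protein_id != h]
            half = length // 2
            d1, d2 = (10, half - 10), (half + 10, length - 10)
            for iv, cl in ((d1, clan), (d2, clan2)):
                if self.rng.random() < p.p_domain_annotation:
                    acc = f"PF{fam:05d}" if cl == clan else f"PF{fam:05d}b"
                    self.domains.append(DomainHit(h, acc, cl, iv[0], iv[1]))
            y1 = self.new_protein(p.species_b, fam, 0, clan)
            y2 = self.new_protein(p.species_b, fam, 1, clan2)
            self.cross_hit(h, y1, "close", q_interval=d1)
            self.cross_hit(h, y2, "distant", q_interval=d2)
            self.truth.trios.append(TrueTrio(h, y1, y2, Scenario.FUSION_RECOMB))
        else:
            raise ValueError(kind)

    def _extra_copies(self, fam: int, clan: str) -> None:
        """Silent within-species paralogs inflating the proteome realistically."""
        p = self.p
        for species in (p.species_a, p.species_b):
            n_extra = min(int(self.rng.geometric(p.family_size_geom_p)) - 1, 2)
            for i in range(n_extra):
                self.new_protein(species, fam, 10 + i, clan)

    # -- world assembly ----------------------------------------------------

    def build(self) -> tuple[WorldBundle, WorldTruth]:
        p = self.p
        for fam in range(p.n_families):
            if fam < p.n_anchor_families:
                kind = "close"
            else:
                u = self.rng.random()
                if u < p.p_ancient_duplication:
                    kind = "ancient"
                elif u < p.p_ancient_duplication + p.p_recent_duplication:
                    kind = "recent"
                elif u < p.p_ancient_duplication + p.p_recent_duplication + p.p_fusion:
                    kind = "fusion"
                else:
                    kind = (
                        "distant"
                        if self.rng.random() < p.p_distant_ortholog
                        else "close"
                    )
            self.build_family(fam, kind)
        self._spurious_hits()
        self._background_complexes()
        clusters = OrthologClusterSet(
            {
                f"og{i:05d}": (frozenset({h}), frozenset({y}))
                for i, (h, y) in self.clusters.items()
            }
        )
        bundle = WorldBundle(
            species_a=p.species_a,
            species_b=p.species_b,
            proteins=self.proteins,
            hsps_ab=self.hsps_ab,
            hsps_within_b=self.hsps_within_b,
            hsps_ba=self.hsps_ba,
            complexes_a=self.complexes_a,
            complexes_b=self.complexes_b,
            clusters=clusters,
            domains=self.domains,
        )
        return bundle, self.truth

    def _spurious_hits(self) -> None:
        p = self.p
        prot_a = sorted(
            pid for pid, pr in self.proteins.items() if pr.species == p.species_a
        )
        prot_b = sorted(
            pid for pid, pr in self.proteins.items() if pr.species == p.species_b
        )
        if not prot_a or not prot_b:
            return
        emitted = 0
        attempts = 0
        while emitted < p.n_spurious_hits and attempts < 50 * p.n_spurious_hits:
            attempts += 1
            h = prot_a[int(self.rng.integers(len(prot_a)))]
            y = prot_b[int(self.rng.integers(len(prot_b)))]
            if self.truth.family_of[h] == self.truth.family_of[y]:
                continue
            if (h, y) in self.truth.pair_class:
                continue
            self.cross_hit(h, y, "spurious")
            emitted += 1

    def _background_complexes(self) -> None:
        p = self.p
        for species, out, tag in (
            (p.species_a, self.complexes_a, "BGA"),
            (p.species_b, self.complexes_b, "BGB"),
        ):
            pool = sorted(
                pid for pid, pr in self.proteins.items() if pr.species == species
            )
            for i in range(p.n_complexes):
                size = min(
                    2 + int(self.rng.geometric(p.complex_size_geom_p)) - 1,
                    6,
                    len(pool),
                )
                if size < 2:
                    break
                members = self.rng.choice(len(pool), size=size, replace=False)
                out.append(
                    ComplexSet(
                        f"{tag}{i:05d}",
                        frozenset(pool[j] for j in members),
                        species,
                    )
                )


def generate_world(params: WorldParams) -> tuple[WorldBundle, WorldTruth]:
    """Generate a complete, deterministic input bundle plus ground truth.

    The same ``params`` (including seed) always produce identical bundles;
    infeasible combinations (e.g. complexes larger than the proteome) raise.
    """
    return _Builder(params).build()


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def _write_blast(hsps, path: Path) -> None:
    with open(path, "w") as fh:
        for h in hsps:
            aln = h.qend - h.qstart + 1
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t50.0\t{aln}\t0\t0\t"
                f"{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t{h.evalue!r}\t{h.bitscore!r}\n"
            )


def write_world(
    bundle: WorldBundle, truth: WorldTruth, out_dir: Union[str, Path]
) -> dict[str, Path]:
    """Write every input table plus the truth tables; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def reg(name: str, fname: str) -> Path:
        paths[name] = out / fname
        return paths[name]

    _write_blast(bundle.hsps_ab, reg("blast_ab", "blast_ab.tsv"))
    _write_blast(bundle.hsps_within_b, reg("blast_within_b", "blast_within_b.tsv"))
    _write_blast(bundle.hsps_ba, reg("blast_ba", "blast_ba.tsv"))
    for name, fname, complexes in (
        ("complexes_a", "complexes_a.tsv", bundle.complexes_a),
        ("complexes_b", "complexes_b.tsv", bundle.complexes_b),
    ):
        with open(reg(name, fname), "w") as fh:
            for c in sorted(complexes, key=lambda c: c.complex_id):
                for m in sorted(c.members):
                    fh.write(f"{c.complex_id}\t{m}\n")
    with open(reg("clusters", "clusters.tsv"), "w") as fh:
        for cid in sorted(bundle.clusters.cluster_ids):
            a, b = bundle.clusters.members(cid)
            for m in sorted(a):
                fh.write(f"{cid}\t{bundle.species_a}\t{m}\n")
            for m in sorted(b):
                fh.write(f"{cid}\t{bundle.species_b}\t{m}\n")
    with open(reg("domains", "domains.tsv"), "w") as fh:
        for d in sorted(bundle.domains, key=lambda d: (d.protein_id, d.start, d.domain_acc)):
            fh.write(
                f"{d.protein_id}\t{d.domain_acc}\t{d.clan_acc or ''}\t{d.start}\t{d.end}\n"
            )
    for species, name, fname in (
        (bundle.species_a, "fasta_a", "proteins_a.fasta"),
        (bundle.species_b, "fasta_b", "proteins_b.fasta"),
    ):
        with open(reg(name, fname), "w") as fh:
            for pid in sorted(bundle.proteins):
                pr = bundle.proteins[pid]
                if pr.species != species:
                    continue
                fh.write(f">{pid}\n")
                seq = "M" + "A" * (pr.length - 1)
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    with open(reg("truth_pairs", "truth_pairs.tsv"), "w") as fh:
        for (q, s) in sorted(truth.pair_class):
            klass = truth.pair_class[(q, s)]
            fh.write(f"{q}\t{s}\t{klass}\t{int((q, s) in truth.true_pairs)}\n")
    with open(reg("truth_trios", "truth_trios.tsv"), "w") as fh:
        for t in sorted(truth.trios, key=lambda t: t.query_id):
            fh.write(f"{t.query_id}\t{t.close_id}\t{t.distant_id}\t{t.scenario.name}\n")
    return paths


# ---------------------------------------------------------------------------
# hand-built worked examples
# ---------------------------------------------------------------------------

def _minimal_rescue() -> dict[str, object]:
    """The minimal conserved-neighborhood configuration: one insignificant
    cross-species hit whose proteins sit next to a clear ortholog pair."""
    complexes_a = [ComplexSet("CA1", frozenset({"h1", "h2"}), "A")]
    complexes_b = [ComplexSet("CB1", frozenset({"y1", "y2"}), "B")]
    clusters = OrthologClusterSet({"og1": (frozenset({"h2"}), frozenset({"y2"}))})
    pair = BlastPair("h1", "y1", BlastHSP("h1", "y1", 0.5, 20.0, 1, 100, 1, 100))
    return {
        "complexes_a": complexes_a,
        "complexes_b": complexes_b,
        "clusters": clusters,
        "pairs": [pair],
    }


def _pass1_completeness() -> dict[str, object]:
    """710 complexes over 1901 distinct subunits, 1199 of them with a
    detectable homolog, partitioning the complexes 172 / 427 / 111."""
    complexes: list[ComplexSet] = []
    pairs: list[BlastPair] = []
    counter = 0

    def subunit(found: bool) -> str:
        nonlocal counter
        pid = f"s{counter:05d}"
        counter += 1
        if found:
            pairs.append(
                BlastPair(pid, f"t_{pid}", BlastHSP(pid, f"t_{pid}", 1e-10, 90.0, 1, 90, 1, 90))
            )
        return pid

    idx = 0
    # 172 complexes fully found: 84 of size 5 and 88 of size 4 (772 subunits)
    for size in [5] * 84 + [4] * 88:
        complexes.append(
            ComplexSet(f"C{idx:04d}", frozenset(subunit(True) for _ in range(size)), "A")
        )
        idx += 1
    # 427 complexes with one found and one missing subunit each
    for _ in range(427):
        complexes.append(
            ComplexSet(f"C{idx:04d}", frozenset({subunit(True), subunit(False)}), "A")
        )
        idx += 1
    # 111 complexes with no subunit found: 53 of size 3 and 58 of size 2 (275)
    for size in [3] * 53 + [2] * 58:
        complexes.append(
            ComplexSet(f"C{idx:04d}", frozenset(subunit(False) for _ in range(size)), "A")
        )
        idx += 1
    return {"complexes": complexes, "pairs": pairs, "n_subunits": counter}


def _fate_counts() -> dict[str, object]:
    """307 ancient duplicate pairs with complex fates 139/25/108/35."""
    complexes: list[ComplexSet] = []
    duplicate_pairs: list[tuple[str, str]] = []
    k = 0

    def fresh(n: int) -> list[str]:
        nonlocal k
        ids = [f"p{k + i:05d}" for i in range(n)]
        k += n
        return ids

    idx = 0

    def add_complex(members: list[str]) -> None:
        nonlocal idx
        complexes.append(ComplexSet(f"F{idx:04d}", frozenset(members), "B"))
        idx += 1

    for _ in range(139):  # both duplicates in one complex
        c, d = fresh(2)
        add_complex([c, d])
        duplicate_pairs.append((c, d))
    for _ in range(25):  # overlapping complexes sharing 3 of 4 subunits
        c, d, p1, p2, p3, extra_c, extra_d = fresh(7)
        add_complex([c, p1, p2, p3, extra_c])
        add_complex([d, p1, p2, p3, extra_d])
        duplicate_pairs.append((c, d))
    for _ in range(108):  # disjoint complexes
        c, d, pc, pd = fresh(4)
        add_complex([c, pc])
        add_complex([d, pd])
        duplicate_pairs.append((c, d))
    for _ in range(35):  # the close duplicate is in no complex
        c, d, pd = fresh(3)
        add_complex([d, pd])
        duplicate_pairs.append((c, d))
    return {"complexes": complexes, "duplicate_pairs": duplicate_pairs}


def _trio_counts() -> dict[str, object]:
    """405 rescued gray-zone pairs, 347 of whose queries also have a
    significant close hit — an 85.68% trio-availability rate."""
    recovered: list[BlastPair] = []
    all_pairs: list[BlastPair] = []
    for i in range(405):
        q, d = f"q{i:04d}", f"d{i:04d}"
        rec = BlastPair(q, d, BlastHSP(q, d, 0.5, 22.0, 1, 100, 1, 100))
        recovered.append(rec)
        all_pairs.append(rec)
        if i < 347:
            c = f"c{i:04d}"
            all_pairs.append(BlastPair(q, c, BlastHSP(q, c, 1e-20, 140.0, 1, 150, 1, 150)))
    return {"recovered": recovered, "all_pairs": all_pairs}


WORKED_EXAMPLES = {
    "minimal_rescue": _minimal_rescue,
    "pass1_completeness": _pass1_completeness,
    "fate_counts": _fate_counts,
    "trio_counts": _trio_counts,
}


def worked_example_fixture(name: str) -> dict[str, object]:
    """Return one of the registered hand-built worked-example bundles."""
    try:
        factory = WORKED_EXAMPLES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; registered: {sorted(WORKED_EXAMPLES)}"
        ) from None
    return factory()
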