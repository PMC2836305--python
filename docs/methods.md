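# Methods

## Context classification

The co-complex network of a species is the undirected graph over proteins
whose edge set is the union, over all annotated complexes, of every
unordered member pair, merged with any standalone binary co-complex pairs
supplied alongside (self-pairs discarded; duplicate complex definitions
under different ids are kept at this stage). A singleton complex
contributes membership but no edges, so its protein does not count as
"in the network" for classification, which requires at least one edge.

A cross-species BLAST pair (query in species A, subject in species B) is
classified by three nested conditions:

- `IN_NETWORKS`: both proteins have ≥ 1 co-complex partner;
- `ORTHO_NEIGHBORS`: additionally, each has ≥ 1 partner belonging to some
  cross-species ortholog cluster;
- `ALIGNED`: additionally, a partner of the query and a partner of the
  subject belong to the *same* cluster.

Only the neighbors are inspected — the query and subject may themselves be
clustered without affecting the verdict. Because the graph has no
self-edges, the witness can never be the pair itself. The reported witness
is the lexicographically smallest (neighbor_A, neighbor_B, cluster) triple,
which makes reports order-independent and byte-reproducible. An optional
flag additionally rejects witnesses whose A-side neighbor is clustered
with the subject itself (off by default: the alignment criterion as stated
inspects neighborhoods only).

Ortholog clusters are taken as input (Inparanoid-style, one cluster per
protein at most, clusters restricted to those with members in both
species). A convenience seeder builds singleton clusters from
bidirectional best hits with bitscore ≥ 50 and alignment coverage ≥ 50% of
the shorter protein — the seed criterion of Inparanoid, without inparalog
expansion or bootstrap confidence. Coverage is measured with the
query-side aligned length of each directional hit; the convention is
deliberately simple since the seeder is a stand-in for a real ortholog
inference run, not a replacement.

## Gold standard and PPV

Multiple HSPs per (query, subject) pair collapse to the one with the
lowest E-value (ties: higher bitscore, then smaller query start). E-values
are binned into eight bins with edges {1e-5, 1e-4, 1e-3, 0.01, 0.1, 1, 10,
100}; the first bin is closed at both ends, the rest are (lower, upper],
and values above 100 — the assumed reporting ceiling of the search — are
rejected rather than binned.

A pair is judged TP when a Pfam domain on each side overlaps that side's
HSP region by strictly more than 50% of the shorter of the two regions and
the two domains share a clan; if either side has no domain reaching that
overlap the pair is IGNORED (the clan standard cannot be applied there);
otherwise it is FP. Two deliberate readings of edge cases:

- A protein with no annotated domain can never reach the overlap bar, so
  its pairs are IGNORED rather than FP — counting unevaluable pairs as
  failures would deflate PPV with noise unrelated to homology.
- Domains in no clan never match, even when the family accessions are
  identical (strict "same clan" reading); a flag lets identical family
  accessions count for users who prefer the looser standard.

PPV per (bin × category) cell is TP/(TP+FP) over evaluable pairs; the
fraction with ignored pairs in the denominator is reported alongside so
either convention can be read. Categories are the nested subsets, so the
`ALIGNED` column of the table is a sub-sample of `ALL`. Cells with fewer
than 60 pairs or 50 queries are flagged with a warning, never filtered.
The family-size-normalized variant gives each query one vote per cell,
split equally over its evaluable pairs; this is an interpretation of
"normalizing per query protein" — the exact historical scheme is not
specified anywhere, and the per-query equal split is the simplest scheme
with the intended effect (a large family cannot dominate a cell).

## Subunit recovery

Subcomplex removal drops every complex whose member set is a strict subset
of another's; exact duplicates keep the lexicographically smallest id; a
mode flag drops supercomplexes instead. Pass 1 takes the best hit with
E ≤ 0.001 (inclusive — the cutoff is quoted without strictness, and ≤ is
the conventional reading). Pass 2 considers only subunits left unresolved
and accepts the best `ALIGNED`-context hit with E ≤ 1. Subunits shared by
several complexes are evaluated once and their verdict propagates to every
containing complex. Completeness summarizes complexes as ALL / SOME /
NONE of their subunits matched, with percentages rounded to two decimals.
External confirmation of pass-2 candidates (profile searches etc.) is a
free-text annotation column, not computed here.

## Trio analysis

For each rescued pair (query, distant subject; E > 0.01 and `ALIGNED`),
a trio forms when the query has a different subject at E ≤ 0.001 (the same
significance convention as pass 1; exposed as `--close-cutoff` because no
canonical value exists for this step). The subject-side pair is
"homologous" when a within-species hit at E ≤ cutoff links them *or* they
share any non-null clan (domain content only, no overlap condition —
divergent paralogs often align poorly yet keep diagnostic domains).
Decision rule:

- not homologous + best HSPs on disjoint query regions → fusion /
  fission / domain recombination;
- homologous + the distant protein has a significant hit back in the
  query species → ancient paralogy (duplication before the speciation);
- homologous + no back-hit → asymmetric divergence after a recent
  duplication;
- anything else → unresolved.

Disjointness uses overlap over the shorter interval with threshold 0 —
"different region" read literally; `--min-overlap` relaxes it. The
back-hit may be the original query itself unless `--exclude-self-family`
is set; the permissive default reflects that a significant back-hit to any
member of the query's family already dates the duplication before the
speciation. Duplicate fate checks, in order: some complex containing both;
some complex pair sharing more than half of the smaller one's subunits;
either protein in no complex; otherwise different complexes. The
multi-complex over-representation test is a one-sided hypergeometric
upper tail (the natural test for "more multi-complex proteins than
expected from the background"); a two-sided Fisher option is provided.

## Synthetic worlds

The generator emits families with one protein per species by default.
Family histories: plain orthologs are "close" (log10 E ~ N(−25, 8),
clipped to E ≤ 1e-4) or "distant" (log10 E ~ N(0, 1.3) clipped into
(0.02, 100], i.e. confined to the gray zone). Ancient-duplication families
produce two ortholog pairs with distant cross pairs and a significant
within-B hit; recent-duplication families produce one conserved and one
fast-evolving B copy whose only A-side relative stays in the gray zone;
fusion families produce an A protein with two disjoint domain regions of
unrelated clans, each matched by a different B protein. Spurious hits
sample non-homologous cross-species pairs from N(0.8, 1.0) in log10 E,
also clipped to the gray zone. Each protein carries a latent domain
(annotated with probability 0.9) covering the central ~76% of its length;
HSPs are placed on the latent domains so that annotated pairs are always
evaluable — TP by construction for true pairs, FP for spurious ones.

Context wiring: every emitted cross pair is, with a baseline probability
of 0.05, placed in the conserved-neighborhood configuration (each protein
into a fresh two-member complex with one side of a randomly chosen anchor
ortholog pair); true pairs get an additional 0.8. The split matters:
setting the conserved component to zero makes wiring strictly independent
of homology, which is the correct null for the enrichment property —
`ALIGNED` then behaves as a random sub-sample of all pairs, up to a small
correlation induced by proteins that occur in several spurious pairs.
Random background complexes (40 per species, sizes 2–6) provide
`IN_NETWORKS` context and fate material independent of the wiring.

Default sizes (400 families, 30 anchors, 700 spurious hits) give roughly
800–900 gray-zone pairs per world — enough for stable per-bin PPV at a
generation cost of milliseconds. What the generator does *not* emulate:
alignment-theoretic E-value statistics, compositional biases, partial
domain overlaps near the 50% boundary, incomplete or wrongly annotated
complexes, and promiscuous domains shared across unrelated families.
Passing tests therefore demonstrate the machinery's correctness and the
qualitative context-enrichment mechanism, not performance on real
proteomes.

## Worked-example bundles

Four hand-built bundles encode printed arithmetic rather than real
proteins: `minimal_rescue` (the minimal rescued-pair configuration),
`pass1_completeness` (710 complexes over 1901 distinct subunits, 1199
found → 63.07%, partitioned 172/427/111 → 24.23/60.14/15.63%),
`fate_counts` (307 duplicate pairs split 139/25/108/35 →
45.3/8.14/35.2%), and `trio_counts` (405 rescued pairs, 347 with a close
hit → 85.68%). Complex sizes inside the bundles are free choices
constrained only by the published totals.

## Numerical and design notes

- All coordinates are 1-based inclusive; interval lengths are
  end − start + 1 everywhere.
- All tie-breaks (best hits, witnesses, duplicate complexes) are
  lexicographic after the scoring criteria, so outputs are reproducible
  byte for byte; report floats use shortest round-trip repr.
- E-value comparisons with cutoffs are inclusive (≤) throughout.
- The pipeline treats BLAST tables as ordered query→subject as given;
  whether the underlying search ran in one or both directions is the
  caller's concern (the trio stage takes the reverse-direction table as a
  separate input).
- Known limitations: no probabilistic network alignment or missing-edge
  model (complex datasets are too sparse for sensible estimates of
  missing co-complex links); at most two species; no inparalog expansion
  in the ortholog seeder; enrichment p-values are unadjusted single
  tests.
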