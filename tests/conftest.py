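"""Shared fixtures: tiny constructors and random-world helpers."""

from __future__ import annotations

import random

import pytest

from cocoalign.model_io import BlastHSP, BlastPair, ComplexSet, OrthologClusterSet


def make_hsp(q, s, evalue, bitscore=50.0, qi=(1, 100), si=(1, 100)):
    return BlastHSP(q, s, evalue, bitscore, qi[0], qi[1], si[0], si[1])


def make_pair(q, s, evalue, bitscore=50.0, qi=(1, 100), si=(1, 100)):
    return BlastPair(q, s, make_hsp(q, s, evalue, bitscore, qi, si))


def random_mini_world(rng: random.Random, n_per_species: int = 10):
    """A small random pair of networks plus clusters, for oracle checks.

    Returns (complexes_a, complexes_b, clusters) over proteins a0..aN / b0..bN
    with random complexes and random disjoint singleton-singleton clusters.
    """
    prot_a = [f"a{i}" for i in range(n_per_species)]
    prot_b = [f"b{i}" for i in range(n_per_species)]
    complexes_a = [
        ComplexSet(
            f"ca{i}",
            frozenset(rng.sample(prot_a, rng.randint(1, min(4, n_per_species)))),
            "A",
        )
        for i in range(rng.randint(1, 5))
    ]
    complexes_b = [
        ComplexSet(
            f"cb{i}",
            frozenset(rng.sample(prot_b, rng.randint(1, min(4, n_per_species)))),
            "B",
        )
        for i in range(rng.randint(1, 5))
    ]
    n_clusters = rng.randint(0, n_per_species // 2)
    pool_a = rng.sample(prot_a, n_clusters)
    pool_b = rng.sample(prot_b, n_clusters)
    clusters = OrthologClusterSet(
        {
            f"og{i}": (frozenset({pool_a[i]}), frozenset({pool_b[i]}))
            for i in range(n_clusters)
        }
    )
    return complexes_a, complexes_b, clusters


@pytest.fixture
def rng():
    return random.Random(20240917)
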