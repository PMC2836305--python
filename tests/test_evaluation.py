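"""E-value binning, clan-based labeling and PPV tabulation."""

from __future__ import annotations

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocoalign.evaluation import (
    ALL_CATEGORY,
    applicability_counts,
    assign_bin,
    dedup_best_hsp,
    label_pair,
    overlap_fraction,
    ppv_table,
    ppv_table_query_normalized,
)
from cocoalign.model_io import ContextCategory, DomainHit, HomologyLabel

from conftest import make_hsp, make_pair


class TestDedup:
    def test_lowest_evalue_wins(self):
        hsps = [make_hsp("q", "s", 0.5), make_hsp("q", "s", 0.01)]
        (pair,) = dedup_best_hsp(hsps)
        assert pair.evalue == 0.01

    def test_single_hsp_identity(self):
        h = make_hsp("q", "s", 1e-3)
        (pair,) = dedup_best_hsp([h])
        assert pair.best_hsp == h

    def test_matches_group_by_min_oracle(self, rng):
        hsps = [
            make_hsp(
                f"q{rng.randint(0, 5)}",
                f"s{rng.randint(0, 5)}",
                rng.choice([1e-8, 1e-3, 0.5, 2.0]),
                bitscore=rng.choice([30.0, 60.0]),
                qi=(s := rng.randint(1, 50), s + 40),
            )
            for _ in range(100)
        ]
        got = {(p.query_id, p.subject_id): p.best_hsp for p in dedup_best_hsp(hsps)}
        # oracle: explicit group-by then min with the documented tie-break
        groups = {}
        for h in hsps:
            groups.setdefault((h.query_id, h.subject_id), []).append(h)
        want = {
            k: min(v, key=lambda h: (h.evalue, -h.bitscore, h.qstart))
            for k, v in groups.items()
        }
        assert got == want


class TestAssignBin:
    @pytest.mark.parametrize(
        "evalue,index",
        [
            (0.0, 1),
            (1e-5, 1),  # upper edge inclusive
            (1.0001e-5, 2),
            (1e-3, 3),
            (0.5, 6),
            (10.0, 7),
            (100.0, 8),
        ],
    )
    def test_boundaries(self, evalue, index):
        assert assign_bin(evalue).index == index

    def test_above_ceiling_errors(self):
        with pytest.raises(ValueError, match="ceiling"):
            assign_bin(100.01)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_bins_partition_the_range(self, evalue):
        b = assign_bin(evalue)
        assert evalue in b


class TestOverlapFraction:
    def test_partial_overlap_inclusive_arithmetic(self):
        assert overlap_fraction((10, 60), (40, 100)) == pytest.approx(21 / 51)

    def test_identical_intervals(self):
        assert overlap_fraction((5, 25), (5, 25)) == 1.0

    def test_adjacent_intervals_are_disjoint(self):
        assert overlap_fraction((1, 10), (11, 20)) == 0.0


def dom(pid, clan, start, end, acc="PF1"):
    return DomainHit(pid, acc, clan, start, end)


class TestLabelPair:
    PAIR = make_pair("q", "s", 0.5, qi=(10, 100), si=(20, 110))

    def test_shared_clan_with_good_overlap_is_tp(self):
        lab = label_pair(
            self.PAIR, [dom("q", "CL1", 10, 95)], [dom("s", "CL1", 25, 100)]
        )
        assert lab is HomologyLabel.TP

    def test_different_clans_is_fp(self):
        lab = label_pair(
            self.PAIR, [dom("q", "CL1", 10, 95)], [dom("s", "CL2", 25, 100)]
        )
        assert lab is HomologyLabel.FP

    def test_no_overlapping_domain_on_query_is_ignored(self):
        lab = label_pair(self.PAIR, [], [dom("s", "CL1", 25, 100)])
        assert lab is HomologyLabel.IGNORED

    def test_exactly_half_overlap_is_ignored(self):
        # domain of length 91 on 10..100; query HSP 10..100 (91 aa);
        # overlap 46/91 > .5 would need 46; pick a domain overlapping exactly half
        pair = make_pair("q", "s", 0.5, qi=(1, 100), si=(1, 100))
        # domain 51..150: overlap 50 aa of shorter (100) = exactly 0.5
        lab = label_pair(
            pair, [dom("q", "CL1", 51, 150)], [dom("s", "CL1", 1, 100)]
        )
        assert lab is HomologyLabel.IGNORED

    def test_clanless_domains_never_match_by_default(self):
        lab = label_pair(
            self.PAIR,
            [dom("q", None, 10, 95, acc="PF9")],
            [dom("s", None, 25, 100, acc="PF9")],
        )
        assert lab is HomologyLabel.FP

    def test_family_accession_flag_accepts_clanless_match(self):
        lab = label_pair(
            self.PAIR,
            [dom("q", None, 10, 95, acc="PF9")],
            [dom("s", None, 25, 100, acc="PF9")],
            accept_same_family=True,
        )
        assert lab is HomologyLabel.TP

    def test_symmetric_under_species_swap(self):
        swapped = make_pair("s", "q", 0.5, qi=(20, 110), si=(10, 100))
        a = label_pair(self.PAIR, [dom("q", "CL1", 10, 95)], [dom("s", "CL1", 25, 100)])
        b = label_pair(swapped, [dom("s", "CL1", 25, 100)], [dom("q", "CL1", 10, 95)])
        assert a is b


def _mk_world(rng, n=120):
    """Random pairs with random contexts and labels for table oracles."""
    pairs, contexts, labels = [], {}, {}
    for i in range(n):
        q = f"q{rng.randint(0, 20)}"
        s = f"s{i}"
        p = make_pair(q, s, rng.choice([1e-8, 1e-4, 0.03, 0.5, 5.0, 50.0]))
        pairs.append(p)
        contexts[(q, s)] = rng.choice(list(ContextCategory))
        labels[(q, s)] = rng.choice(list(HomologyLabel))
    return pairs, contexts, labels


class TestPpvTable:
    def test_counts_and_ppv_excluding_ignored(self, recwarn):
        pairs = [make_pair(f"q{i}", f"s{i}", 0.5) for i in range(6)]
        contexts = {(p.query_id, p.subject_id): ContextCategory.NONE for p in pairs}
        labels = {
            (p.query_id, p.subject_id): lab
            for p, lab in zip(
                pairs,
                [HomologyLabel.TP] * 3 + [HomologyLabel.FP] + [HomologyLabel.IGNORED] * 2,
            )
        }
        stats = {
            (s.category, s.bin.index): s for s in ppv_table(pairs, contexts, labels)
        }
        cell = stats[(ALL_CATEGORY, 6)]
        assert cell.n_pairs == 6 and cell.n_ignored == 2
        assert cell.ppv == pytest.approx(0.75)
        assert cell.tp_fraction_all == pytest.approx(0.5)
        assert cell.low_support

    def test_empty_bin_has_null_ppv(self):
        stats = ppv_table([], {}, {})
        assert all(s.ppv is None and s.n_pairs == 0 for s in stats)

    def test_cells_match_brute_force_filtering(self, rng, recwarn):
        pairs, contexts, labels = _mk_world(rng)
        stats = {
            (s.category, s.bin.index): s for s in ppv_table(pairs, contexts, labels)
        }
        nested = {
            ALL_CATEGORY: set(ContextCategory),
            "IN_NETWORKS": {
                ContextCategory.IN_NETWORKS,
                ContextCategory.ORTHO_NEIGHBORS,
                ContextCategory.ALIGNED,
            },
            "ORTHO_NEIGHBORS": {
                ContextCategory.ORTHO_NEIGHBORS,
                ContextCategory.ALIGNED,
            },
            "ALIGNED": {ContextCategory.ALIGNED},
        }
        from cocoalign.evaluation import assign_bin

        for cat, members in nested.items():
            for b in range(1, 9):
                cell = [
                    p
                    for p in pairs
                    if assign_bin(p.evalue).index == b
                    and contexts[(p.query_id, p.subject_id)] in members
                ]
                s = stats[(cat, b)]
                assert s.n_pairs == len(cell)
                assert s.n_tp == sum(
                    1
                    for p in cell
                    if labels[(p.query_id, p.subject_id)] is HomologyLabel.TP
                )
                assert s.n_queries == len({p.query_id for p in cell})

    def test_bin_partition_covers_all_pairs(self, rng, recwarn):
        pairs, contexts, labels = _mk_world(rng)
        stats = ppv_table(pairs, contexts, labels)
        total = sum(s.n_pairs for s in stats if s.category == ALL_CATEGORY)
        assert total == len(pairs)


class TestQueryNormalized:
    def test_per_query_weighting_example(self, recwarn):
        pairs = [make_pair("qa", f"s{i}", 0.5) for i in range(3)]
        pairs.append(make_pair("qb", "s9", 0.5))
        key = lambda p: (p.query_id, p.subject_id)  # noqa: E731
        contexts = {key(p): ContextCategory.NONE for p in pairs}
        labels = {key(p): HomologyLabel.TP for p in pairs[:3]}
        labels[key(pairs[3])] = HomologyLabel.FP
        raw = {
            (s.category, s.bin.index): s for s in ppv_table(pairs, contexts, labels)
        }
        norm = {
            (s.category, s.bin.index): s
            for s in ppv_table_query_normalized(pairs, contexts, labels)
        }
        assert raw[(ALL_CATEGORY, 6)].ppv == pytest.approx(0.75)
        assert norm[(ALL_CATEGORY, 6)].ppv == pytest.approx(0.5)

    def test_equals_raw_when_one_pair_per_query(self, rng, recwarn):
        pairs = [make_pair(f"q{i}", f"s{i}", rng.choice([0.03, 0.5, 5.0])) for i in range(40)]
        key = lambda p: (p.query_id, p.subject_id)  # noqa: E731
        contexts = {key(p): ContextCategory.ALIGNED for p in pairs}
        labels = {
            key(p): rng.choice([HomologyLabel.TP, HomologyLabel.FP]) for p in pairs
        }
        raw = ppv_table(pairs, contexts, labels)
        norm = ppv_table_query_normalized(pairs, contexts, labels)
        for a, b in zip(raw, norm):
            if a.ppv is None:
                assert b.ppv is None
            else:
                assert b.ppv == pytest.approx(a.ppv)

    def test_matches_explicit_weight_sum_oracle(self, rng, recwarn):
        pairs, contexts, labels = _mk_world(rng)
        from cocoalign.evaluation import assign_bin

        norm = {
            (s.category, s.bin.index): s
            for s in ppv_table_query_normalized(pairs, contexts, labels)
        }
        for b in range(1, 9):
            cell = [p for p in pairs if assign_bin(p.evalue).index == b]
            evaluable = [
                p
                for p in cell
                if labels[(p.query_id, p.subject_id)] is not HomologyLabel.IGNORED
            ]
            per_q = {}
            for p in evaluable:
                per_q.setdefault(p.query_id, []).append(p)
            w_tp = sum(
                1.0 / len(per_q[p.query_id])
                for p in evaluable
                if labels[(p.query_id, p.subject_id)] is HomologyLabel.TP
            )
            w_all = float(len(per_q))
            want = w_tp / w_all if w_all else None
            got = norm[(ALL_CATEGORY, b)].ppv
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)


class TestApplicability:
    def test_hand_counted_example(self):
        pairs = [
            make_pair("q1", "s1", 0.5),
            make_pair("q1", "s2", 0.5),
            make_pair("q2", "s3", 0.5),
            make_pair("q3", "s4", 0.5),
            make_pair("q4", "s5", 0.5),
        ]
        contexts = {
            ("q1", "s1"): ContextCategory.ALIGNED,
            ("q1", "s2"): ContextCategory.NONE,
            ("q2", "s3"): ContextCategory.ALIGNED,
            ("q3", "s4"): ContextCategory.IN_NETWORKS,
            ("q4", "s5"): ContextCategory.ORTHO_NEIGHBORS,
        }
        rows = {r["bin"]: r for r in applicability_counts(pairs, contexts)}
        assert rows[6]["n_pairs_all"] == 5
        assert rows[6]["n_queries_all"] == 4
        assert rows[6]["n_pairs_aligned"] == 2
        assert rows[6]["n_queries_aligned"] == 2

    def test_no_aligned_pairs_gives_zeros(self):
        pairs = [make_pair("q1", "s1", 0.5)]
        contexts = {("q1", "s1"): ContextCategory.NONE}
        rows = {r["bin"]: r for r in applicability_counts(pairs, contexts)}
        assert rows[6]["n_pairs_aligned"] == 0
        assert rows[6]["n_queries_aligned"] == 0
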