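"""Caller contracts: normalization, candidate rules, merging, consensus."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drnatss.calling import (
    NormalizationError,
    TssCandidate,
    call_tss,
    merge_close,
    normalize_coverage,
    replicate_consensus,
    support_counts,
)
from drnatss.tracks import CoverageTrack


def track(values, strand="+", treatment="plus_tex", replicate=1, mapped=100.0):
    return CoverageTrack("chr", strand, np.asarray(values, float), treatment, replicate, mapped)


def cand(position, height, strand="+", replicate=1, enriched=True):
    return TssCandidate("chr", position, strand, height, 0.0, 10.0, replicate, enriched)


class TestNormalize:
    def test_deeper_library_scaled_to_min_depth(self):
        tracks = [track([10, 0], mapped=200), track([4, 4], treatment="minus_tex", mapped=100)]
        out = normalize_coverage(tracks)
        assert out[0].values[0] == 5.0          # 10 * 100/200
        assert np.array_equal(out[1].values, tracks[1].values)  # min-depth unchanged

    def test_three_library_scaling(self):
        tracks = [
            track([30], mapped=150, replicate=1),
            track([8], mapped=100, replicate=2),
            track([5], mapped=50, replicate=3),
        ]
        out = normalize_coverage(tracks)
        assert out[0].values[0] == pytest.approx(10.0)   # 30 * 50/150
        assert out[1].values[0] == pytest.approx(4.0)
        assert out[2].values[0] == pytest.approx(5.0)

    def test_zero_mapped_reads_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_coverage([track([1], mapped=0)])

    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=30),
           st.integers(2, 10))
    def test_within_library_order_preserved(self, values, depth_ratio):
        tracks = [track(values, mapped=100 * depth_ratio), track([0] * len(values), mapped=100)]
        out = normalize_coverage(tracks)
        order = np.argsort(np.asarray(values, float), kind="stable")
        assert np.array_equal(np.argsort(out[0].values, kind="stable"), order)


class TestCallTss:
    def make_pair(self, minus_values, plus_values, strand="+"):
        return (
            track(minus_values, strand=strand, treatment="minus_tex"),
            track(plus_values, strand=strand, treatment="plus_tex"),
        )

    def test_enrichment_threshold_uses_pseudocount(self):
        # step from 0 to the peak; enrichment 25/11 < 2.5 but 28/11 >= 2.5
        minus, plus = self.make_pair([0, 10, 0], [0, 25, 0])
        assert call_tss(minus, plus) == []
        minus, plus = self.make_pair([0, 10, 0], [0, 28, 0])
        calls = call_tss(minus, plus)
        assert [c.position for c in calls] == [2]
        assert calls[0].enrichment_factor == pytest.approx(28 / 11)

    def test_flat_track_has_no_step(self):
        minus, plus = self.make_pair([0] * 6, [50] * 6)
        assert call_tss(minus, plus) == []

    def test_zero_minus_coverage_allowed_by_pseudocount(self):
        minus, plus = self.make_pair([0, 0, 0], [0, 10, 0])
        calls = call_tss(minus, plus)
        assert len(calls) == 1 and calls[0].enrichment_factor == 10.0

    def test_reverse_strand_step_looks_downstream_in_coordinates(self):
        # on '-' the upstream neighbour is position + 1
        minus, plus = self.make_pair([0, 0, 0], [0, 10, 0], strand="-")
        calls = call_tss(minus, plus)
        assert [c.position for c in calls] == [2]
        minus, plus = self.make_pair([0, 0, 0], [0, 10, 9], strand="-")
        assert call_tss(minus, plus) == []

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            call_tss(track([0], treatment="minus_tex"), track([0, 1]))

    def test_keep_unenriched_records_flag(self):
        minus, plus = self.make_pair([0, 10, 0], [0, 20, 0])
        assert call_tss(minus, plus) == []
        calls = call_tss(minus, plus, keep_unenriched=True)
        assert len(calls) == 1 and not calls[0].enriched


class TestMergeClose:
    def test_pair_within_10_merges_to_higher(self):
        merged = merge_close([cand(100, 5.0), cand(105, 9.0)])
        assert [(c.position) for c in merged] == [105]

    def test_gap_of_exactly_10_stays_separate(self):
        merged = merge_close([cand(100, 5.0), cand(110, 9.0)])
        assert [c.position for c in merged] == [100, 110]

    def test_single_linkage_chain_collapses_to_max_height(self):
        merged = merge_close([cand(100, 5.0), cand(108, 9.0), cand(116, 4.0)])
        assert [c.position for c in merged] == [108]

    def test_tie_goes_most_upstream(self):
        assert merge_close([cand(100, 5.0), cand(105, 5.0)])[0].position == 100
        rev = [cand(100, 5.0, strand="-"), cand(105, 5.0, strand="-")]
        assert merge_close(rev)[0].position == 105

    @given(st.lists(st.tuples(st.integers(1, 500), st.floats(1, 100)), min_size=1, max_size=40))
    def test_merging_is_idempotent(self, raw):
        cands = [cand(p, h) for p, h in {p: h for p, h in raw}.items()]
        once = merge_close(cands)
        assert merge_close(once) == once


class TestConsensus:
    def test_tss_in_all_replicates_has_support_three(self):
        per_rep = [[cand(200, 5.0, replicate=r)] for r in (1, 2, 3)]
        records = replicate_consensus(per_rep)
        assert len(records) == 1 and records[0].support == 3
        assert records[0].average_coverage == pytest.approx(5.0)

    def test_cross_replicate_merge_rule(self):
        per_rep = [[cand(200, 5.0, replicate=1)], [cand(204, 9.0, replicate=2)],
                   [cand(260, 2.0, replicate=3)]]
        records = replicate_consensus(per_rep)
        assert [(r.position, r.support) for r in records] == [(204, 2), (260, 1)]

    def test_disjoint_candidates_keep_support_one(self):
        per_rep = [
            [cand(1000 * i, 5.0, replicate=1) for i in range(1, 4)],
            [cand(1000 * i + 500, 5.0, replicate=2) for i in range(1, 5)],
            [cand(10000 * i, 5.0, replicate=3) for i in range(2, 7)],
        ]
        records = replicate_consensus(per_rep)
        assert len(records) == 12
        assert all(r.support == 1 for r in records)

    def test_enriched_in_subset_of_detected_in(self):
        per_rep = [[cand(200, 5.0, replicate=1, enriched=False)], [cand(204, 9.0, replicate=2)]]
        (rec,) = replicate_consensus(per_rep)
        assert rec.enriched_in == frozenset({2})
        assert rec.detected_in == frozenset({1, 2})

    def test_support_counts_are_monotone(self, small_result):
        counts = support_counts(small_result.records)
        assert counts[">=1"] >= counts[">=2"] >= counts["==3"]
        assert counts[">=1"] == len(small_result.records)


def test_caller_recovers_planted_tss(small_result):
    """On well-expressed synthetic truth, the consensus set finds every
    planted primary TSS and calls nothing at TEX-neutral processed sites."""
    truth = small_result.truth
    by_strand = {"+": [], "-": []}
    for r in small_result.records:
        by_strand[r.strand].append(r.position)
    by_strand = {k: np.array(sorted(v)) for k, v in by_strand.items()}

    def called_near(position, strand):
        arr = by_strand[strand]
        return arr.size and np.min(np.abs(arr - position)) < 10

    recall = np.mean([called_near(t.position, t.strand) for t in truth])
    assert recall >= 0.9
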