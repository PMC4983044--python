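"""PWM construction, exact p-value thresholds, scanning, refinement, logos."""

import itertools

import numpy as np
import pytest

from drnatss.genome import GenomeModel
from drnatss.promoter import (
    Pwm,
    UpstreamSeq,
    build_pwm,
    extract_upstream,
    genome_background,
    logo_matrix,
    pvalue_threshold,
    refine_pwm,
    scan,
    score_distribution,
)
from drnatss.synthetic import make_upstream_set, random_sequence

UNIFORM = np.array([0.25] * 4)
GC67 = np.array([0.165, 0.335, 0.335, 0.165])


class TestExtractUpstream:
    def test_forward_strand_window(self, toy_genome):
        u = extract_upstream(toy_genome, "chr", 100, "+")
        assert u.sequence == toy_genome.sequences["chr"][29:100]
        assert len(u.sequence) == 71

    def test_reverse_strand_window_is_revcomp(self, toy_genome):
        from Bio.Seq import reverse_complement

        u = extract_upstream(toy_genome, "chr", 100, "-")
        assert u.sequence == reverse_complement(toy_genome.sequences["chr"][99:170])

    def test_tss_too_close_to_edge_skipped(self, toy_genome):
        assert extract_upstream(toy_genome, "chr", 50, "+") is None
        assert extract_upstream(toy_genome, "chr", 2940, "-") is None


class TestBackground:
    def test_uniform_genome_near_uniform(self):
        rng = np.random.default_rng(0)
        genome = GenomeModel({"chr": random_sequence(rng, 200_000, 0.5)})
        q = genome_background(genome)
        assert np.allclose(q, 0.25, atol=0.01)

    def test_gc_rich_genome(self, small_study):
        genome, _ = small_study
        q = genome_background(genome)
        assert 0.66 <= q[1] + q[2] <= 0.68

    def test_sums_to_one_and_strand_symmetric(self, toy_genome):
        q = genome_background(toy_genome)
        assert q.sum() == pytest.approx(1.0)
        assert q[0] == pytest.approx(q[3]) and q[1] == pytest.approx(q[2])


class TestBuildPwm:
    def test_identical_windows_zero_pseudocount(self):
        pwm = build_pwm(["ACGT"] * 8, UNIFORM, pseudocount=0.0)
        for j, base_index in enumerate([0, 1, 2, 3]):
            assert pwm.log_odds[base_index, j] == pytest.approx(2.0)
        off = pwm.log_odds[1, 0]
        assert np.isfinite(off) and off < -10  # guarded, not -inf

    def test_column_counts_sum_to_n(self):
        windows = ["ACG", "ATG", "GCG", "ACA"]
        pwm = build_pwm(windows, UNIFORM)
        assert np.allclose(pwm.counts.sum(axis=0), len(windows))

    def test_pseudocount_arithmetic(self):
        # 10 windows all 'A' in one column, pseudocount 0.5, uniform q:
        # log2((10.5/12)/0.25) = 1.8074
        pwm = build_pwm(["A"] * 10, UNIFORM, pseudocount=0.5)
        assert pwm.log_odds[0, 0] == pytest.approx(np.log2((10.5 / 12) / 0.25), abs=1e-6)
        assert pwm.log_odds[0, 0] == pytest.approx(1.807, abs=5e-4)

    def test_mismatched_widths_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACG", "AC"], UNIFORM)


def brute_force_threshold(pwm: Pwm, p: float, granularity: float = 1e-3) -> float:
    """Oracle: enumerate all 4^W windows, floor per-column scores to the
    grid, and take the smallest achievable score whose tail <= p."""
    grid = np.floor(pwm.log_odds / granularity).astype(np.int64)
    scores, probs = [], []
    for word in itertools.product(range(4), repeat=pwm.width):
        scores.append(sum(int(grid[b, j]) for j, b in enumerate(word)))
        probs.append(np.prod([pwm.background[b] for b in word]))
    scores, probs = np.array(scores), np.array(probs)
    probs = probs / probs.sum()
    passing = [u for u in np.unique(scores) if probs[scores >= u].sum() <= p * (1 + 1e-9)]
    t = min(passing) if passing else scores.max() + 1
    return t * granularity


class TestPvalueThreshold:
    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("p", [0.001, 0.01, 0.1, 0.5, 1.0])
    def test_dp_matches_enumeration(self, width, p):
        rng = np.random.default_rng(width)
        counts = rng.multinomial(30, [0.25] * 4, size=width).T.astype(float)
        q = rng.dirichlet([5.0] * 4)
        pwm = Pwm(counts, q, 0.5)
        assert pvalue_threshold(pwm, p) == pytest.approx(brute_force_threshold(pwm, p), abs=1e-9)

    def test_width_one_closed_form(self):
        pwm = Pwm(np.ones((4, 1)), UNIFORM, 0.5)
        pwm.log_odds = np.array([[2.0], [-1.0], [-1.0], [-1.0]])
        assert pvalue_threshold(pwm, 0.25) == pytest.approx(2.0)

    def test_p_to_one_gives_minimal_achievable_score(self):
        pwm = build_pwm(["ACG", "TTG", "GCA"], GC67)
        base, dist = score_distribution(pwm)
        minimal = (base + int(np.nonzero(dist > 0)[0][0])) * 1e-3
        assert pvalue_threshold(pwm, 1.0) == pytest.approx(minimal)

    def test_threshold_monotone_in_p(self):
        rng = np.random.default_rng(3)
        counts = rng.multinomial(40, [0.25] * 4, size=12).T.astype(float)
        pwm = Pwm(counts, GC67, 0.5)
        thresholds = [pvalue_threshold(pwm, p) for p in (0.001, 0.01, 0.1, 0.5)]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_degenerate_background_rejected(self):
        pwm = build_pwm(["AC", "AG"], UNIFORM)
        pwm.background = np.array([0.5, 0.5, 0.0, 0.0])
        with pytest.raises(ValueError):
            pvalue_threshold(pwm, 0.01)


class TestScan:
    def test_planted_consensus_found_at_offset(self):
        rng = np.random.default_rng(8)
        pwm = build_pwm(["CGAAATTAT"] * 20, GC67)
        seq = random_sequence(rng, 71, 0.67)
        seq = seq[:20] + "CGAAATTAT" + seq[29:]
        score, offset = scan(pwm, seq, threshold=-1e9)
        assert offset == 20
        assert score == pytest.approx(pwm.log_odds.max(axis=0).sum())

    def test_score_additivity(self):
        rng = np.random.default_rng(9)
        windows = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(10)]
        pwm = build_pwm(windows, UNIFORM)
        seq = random_sequence(rng, 30, 0.5)
        score, offset = scan(pwm, seq, threshold=-1e9)
        from drnatss.genome import BASE_INDEX

        manual = sum(pwm.log_odds[BASE_INDEX[b], j] for j, b in enumerate(seq[offset : offset + 6]))
        assert score == pytest.approx(manual)

    def test_sequence_shorter_than_pwm_rejected(self):
        pwm = build_pwm(["ACGTACGT"] * 3, UNIFORM)
        with pytest.raises(ValueError):
            scan(pwm, "ACG", 0.0)

    def test_background_hit_fraction_bounded_by_union_bound(self):
        """At the p = 0.001 threshold, <= ~44 x 0.001 of random 71-mers can
        contain a hit (union bound over the 44 offsets), observed within
        binomial error."""
        seqs, _ = make_upstream_set(1000, 0.0, seed=17)
        windows, _ = make_upstream_set(300, 1.0, seed=18)
        pwm = build_pwm([w[37:65] for w in windows], GC67)
        threshold = pvalue_threshold(pwm, 0.001)
        hits = sum(scan(pwm, s, threshold) is not None for s in seqs)
        assert hits / len(seqs) <= 0.044 + 3 * np.sqrt(0.044 * 0.956 / 1000)


class TestRefine:
    def test_planted_motif_recovered(self):
        seqs, planted = make_upstream_set(500, 0.8, seed=4)
        ups = [UpstreamSeq(f"u{i}", s) for i, s in enumerate(seqs)]
        result = refine_pwm(ups, GC67)
        assert result.converged
        consensus = result.pwm.consensus
        motif = "CGAAATTAT"
        best = max(
            sum(a == b for a, b in zip(motif, consensus[o : o + len(motif)]))
            for o in range(len(consensus) - len(motif) + 1)
        )
        assert best >= 7
        recall = np.mean([f"u{i}" in result.positives for i in np.nonzero(planted)[0]])
        assert recall >= 0.7

    def test_fixed_point_converges_in_one_iteration(self):
        # jitter-free planted set: the initial alignment is already the
        # refined alignment, so the first rescan reproduces it exactly
        seqs, _ = make_upstream_set(150, 1.0, seed=6, jitter_range=0)
        ups = [UpstreamSeq(f"u{i}", s) for i, s in enumerate(seqs)]
        result = refine_pwm(ups, GC67)
        assert result.converged and result.n_iterations == 1
        assert set(result.positives.values()) == {25}

    def test_pure_noise_terminates(self):
        seqs, _ = make_upstream_set(120, 0.0, seed=12)
        ups = [UpstreamSeq(f"u{i}", s) for i, s in enumerate(seqs)]
        try:
            result = refine_pwm(ups, GC67, max_iter=60)
        except Exception as err:  # degenerate motif is an acceptable outcome
            from drnatss.promoter import DegenerateMotifError

            assert isinstance(err, DegenerateMotifError)
        else:
            assert result.n_iterations <= 60

    def test_refinement_deterministic(self):
        seqs, _ = make_upstream_set(200, 0.7, seed=13)
        ups = [UpstreamSeq(f"u{i}", s) for i, s in enumerate(seqs)]
        a = refine_pwm(ups, GC67)
        b = refine_pwm(ups, GC67)
        assert a.positives == b.positives
        assert a.n_iterations == b.n_iterations
        assert np.array_equal(a.pwm.counts, b.pwm.counts)


class TestClassifyPromoters:
    def test_stringent_threshold_at_least_relaxed(self, small_result):
        assert small_result.t_stringent >= small_result.t_relaxed

    def test_classes_respect_thresholds(self, small_result):
        for call in small_result.promoter_calls:
            if call.promoter_class == "none":
                assert call.score is None or call.score < small_result.t_relaxed
            elif call.promoter_class == "relaxed":
                assert small_result.t_relaxed <= call.score < small_result.t_stringent
            else:
                assert call.score >= small_result.t_stringent

    def test_planted_fraction_recovered(self, small_result, small_config):
        fractions = small_result.promoter_class_fractions()
        assert 0.4 <= fractions["stringent"] <= 0.6


class TestLogo:
    def test_pure_column_carries_two_bits(self):
        contrib, info = logo_matrix(["A", "A", "A", "A"], UNIFORM)
        assert info[0] == pytest.approx(2.0)
        assert contrib[0, 0] == pytest.approx(2.0)

    def test_background_frequencies_carry_no_information(self):
        contrib, info = logo_matrix(["A", "C", "G", "T"], UNIFORM)
        assert info[0] == pytest.approx(0.0, abs=1e-12)

    def test_negative_contribution_iff_rarer_than_background(self):
        windows = ["AA", "AC", "AG", "AT"]  # col 2: each base at 0.25
        contrib, info = logo_matrix(windows, GC67)
        # A at f=0.25 > q=0.165 -> positive; C at 0.25 < 0.335 -> negative
        assert contrib[0, 1] > 0 > contrib[1, 1]
        assert (info >= 0).all()
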