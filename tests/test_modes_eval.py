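"""Calibration, SNR, E range, both alignment modes and the altered flag."""

import numpy as np
import pytest

from epialign import (
    EpiRegion,
    GenomicInterval,
    ScoringParams,
    build_score_tables,
    calibrate,
    compute_snr,
    dinucleotide_shuffle,
    e_range,
    epialign,
    many_vs_many,
    one_vs_one,
    reference_score_ranges,
)

from conftest import (
    make_hit_shift_fixture,
    mutate_to_identity,
    random_region,
    span_overlap,
)


class TestCalibration:
    def test_per_kilobase_rule(self):
        assert calibrate(50, 100) == 500
        assert calibrate(12.5, 1000) == 12.5
        assert calibrate(0, 123) == 0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            calibrate(10, 0)


class TestERange:
    def test_all_zero_and_all_one_vectors(self, default_params):
        lo, hi = e_range(np.zeros(10, dtype=int), default_params)
        assert hi == 10 * default_params.epi_match0
        assert lo == 10 * default_params.epi_mismatch
        lo, hi = e_range(np.ones(10, dtype=int), default_params)
        assert hi == 10 * default_params.epi_match1
        assert lo == 10 * default_params.epi_mismatch

    def test_mixed_vector_arithmetic(self, default_params):
        states = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        lo, hi = e_range(states, default_params)
        assert hi == pytest.approx(3 * 2 + 7 * 0.2)
        assert lo == pytest.approx(-20.0)

    def test_non_binary_rejected(self, default_params):
        with pytest.raises(ValueError, match="binary"):
            e_range(np.array([0, 1, 2]), default_params)

    def test_bounds_any_gap_free_full_query_alignment(self, default_params):
        rng = np.random.default_rng(4)
        tables = build_score_tables(default_params)
        for _ in range(10):
            q = random_region(rng, 15)
            t = random_region(rng, 15)
            # gap-free overlay: E of the diagonal path
            E = sum(tables.epi[q.states[i], t.states[i]] for i in range(15))
            lo, hi = e_range(q.states, default_params)
            assert lo - 1e-9 <= E <= hi + 1e-9


class TestSnr:
    def test_tandem_repeat_target_scores_like_background(self, default_tables):
        rng = np.random.default_rng(42)
        unit = "".join(rng.choice(list("ACGT"), 200))
        q = EpiRegion(GenomicInterval("q", 0, 200), unit, np.zeros(200, int))
        t = EpiRegion(
            GenomicInterval("t", 0, 4000), unit * 20, np.zeros(4000, int)
        )
        tables0 = default_tables.with_weight(0.0)
        aln, _ = epialign(q, t, tables0)
        snr = compute_snr(q, t, aln, tables0, seed=1)
        assert snr.value == pytest.approx(1.0, abs=0.2)

    def test_planted_copy_stands_out(self, default_tables):
        rng = np.random.default_rng(43)
        qseq = "".join(rng.choice(list("ACGT"), 200))
        bg = list(rng.choice(list("ACGT"), 2000))
        bg[900:1100] = list(qseq)
        q = EpiRegion(GenomicInterval("q", 0, 200), qseq, np.zeros(200, int))
        t = EpiRegion(GenomicInterval("t", 0, 2000), "".join(bg), np.zeros(2000, int))
        tables0 = default_tables.with_weight(0.0)
        aln, _ = epialign(q, t, tables0)
        snr = compute_snr(q, t, aln, tables0, seed=2)
        assert float(snr) > 1.5

    def test_target_shorter_than_query_rejected(self, default_tables):
        rng = np.random.default_rng(44)
        q = random_region(rng, 50)
        t = random_region(rng, 30)
        aln, _ = epialign(q, t, default_tables)
        with pytest.raises(ValueError, match="shorter than query"):
            compute_snr(q, t, aln, default_tables)

    def test_seeded_reproducibility(self, default_tables):
        rng = np.random.default_rng(45)
        q = random_region(rng, 40)
        t = random_region(rng, 500)
        aln, _ = epialign(q, t, default_tables)
        a = compute_snr(q, t, aln, default_tables, seed=7)
        b = compute_snr(q, t, aln, default_tables, seed=7)
        assert a.value == b.value and a.background == b.background


class TestOneVsOne:
    def test_w0_run_collapses_the_two_hits(self):
        rng = np.random.default_rng(8)
        pairs = [(random_region(rng, 30), random_region(rng, 80))]
        (out,) = one_vs_one(pairs, ScoringParams(w=0.0), seed=0)
        assert out.epi_aln is out.seq_aln
        assert out.hits_overlap
        assert out.T_epi == out.S_seq

    def test_contained_query_identical_states_found_by_both(self):
        rng = np.random.default_rng(9)
        m = 50
        q = random_region(rng, m, states=np.ones(m, int))
        tseq = (
            "".join(rng.choice(list("ACGT"), 60))
            + q.seq
            + "".join(rng.choice(list("ACGT"), 60))
        )
        tstates = np.concatenate([np.zeros(60, int), q.states, np.zeros(60, int)])
        t = EpiRegion(GenomicInterval("t", 0, len(tseq)), tseq, tstates)
        (out,) = one_vs_one([(q, t)], ScoringParams(), seed=0)
        for aln in (out.epi_aln, out.seq_aln):
            assert (aln.target_hit.start, aln.target_hit.end) == (60, 110)
        assert out.hits_overlap

    def test_decomposition_identities_hold_exactly(self):
        rng = np.random.default_rng(10)
        pairs = [
            (random_region(rng, 25), random_region(rng, 70)) for _ in range(5)
        ]
        for out in one_vs_one(pairs, ScoringParams(), seed=3):
            assert out.E_epi == pytest.approx(out.T_epi - out.S_epi, abs=1e-9)
            assert out.E_seq == pytest.approx(out.T_seq - out.S_seq, abs=1e-9)

    def test_hit_shift_pattern(self):
        """A conserved signal-free locus wins on sequence; with enough
        epigenome weight the hit moves to the diverged locus carrying the
        matching signal, and the two hits no longer overlap."""
        query, target, span_a, span_b = make_hit_shift_fixture(seed=1)
        shifted_at = None
        for w in np.arange(0.01, 0.31, 0.01):
            (out,) = one_vs_one([(query, target)], ScoringParams(w=float(w)),
                                with_snr=False)
            seq_hit = out.seq_aln.target_hit
            assert span_overlap(seq_hit, span_a) > span_overlap(seq_hit, span_b)
            epi_hit = out.epi_aln.target_hit
            if span_overlap(epi_hit, span_b) > span_overlap(epi_hit, span_a):
                shifted_at = float(w)
                assert not out.hits_overlap
                break
        assert shifted_at is not None and 0 < shifted_at <= 0.3

    def test_no_cross_pair_leakage(self):
        rng = np.random.default_rng(12)
        pairs = [(random_region(rng, 30), random_region(rng, 90)) for _ in range(3)]
        batch = one_vs_one(pairs, ScoringParams(), with_snr=False)
        solo = one_vs_one([pairs[1]], ScoringParams(), with_snr=False)[0]
        assert batch[1].T_epi == solo.T_epi
        assert batch[1].S_seq == solo.S_seq
        assert batch[1].T_epi_per_kb == solo.T_epi_per_kb


class TestManyVsMany:
    def _exact_copy_setup(self):
        rng = np.random.default_rng(14)
        q = random_region(rng, 40, chrom="q0", states=np.ones(40, int))
        t1 = EpiRegion(GenomicInterval("t1", 0, 40, "+", "t1"), q.seq, q.states.copy())
        t2 = random_region(rng, 60, chrom="t2")
        return q, t1, t2

    def test_exact_copy_dominates_both_matrices(self):
        q, t1, t2 = self._exact_copy_setup()
        matrices, (out,) = many_vs_many([q], [t1, t2], ScoringParams(), with_snr=False)
        assert np.argmax(matrices.epi_scores[0]) == 0
        assert np.argmax(matrices.seq_scores[0]) == 0
        assert not out.altered

    def test_matrix_shape_and_labels(self):
        rng = np.random.default_rng(15)
        queries = [random_region(rng, 20, chrom=f"q{i}") for i in range(2)]
        targets = [random_region(rng, 50, chrom=f"t{j}") for j in range(3)]
        matrices, outcomes = many_vs_many(
            queries, targets, ScoringParams(), with_snr=False
        )
        assert matrices.epi_scores.shape == (2, 3)
        assert matrices.seq_scores.shape == (2, 3)
        assert matrices.epi_frame().shape == (2, 3)
        assert len(outcomes) == 2

    def test_empty_lists_rejected(self):
        rng = np.random.default_rng(16)
        q = random_region(rng, 10)
        with pytest.raises(ValueError, match="non-empty"):
            many_vs_many([], [q], ScoringParams())
        with pytest.raises(ValueError, match="non-empty"):
            many_vs_many([q], [], ScoringParams())

    def test_altered_hit_fixture(self):
        """Anti-matching states at the conserved target, matching states at
        the diverged one: the epi hit moves while the epigenome term is
        positive there and negative at the sequence-only hit."""
        rng = np.random.default_rng(5)
        L = 200
        qseq = "".join(rng.choice(list("ACGT"), L))
        q = EpiRegion(GenomicInterval("q", 0, L, "+", "q0"), qseq, np.ones(L, int))

        def make_target(name, identity, with_signal):
            fl = "".join(rng.choice(list("ACGT"), 100))
            fr = "".join(rng.choice(list("ACGT"), 100))
            core = mutate_to_identity(qseq, identity, rng)
            seq = fl + core + fr
            st = np.zeros(len(seq), int)
            if with_signal:
                st[100 : 100 + L] = 1
            return EpiRegion(GenomicInterval(name, 0, len(seq), "+", name), seq, st)

        t_a = make_target("tA", 0.95, with_signal=False)
        t_b = make_target("tB", 0.85, with_signal=True)
        altered_w = None
        for w in np.arange(0.02, 0.32, 0.02):
            _, (out,) = many_vs_many(
                [q], [t_a, t_b], ScoringParams(w=float(w)), with_snr=False
            )
            if out.altered:
                altered_w = float(w)
                assert out.epi_target_index == 1
                assert out.seq_target_index == 0
                assert out.T_epi > out.S_epi
                assert out.T_seq < out.S_seq
                break
        assert altered_w is not None

    def test_self_alignment_dominates_identity_matrix(self):
        rng = np.random.default_rng(17)
        regions = [random_region(rng, 60, chrom=f"r{i}") for i in range(4)]
        _, outcomes = many_vs_many(
            regions, regions, ScoringParams(w=0.0), with_snr=False
        )
        for i, out in enumerate(outcomes):
            assert out.seq_target_index == i

    def test_monotone_weight_when_epi_term_nonnegative(self):
        query, target, _, _ = make_hit_shift_fixture(seed=2)
        prev_T, prev_E = None, None
        for w in np.arange(0.0, 0.31, 0.03):
            (out,) = one_vs_one([(query, target)], ScoringParams(w=float(w)) if w > 0
                                else ScoringParams(w=0.0), with_snr=False)
            if prev_T is not None and prev_E >= 0:
                assert out.T_epi >= prev_T - 1e-9
            prev_T, prev_E = out.T_epi, out.epi_aln.E


class TestReferenceRanges:
    def test_dinucleotide_shuffle_preserves_composition(self):
        rng = np.random.default_rng(18)
        seq = "".join(rng.choice(list("ACGT"), 300))
        shuffled = dinucleotide_shuffle(seq, rng)
        assert shuffled != seq

        def dinucs(s):
            from collections import Counter

            return Counter(zip(s, s[1:]))

        assert dinucs(shuffled) == dinucs(seq)
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]

    def test_homologous_range_exceeds_random_range(self):
        rng = np.random.default_rng(19)
        q = random_region(rng, 150)
        t = random_region(rng, 500)
        ranges = reference_score_ranges(q, t, ScoringParams(), n=5, seed=3)
        assert ranges["homologous"][0] > ranges["random"][1]
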