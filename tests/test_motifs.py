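import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ciskit import (BackgroundModel, CiskitError, DNATrack, GenomicSequence,
                    Motif, SequenceSet, match_consensus, motif_from_sites,
                    pwm_score_profile, reverse_complement, sample_background,
                    scan_motifs, train_background)
from ciskit.motifs import relative_score_params


def one_seq(s, name="s1"):
    seqs = SequenceSet([GenomicSequence(name, name, 0, len(s))])
    return DNATrack(seqs, {name: s})


def naive_scan(seq: str, motif: Motif, threshold: float, q=None):
    """Independent O(L*w) re-implementation of the scanner."""
    q = q if q is not None else np.full(4, 0.25)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.maximum(motif.matrix, 1e-9)
    lo = np.log(m / q[:, None])
    smin = sum(min(lo[b, j] for b in range(4)) for j in range(motif.width))
    smax = sum(max(lo[b, j] for b in range(4)) for j in range(motif.width))
    hits = []
    for i in range(len(seq) - motif.width + 1):
        for strand in "+-":
            window = seq[i:i + motif.width].upper()
            if strand == "-":
                window = reverse_complement(window)
            s = 0.0
            for j, c in enumerate(window):
                if c in idx:
                    s += lo[idx[c], j]
            r = (s - smin) / (smax - smin)
            if r >= threshold:
                hits.append((i, strand, r))
    return hits


class TestBackground:
    def test_order0_counts_with_pseudocount(self):
        bg = train_background(one_seq("AACC"), 0)
        assert np.allclose(bg.order0, [0.375, 0.375, 0.125, 0.125])

    def test_order1_conditional_monotonic(self):
        bg = train_background(one_seq("AAAA"), 1)
        cond = bg.conditional("A")
        assert cond[0] == cond.max()

    def test_conditionals_sum_to_one(self):
        bg = train_background(one_seq("ACGTACGTGGTTAACC"), 2)
        for table in bg.tables:
            for p in table.values():
                assert abs(p.sum() - 1) < 1e-9
                assert np.all(p > 0)

    def test_empty_input_rejected(self):
        with pytest.raises(CiskitError):
            BackgroundModel(7, [])

    def test_sampled_kmer_frequencies_track_model(self):
        # train order 1 on skewed text, sample long string, compare 2-mer freq
        bg = train_background(one_seq("AAAC" * 200), 1)
        s = sample_background(bg, 100_000, seed=5)
        # P(A|A) from the model vs the empirical estimate
        from_model = bg.conditional("A")[0]
        aa = sum(1 for i in range(len(s) - 1) if s[i] == "A" and s[i + 1] == "A")
        a_total = sum(1 for i in range(len(s) - 1) if s[i] == "A")
        empirical = aa / a_total
        se = np.sqrt(from_model * (1 - from_model) / a_total)
        assert abs(empirical - from_model) < 3 * se + 1e-9

    def test_sampling_deterministic(self):
        bg = train_background(one_seq("ACGT" * 10), 0)
        assert sample_background(bg, 50, 9) == sample_background(bg, 50, 9)

    def test_degenerate_model_sampling(self):
        bg = BackgroundModel(0, [{"": np.array([1 - 3e-12, 1e-12, 1e-12, 1e-12])}])
        assert sample_background(bg, 5, 1) == "AAAAA"


class TestScanning:
    def test_single_column_motif_both_strands(self):
        motif = Motif("A1", np.array([[1.0], [0.0], [0.0], [0.0]]))
        track = scan_motifs(one_seq("ATA"), [motif], 1.0)
        hits = sorted((r.start, r.strand) for r in track["s1"])
        assert hits == [(0, "+"), (1, "-"), (2, "+")]

    def test_threshold_zero_hits_everywhere(self):
        motif = motif_from_sites(["ACG"] * 5, "m")
        dna = one_seq("ACGTACGT")
        track = scan_motifs(dna, [motif], 0.0)
        assert len(track["s1"]) == 2 * (8 - 3 + 1)

    def test_forward_only(self):
        motif = Motif("A1", np.array([[1.0], [0.0], [0.0], [0.0]]))
        track = scan_motifs(one_seq("ATA"), [motif], 1.0, strands="forward")
        assert sorted((r.start, r.strand) for r in track["s1"]) == [(0, "+"), (2, "+")]

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_scanner_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 200))
        counts = rng.integers(0, 20, size=(4, int(rng.integers(4, 9)))) + 1.0
        motif = Motif("m", counts / counts.sum(axis=0))
        track = scan_motifs(one_seq(seq), [motif], 0.8)
        got = sorted((r.start, r.strand, round(r.score, 9)) for r in track["s1"])
        expected = sorted((i, s, round(r, 9)) for i, s, r in naive_scan(seq, motif, 0.8))
        assert got == expected

    def test_strand_symmetry(self):
        rng = np.random.default_rng(44)
        seq = "".join(rng.choice(list("ACGT"), 80))
        counts = rng.integers(1, 15, size=(4, 6)).astype(float)
        motif = Motif("m", counts / counts.sum(axis=0))
        fwd = scan_motifs(one_seq(seq), [motif], 0.7)
        rev = scan_motifs(one_seq(reverse_complement(seq)), [motif], 0.7)
        n = len(seq)
        mirrored = sorted((n - r.end, {"+": "-", "-": "+"}[r.strand],
                           round(r.score, 9)) for r in rev["s1"])
        assert mirrored == sorted((r.start, r.strand, round(r.score, 9))
                                  for r in fwd["s1"])

    def test_relative_score_invariant_to_column_scaling(self):
        counts = np.array([[8, 1], [1, 8], [1, 1], [1, 1]], dtype=float).T.copy()
        counts = counts.T
        m1 = Motif("a", counts / counts.sum(axis=0))
        # multiplying all columns by a constant before normalization is a no-op
        m2 = Motif("b", (5 * counts) / (5 * counts).sum(axis=0))
        _, s1min, s1max = relative_score_params(m1)
        _, s2min, s2max = relative_score_params(m2)
        assert s1min == pytest.approx(s2min) and s1max == pytest.approx(s2max)

    def test_unknown_bases_score_background(self):
        motif = motif_from_sites(["AC"] * 10, "m")
        profile_with_n = pwm_score_profile(one_seq("NC"), motif)
        # N contributes 0 to the log-odds sum
        lo, smin, smax = relative_score_params(motif)
        expected = (lo[1, 1] - smin) / (smax - smin)
        assert profile_with_n["s1"][0] == pytest.approx(expected)


class TestConsensusMatching:
    def test_ccaat_both_orientations(self):
        track = match_consensus(one_seq("ACCAATG"), "CCAAT")
        assert [(r.start, r.end, r.strand) for r in track["s1"]] == [(1, 6, "+")]
        rev = match_consensus(one_seq("AATTGGC"), "CCAAT")
        assert [(r.start, r.end, r.strand) for r in rev["s1"]] == [(1, 6, "-")]

    def test_n_matches_everything_once(self):
        track = match_consensus(one_seq("ACGT"), "N")
        assert len(track["s1"]) == 4
        assert all(r.strand == "+" for r in track["s1"])

    def test_no_match_empty(self):
        assert match_consensus(one_seq("AAAA"), "CCC").count() == 0

    def test_invalid_iupac_rejected(self):
        with pytest.raises(CiskitError):
            match_consensus(one_seq("ACGT"), "QQ")


class TestMotifConstruction:
    def test_pseudocount_arithmetic(self):
        m = motif_from_sites(["AA", "AA"], "m")
        assert m.matrix[0, 0] == pytest.approx(2.25 / 3)

    def test_single_site_consensus(self):
        assert motif_from_sites(["ACGT"], "m").consensus == "ACGT"

    def test_ragged_rejected(self):
        with pytest.raises(CiskitError):
            motif_from_sites(["AC", "ACG"], "m")


class TestScoreProfile:
    def test_profile_max_equals_best_hit(self):
        rng = np.random.default_rng(10)
        seq = "".join(rng.choice(list("ACGT"), 120))
        counts = rng.integers(1, 15, size=(4, 5)).astype(float)
        motif = Motif("m", counts / counts.sum(axis=0))
        profile = pwm_score_profile(one_seq(seq), motif)
        track = scan_motifs(one_seq(seq), [motif], 0.0)
        best = max(r.score for r in track["s1"])
        assert profile["s1"].max() == pytest.approx(best)

    def test_uniform_motif_degenerate(self):
        motif = Motif("u", np.full((4, 3), 0.25))
        profile = pwm_score_profile(one_seq("ACGTACGT"), motif)
        assert np.array_equal(profile["s1"], np.zeros(8))

    def test_consensus_window_scores_one(self):
        motif = motif_from_sites(["ACGTT"] * 30, "m")
        profile = pwm_score_profile(one_seq("ACGTT"), motif)
        assert profile["s1"][0] == pytest.approx(1.0)
        assert np.all(profile["s1"][1:] == 0)  # trailing w-1 positions
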