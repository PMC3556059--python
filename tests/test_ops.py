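import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ciskit import (AvgWithin, CiskitError, DNATrack, GenomicSequence, Inside,
                    NumericMap, NumericTrack, Overlaps, Region, RegionTrack,
                    SequenceSet, TrueCondition, arithmetic, collection_from_map,
                    combine_tracks, eval_condition, extend_regions,
                    filter_regions, mask, merge_regions, numeric_to_regions,
                    parse_condition, regions_to_numeric, sequence_statistic,
                    sliding_window, train_background)


def one_seq(length=10, name="s1"):
    return SequenceSet([GenomicSequence(name, name, 0, length)])


class TestConditions:
    def test_inside_at_position(self):
        seqs = one_seq(5)
        track = RegionTrack(seqs, {"s1": [Region(1, 3, "rep")]})
        cond = Inside(track)
        assert eval_condition(cond, {}, "s1", 1) is True
        assert eval_condition(cond, {}, "s1", 3) is False

    def test_avg_within_region(self):
        seqs = one_seq(4)
        cons = NumericTrack(seqs, {"s1": [0.2, 0.4, 0.9, 0.9]})
        cond = AvgWithin(cons, "<", 0.5)
        assert eval_condition(cond, {}, "s1", Region(0, 2)) is True
        assert eval_condition(cond, {}, "s1", Region(2, 4)) is False

    def test_boolean_combinators(self):
        t, f = TrueCondition(), ~TrueCondition()
        assert eval_condition(~(t & f), {}, "s1", 0) is True
        assert eval_condition(t | f, {}, "s1", 0) is True

    def test_context_mismatch_is_error(self):
        seqs = one_seq(5)
        track = RegionTrack(seqs, {"s1": [Region(1, 3)]})
        with pytest.raises(CiskitError):
            eval_condition(Overlaps(track), {}, "s1", 2)  # region pred at position

    def test_parse_concrete_syntax(self):
        seqs = one_seq(4)
        cons = NumericTrack(seqs, {"s1": [0.9, 0.9, 0.1, 0.1]})
        reps = RegionTrack(seqs, {"s1": [Region(2, 4, "rep")]})
        env = {"conservation": cons, "repeats": reps}
        cond = parse_condition("avg(conservation) >= 0.3 and not overlaps(repeats)")
        assert eval_condition(cond, env, "s1", Region(0, 2)) is True
        assert eval_condition(cond, env, "s1", Region(2, 4)) is False

    def test_parse_error_reported(self):
        with pytest.raises(CiskitError):
            parse_condition("avg(conservation >= 0.3")


class TestMask:
    def test_letter_fill_on_interval(self):
        seqs = one_seq(4)
        dna = DNATrack(seqs, {"s1": "ACGT"})
        where = RegionTrack(seqs, {"s1": [Region(1, 3)]})
        assert mask(dna, "N", where)["s1"] == "ANNT"

    def test_repeat_masking_changes_exactly_covered_bases(self):
        seqs = one_seq(30)
        rng = np.random.default_rng(0)
        dna = DNATrack(seqs, {"s1": "".join(rng.choice(list("ACGT"), 30))})
        reps = RegionTrack(seqs, {"s1": [Region(3, 9), Region(15, 20)]})
        out = mask(dna, "N", reps)
        changed = [i for i in range(30) if out["s1"][i] != dna["s1"][i]]
        covered = [i for i in range(30) if 3 <= i < 9 or 15 <= i < 20]
        assert out["s1"].count("N") == 11
        assert set(changed) <= set(covered)

    def test_background_fill_deterministic(self):
        seqs = one_seq(20)
        dna = DNATrack(seqs, {"s1": "A" * 20})
        bg = train_background(dna, 0)
        where = RegionTrack(seqs, {"s1": [Region(0, 20)]})
        a = mask(dna, bg, where, seed=11)
        b = mask(dna, bg, where, seed=11)
        assert a == b
        with pytest.raises(CiskitError):
            mask(dna, bg, where)  # missing seed

    def test_input_not_mutated(self):
        seqs = one_seq(4)
        dna = DNATrack(seqs, {"s1": "ACGT"})
        mask(dna, "N", RegionTrack(seqs, {"s1": [Region(0, 4)]}))
        assert dna["s1"] == "ACGT"


class TestRegionOps:
    def test_filter_true_keeps_all(self, seqs, region_track):
        out = filter_regions(region_track, TrueCondition())
        assert out == region_track

    def test_filter_by_overlap_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        seqs = one_seq(200)
        answer = RegionTrack(seqs, {"s1": [Region(30, 45, "ans"), Region(90, 100, "ans")]})
        preds = [Region(int(a), int(a) + 8, "p") for a in rng.integers(0, 192, 30)]
        track = RegionTrack(seqs, {"s1": preds})
        out = filter_regions(track, Overlaps(answer))
        expected = [r for r in track["s1"]
                    if any(r.start < t.end and t.start < r.end
                           for t in answer["s1"])]
        assert [(r.start, r.end) for r in out["s1"]] == \
               [(r.start, r.end) for r in expected]

    def test_extend_plain_and_strand_aware(self):
        seqs = one_seq(100)
        t = RegionTrack(seqs, {"s1": [Region(10, 20, "x", 0, "-")]})
        plain = extend_regions(t, up=5, down=3)
        assert (plain["s1"][0].start, plain["s1"][0].end) == (5, 23)
        aware = extend_regions(t, up=5, down=3, strand_aware=True)
        assert (aware["s1"][0].start, aware["s1"][0].end) == (7, 25)

    def test_extend_clips_at_bounds(self):
        seqs = one_seq(15)
        t = RegionTrack(seqs, {"s1": [Region(2, 14)]})
        out = extend_regions(t, up=5, down=5)
        assert (out["s1"][0].start, out["s1"][0].end) == (0, 15)

    def test_merge_overlapping(self):
        seqs = one_seq(20)
        t = RegionTrack(seqs, {"s1": [Region(0, 5, "A", 0.2), Region(3, 8, "A", 0.9)]})
        out = merge_regions(t, 0)
        m = out["s1"][0]
        assert (m.start, m.end, m.score, m.type) == (0, 8, 0.9, "A")

    def test_merge_idempotent(self):
        rng = np.random.default_rng(1)
        seqs = one_seq(300)
        regions = [Region(int(a), int(a) + int(w), "x")
                   for a, w in zip(rng.integers(0, 280, 40), rng.integers(1, 20, 40))]
        t = RegionTrack(seqs, {"s1": regions})
        once = merge_regions(t, 2)
        twice = merge_regions(once, 2)
        assert once == twice


class TestNumericOps:
    def test_add_and_range_normalize(self):
        seqs = one_seq(3)
        t = NumericTrack(seqs, {"s1": [0, 1, 2]})
        assert np.array_equal(arithmetic(t, "add", 1)["s1"], [1, 2, 3])
        t2 = NumericTrack(seqs, {"s1": [2, 4, 6]})
        assert np.array_equal(arithmetic(t2, "range_normalize", target=(0, 1))["s1"],
                              [0, 0.5, 1])

    def test_mul_by_numeric_map_broadcasts_per_sequence(self):
        seqs = one_seq(2)
        t = NumericTrack(seqs, {"s1": [1, 2]})
        out = arithmetic(t, "mul", NumericMap("sequence", {"s1": 2.0}))
        assert np.array_equal(out["s1"], [2, 4])

    def test_log_domain_error_names_position(self):
        seqs = one_seq(3)
        t = NumericTrack(seqs, {"s1": [1.0, -1.0, 2.0]})
        with pytest.raises(CiskitError, match="s1.*position 1"):
            arithmetic(t, "log")

    def test_sliding_window_mean_edges_clipped(self):
        seqs = one_seq(3)
        t = NumericTrack(seqs, {"s1": [0, 3, 6]})
        assert np.allclose(sliding_window(t, "mean", 3)["s1"], [1.5, 3, 4.5])

    def test_sliding_window_max_bruteforce(self):
        seqs = one_seq(4)
        t = NumericTrack(seqs, {"s1": [1, 0, 0, 2]})
        assert np.array_equal(sliding_window(t, "max", 3)["s1"], [1, 1, 2, 2])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_sliding_window_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        size = int(rng.choice([1, 3, 5, 9]))
        seqs = one_seq(n)
        t = NumericTrack(seqs, {"s1": rng.normal(size=n)})
        out = sliding_window(t, "mean", size)["s1"]
        half = size // 2
        brute = [np.mean(t["s1"][max(0, i - half):min(n, i + half + 1)])
                 for i in range(n)]
        assert np.allclose(out, brute)

    def test_even_window_rejected(self):
        seqs = one_seq(3)
        t = NumericTrack(seqs, {"s1": [0, 1, 2]})
        with pytest.raises(CiskitError):
            sliding_window(t, "mean", 2)

    def test_combine_tracks(self):
        seqs = one_seq(2)
        a = NumericTrack(seqs, {"s1": [0, 1]})
        b = NumericTrack(seqs, {"s1": [1, 0]})
        assert np.array_equal(combine_tracks([a, b], [1, 0])["s1"], [0, 1])
        assert np.array_equal(combine_tracks([a, b], [0.5, 0.5])["s1"], [0.5, 0.5])
        c = NumericTrack(seqs, {"s1": [2, 2]})
        out = combine_tracks([a, b, c], [0.2, 0.3, 0.5])["s1"]
        assert np.allclose(out, 0.2 * a["s1"] + 0.3 * b["s1"] + 0.5 * c["s1"])


class TestTrackConversions:
    def test_runs_to_regions(self):
        seqs = one_seq(4)
        t = NumericTrack(seqs, {"s1": [0, 1, 1, 0]})
        out = numeric_to_regions(t, 1.0)
        assert [(r.start, r.end) for r in out["s1"]] == [(1, 3)]
        empty = numeric_to_regions(NumericTrack(seqs, {"s1": [0, 0, 0, 0]}), 1.0)
        assert empty.count() == 0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_runs_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        seqs = one_seq(n)
        v = rng.integers(0, 3, n).astype(float)
        t = NumericTrack(seqs, {"s1": v})
        out = numeric_to_regions(t, 1.5, min_length=2)
        brute = []
        i = 0
        while i < n:
            if v[i] >= 1.5:
                j = i
                while j < n and v[j] >= 1.5:
                    j += 1
                if j - i >= 2:
                    brute.append((i, j))
                i = j
            else:
                i += 1
        assert [(r.start, r.end) for r in out["s1"]] == brute

    def test_coverage_and_max_score(self):
        seqs = one_seq(4)
        t = RegionTrack(seqs, {"s1": [Region(1, 3, "a", 0.5), Region(2, 4, "b", 0.9)]})
        assert np.array_equal(regions_to_numeric(t, "coverage")["s1"], [0, 1, 2, 1])
        assert np.array_equal(regions_to_numeric(t, "max_score")["s1"],
                              [0, 0.5, 0.9, 0.9])


class TestSequenceStatistics:
    def test_gc_content_excludes_unknown(self):
        seqs = one_seq(4)
        assert sequence_statistic(DNATrack(seqs, {"s1": "GGCC"}))["s1"] == 1.0
        assert sequence_statistic(DNATrack(seqs, {"s1": "ANGC"}))["s1"] == \
            pytest.approx(2 / 3)

    def test_collection_from_map(self):
        gc = NumericMap("sequence", {"s1": 0.3, "s2": 0.5})
        low = collection_from_map(gc, "<", 0.40)
        assert set(low.members) == {"s1"}
        assert len(collection_from_map(gc, ">", 2.0)) == 0
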