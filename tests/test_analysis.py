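import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from ciskit import (AnalysisResult, BenchmarkStats, CiskitError, Collection,
                    GenomicSequence, NumericMap, NumericTrack, Region,
                    RegionTrack, SequenceSet, benchmark_stats, collate,
                    count_motif_occurrences, group_comparison,
                    overrepresentation, positional_distribution, rank_sum,
                    render_result, sites_vs_numeric)
from ciskit.analysis import parse_raw


def make_seqs(n, length, tss=None):
    return SequenceSet([GenomicSequence(f"s{i+1}", f"s{i+1}", 0, length, "+",
                                        tss_offset=tss) for i in range(n)])


class TestCounting:
    def test_total_and_support(self):
        seqs = make_seqs(3, 50)
        t = RegionTrack(seqs, {"s1": [Region(0, 5, "A"), Region(10, 15, "A")],
                               "s2": [Region(3, 8, "A"), Region(20, 25, "B")]})
        res = count_motif_occurrences(t)
        assert res.table.loc["A", "total"] == 3
        assert res.table.loc["A", "support"] == 2
        assert res.table.loc["B", "support"] == 1

    def test_empty_track(self):
        res = count_motif_occurrences(RegionTrack(make_seqs(2, 10), {}))
        assert len(res.members) == 0

    def test_support_bounds(self):
        seqs = make_seqs(4, 100)
        rng = np.random.default_rng(0)
        regions = {n: [Region(int(a), int(a) + 5, str(rng.choice(["A", "B"])))
                       for a in rng.integers(0, 90, 6)] for n in seqs.names}
        res = count_motif_occurrences(RegionTrack(seqs, regions))
        for m in res.members:
            assert res.table.loc[m, "support"] <= 4
            assert res.table.loc[m, "total"] >= res.table.loc[m, "support"]


class TestOverrepresentation:
    def _counts(self, k, motif="A"):
        import pandas as pd
        table = pd.DataFrame({"total": [k], "support": [1]},
                             index=pd.Index([motif], name="motif"))
        return AnalysisResult("c", table, {"total": "number", "support": "number"})

    def test_exact_tail_small_n(self):
        # P(X >= 8), X ~ Bin(10, 0.5) = 56/1024
        res = overrepresentation(self._counts(8),
                                 NumericMap("motif", {"A": 0.5}), 10)
        assert res.table.loc["A", "p_value"] == pytest.approx(56 / 1024, rel=1e-12)

    def test_zero_observed_is_one(self):
        res = overrepresentation(self._counts(0), NumericMap("motif", {"A": 0.3}), 10)
        assert res.table.loc["A", "p_value"] == 1.0

    def test_matches_enumeration_all_small_cases(self):
        for n in (5, 12, 30):
            for k in range(n + 1):
                p = 0.2
                res = overrepresentation(self._counts(k),
                                         NumericMap("motif", {"A": p}), n)
                exact = sum(math.comb(n, j) * p ** j * (1 - p) ** (n - j)
                            for j in range(k, n + 1))
                assert res.table.loc["A", "p_value"] == pytest.approx(exact, abs=1e-12)

    def test_bonferroni_threshold_for_large_library(self):
        import pandas as pd
        table = pd.DataFrame({"total": [1] * 931, "support": [1] * 931},
                             index=pd.Index([f"m{i}" for i in range(931)],
                                            name="motif"))
        counts = AnalysisResult("c", table, {"total": "number", "support": "number"})
        res = overrepresentation(counts, NumericMap("motif", {}, default=0.001),
                                 10000, alpha=0.05)
        assert res.extras["corrected_threshold"] == pytest.approx(5.37e-5, rel=1e-3)

    def test_bad_frequency_rejected(self):
        with pytest.raises(CiskitError):
            overrepresentation(self._counts(1), NumericMap("motif", {"A": 1.5}), 10)


class TestGroupComparison:
    def test_one_sided_enrichment_class_A(self):
        seqs = make_seqs(4, 200)
        regions = {"s1": [Region(i * 10, i * 10 + 5, "A") for i in range(15)],
                   "s2": [Region(i * 10, i * 10 + 5, "A") for i in range(15)],
                   "s3": [], "s4": []}
        t = RegionTrack(seqs, regions)
        res = group_comparison(t, Collection("sequence", {"s1", "s2"}),
                               Collection("sequence", {"s3", "s4"}))
        assert res.table.loc["A", "group"] == "A"

    def test_identical_rates_class_C(self):
        seqs = make_seqs(2, 100)
        t = RegionTrack(seqs, {"s1": [Region(0, 5, "A")], "s2": [Region(0, 5, "A")]})
        res = group_comparison(t, Collection("sequence", {"s1"}),
                               Collection("sequence", {"s2"}))
        assert res.table.loc["A", "group"] == "C"

    def test_swap_antisymmetry(self):
        seqs = make_seqs(4, 200)
        rng = np.random.default_rng(8)
        regions = {"s1": [Region(i * 12, i * 12 + 5, "A") for i in range(12)],
                   "s2": [Region(i * 12, i * 12 + 5, "A") for i in range(10)],
                   "s3": [Region(0, 5, "A")], "s4": []}
        t = RegionTrack(seqs, regions)
        g1 = Collection("sequence", {"s1", "s2"})
        g2 = Collection("sequence", {"s3", "s4"})
        fwd = group_comparison(t, g1, g2).table.loc["A", "group"]
        rev = group_comparison(t, g2, g1).table.loc["A", "group"]
        assert (fwd in "AB") == (rev == "D")

    def test_overlapping_groups_rejected(self):
        seqs = make_seqs(2, 10)
        t = RegionTrack(seqs, {})
        with pytest.raises(CiskitError):
            group_comparison(t, Collection("sequence", {"s1"}),
                             Collection("sequence", {"s1", "s2"}))


class TestPositionalDistribution:
    def test_kurtosis_two_point(self):
        # midpoints {-1,-1,1,1}: m2 = 1, m4 = 1 -> kurtosis 1
        seqs = make_seqs(1, 100, tss=50)
        # midpoint = (start+end)//2; rel = mid - tss on '+'
        t = RegionTrack(seqs, {"s1": [Region(48, 50, "A"), Region(48, 50, "A"),
                                      Region(50, 52, "A"), Region(50, 52, "A")]})
        res = positional_distribution(t, "tss", bin_size=10)
        assert res.table.loc["A", "kurtosis"] == pytest.approx(1.0)

    def test_all_same_position_blank(self):
        seqs = make_seqs(1, 100, tss=50)
        t = RegionTrack(seqs, {"s1": [Region(10, 14, "A")] * 5})
        res = positional_distribution(t, "tss")
        assert math.isnan(res.table.loc["A", "kurtosis"])

    def test_normal_midpoints_kurtosis_three(self):
        rng = np.random.default_rng(123)
        length = 20000
        seqs = make_seqs(1, length, tss=10000)
        mids = rng.normal(0, 300, 10_000)
        regions = [Region(int(m) + 10000 - 1, int(m) + 10000 + 1, "A")
                   for m in mids]
        res = positional_distribution(RegionTrack(seqs, {"s1": regions}), "tss")
        assert res.table.loc["A", "kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_minus_strand_upstream_negative(self):
        # on a '-' sequence, upstream of the TSS is genomically to the right
        seqs = SequenceSet([GenomicSequence("s1", "s1", 0, 100, "-",
                                            tss_offset=50)])
        t = RegionTrack(seqs, {"s1": [Region(59, 61, "A")] * 4})  # mid 60
        res = positional_distribution(t, "tss", bin_size=5)
        edges = res.extras["bin_edges"]
        hist = [int(x) for x in res.table.loc["A", "histogram"].split(",")]
        # relative position is 50 - 60 = -10 -> counts fall in a negative bin
        bin_lo = edges[hist.index(4)]
        assert bin_lo == -10

    def test_missing_tss_rejected(self):
        seqs = make_seqs(1, 100, tss=None)
        t = RegionTrack(seqs, {"s1": [Region(0, 4, "A")]})
        with pytest.raises(CiskitError):
            positional_distribution(t, "tss")


class TestSitesVsNumeric:
    def test_single_site_mean(self):
        seqs = make_seqs(1, 4)
        t = RegionTrack(seqs, {"s1": [Region(0, 2, "A")]})
        f = NumericTrack(seqs, {"s1": [1, 3, 7, 9]})
        assert sites_vs_numeric(t, f).table.loc["A", "mean"] == 2.0

    def test_position_weighted_over_sites(self):
        seqs = make_seqs(1, 10)
        t = RegionTrack(seqs, {"s1": [Region(0, 2, "A"), Region(4, 8, "A")]})
        f = NumericTrack(seqs, {"s1": np.arange(10, dtype=float)})
        values = np.concatenate([f["s1"][0:2], f["s1"][4:8]])
        assert sites_vs_numeric(t, f).table.loc["A", "mean"] == \
            pytest.approx(values.mean())


class TestRankSum:
    def test_midranks_for_ties(self):
        a = NumericMap("motif", {"x": 1, "y": 1, "z": 2})
        b = NumericMap("motif", {"x": 1, "y": 2, "z": 3})
        out = rank_sum([(a, "ascending"), (b, "ascending")])
        assert out["x"] == 1.5 + 1
        assert out["y"] == 1.5 + 2
        assert out["z"] == 3 + 3

    def test_direction_flips_order(self):
        a = NumericMap("motif", {"x": 1, "y": 2})
        b = NumericMap("motif", {"x": 1, "y": 2})
        asc = rank_sum([(a, "ascending"), (b, "ascending")])
        desc = rank_sum([(a, "descending"), (b, "descending")])
        assert asc["x"] < asc["y"]
        assert desc["x"] > desc["y"]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        values = {f"m{i}": float(v) for i, v in enumerate(rng.random(10))}
        a = NumericMap("motif", values)
        a2 = NumericMap("motif", {k: np.exp(3 * v) for k, v in values.items()})
        b = NumericMap("motif", {k: float(v) for k, v in
                                 zip(values, rng.random(10))})
        r1 = rank_sum([(a, "ascending"), (b, "descending")])
        r2 = rank_sum([(a2, "ascending"), (b, "descending")])
        assert r1.values == r2.values

    def test_blanks_rank_last(self):
        a = NumericMap("motif", {"x": 1, "y": 2, "z": 3})
        b = NumericMap("motif", {"x": 5, "y": 1})  # z blank in b
        out = rank_sum([(a, "ascending"), (b, "ascending")])
        assert out["z"] == 3 + 3  # trailing midrank of the single blank slot

    def test_disjoint_maps_rejected(self):
        with pytest.raises(CiskitError):
            rank_sum([(NumericMap("motif", {"x": 1}), "ascending"),
                      (NumericMap("motif", {"y": 1}), "ascending")])


class TestBenchmarkStats:
    def test_perfect_prediction(self):
        seqs = make_seqs(1, 50)
        t = RegionTrack(seqs, {"s1": [Region(5, 15, "A")]})
        stats = benchmark_stats(t, t)
        assert stats.Sn == stats.Sp == stats.PPV == stats.CC == 1.0
        assert stats.sSn == 1.0

    def test_matthews_formula(self):
        stats = BenchmarkStats(TP=3, FP=1, TN=94, FN=2)
        assert stats.CC == pytest.approx(280 / math.sqrt(182400))

    def test_site_overlap_rule(self):
        # prediction [0,10) overlaps target [8,40) by 2 < 0.25 * 32
        seqs = make_seqs(1, 50)
        pred = RegionTrack(seqs, {"s1": [Region(0, 10, "p")]})
        ans = RegionTrack(seqs, {"s1": [Region(8, 40, "a")]})
        assert benchmark_stats(pred, ans).sSn == 0.0
        # a 10 bp overlap satisfies the 25% rule
        pred2 = RegionTrack(seqs, {"s1": [Region(0, 18, "p")]})
        assert benchmark_stats(pred2, ans).sSn == 1.0

    def test_zero_denominators_defined(self):
        seqs = make_seqs(1, 20)
        empty = RegionTrack(seqs, {})
        stats = benchmark_stats(empty, empty)
        assert stats.Sn == 0.0 and stats.CC == 0.0 and stats.sSn == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_labeler(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        seqs = make_seqs(2, n)
        def rand_track():
            return RegionTrack(seqs, {
                name: [Region(int(a), int(a) + int(w), "x")
                       for a, w in zip(rng.integers(0, n - 12, 6),
                                       rng.integers(1, 12, 6))]
                for name in seqs.names})
        pred, ans = rand_track(), rand_track()
        stats = benchmark_stats(pred, ans)
        tp = fp = tn = fn = 0
        for name in seqs.names:
            for i in range(n):
                p = any(r.start <= i < r.end for r in pred[name])
                a = any(r.start <= i < r.end for r in ans[name])
                tp += p and a
                fp += p and not a
                fn += a and not p
                tn += not p and not a
        assert (stats.TP, stats.FP, stats.TN, stats.FN) == (tp, fp, tn, fn)
        hit = total = 0
        for name in seqs.names:
            for t in ans[name]:
                total += 1
                if any(min(p.end, t.end) - max(p.start, t.start) >= 0.25 * t.length
                       and min(p.end, t.end) - max(p.start, t.start) > 0
                       for p in pred[name]):
                    hit += 1
        assert stats.sSn == pytest.approx(hit / total)


class TestCollateAndRender:
    def _tables(self):
        seqs = make_seqs(2, 300, tss=150)
        rng = np.random.default_rng(3)
        regions = {n: sorted([Region(int(a), int(a) + 6,
                                     str(rng.choice(["A", "B"])))
                              for a in rng.integers(0, 290, 8)],
                             key=lambda r: r.start)
                   for n in seqs.names}
        t = RegionTrack(seqs, regions)
        counts = count_motif_occurrences(t)
        over = overrepresentation(counts, NumericMap("motif", {}, default=0.001),
                                  600)
        pos = positional_distribution(t, "tss", bin_size=50)
        return counts, over, pos

    def test_collate_joins_columns(self):
        counts, over, pos = self._tables()
        meta = collate([(counts, ["total", "support"]),
                        (over, ["p_value"]),
                        (pos, ["kurtosis", "histogram"])])
        assert list(meta.table.columns) == ["total", "support", "p_value",
                                            "kurtosis", "histogram"]
        assert set(meta.members) == set(counts.members)

    def test_collate_single_identity(self):
        counts, _, _ = self._tables()
        meta = collate([(counts, ["total", "support"])])
        assert meta.table[["total", "support"]].equals(counts.table)

    def test_sorted_by_rank_sum(self):
        counts, over, pos = self._tables()
        meta = collate([(over, ["p_value"]), (pos, ["kurtosis"])],
                       sort_by=[("p_value", "ascending"),
                                ("kurtosis", "descending")])
        ranks = rank_sum([(over.to_numeric_map("p_value"), "ascending"),
                          (pos.to_numeric_map("kurtosis"), "descending")])
        got = [ranks[m] for m in meta.members]
        assert got == sorted(got)

    def test_raw_round_trip(self):
        counts, over, _ = self._tables()
        text = render_result(over, "raw")
        frame = parse_raw(text)
        for m in over.members:
            assert frame.loc[m, "total"] == over.table.loc[m, "total"]
            assert frame.loc[m, "p_value"] == pytest.approx(
                over.table.loc[m, "p_value"], rel=1e-5)

    def test_render_deterministic_and_flags_significant(self):
        counts, over, pos = self._tables()
        html1 = render_result(over, "html")
        html2 = render_result(over, "html")
        assert html1 == html2
        if over.table["significant"].any():
            assert "class='significant'" in html1
        assert "<svg" in render_result(pos, "html")

    def test_html_embeds_motif_logos(self):
        from ciskit import MotifCollectionObj, motif_from_sites
        counts, over, _ = self._tables()
        lib = MotifCollectionObj([motif_from_sites(["ACGT"] * 10, "A"),
                                  motif_from_sites(["TTGG"] * 10, "B")])
        html = render_result(counts, "html", motifs=lib)
        assert html.count("font-family=\"monospace\"") > 0
        assert "<th>logo</th>" in html

    def test_result_to_collection(self):
        counts, over, _ = self._tables()
        sig = over.to_collection("p_value", "<=", 1.0)
        assert set(sig.members) == set(over.members)

    def test_empty_result_header_only(self):
        import pandas as pd
        empty = AnalysisResult("empty", pd.DataFrame(columns=["x"]).astype(float),
                               {"x": "number"})
        raw = render_result(empty, "raw")
        assert raw.strip().split("\n") == ["member\tx"]
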