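import numpy as np
import pandas as pd
import pytest

from th17pipe.core import GeneModel, Interval, SignalTrack
from th17pipe.integration import (
    L1Config,
    TargetSets,
    build_target_sets,
    compare_group_enrichment,
    define_l1,
    expression_accessibility_strata,
    gc_content,
    gc_enrichment,
    metagene_profile,
    overlap_fractions,
    peak_enrichment_per_gene,
    rank_sum_test,
    shuffle_intervals,
    tertile_split,
    tss_signal,
)


def frame(d, columns):
    return pd.DataFrame({c: [v[i] for v in d.values()] for i, c in enumerate(columns)},
                        index=list(d))


class TestDefineL1:
    CFG = L1Config(input_sample_ids=("i1", "i2", "i3", "i4"))

    def test_gene_passing_both_criteria_included(self):
        mrna = frame({"g": (1.5, 0.9)}, ["wt1", "wt2"])  # mean 1.2 > 1
        inputs = frame({"g": (1.1, 2.0, 1.4, 3.0)}, ["i1", "i2", "i3", "i4"])
        assert define_l1(mrna, inputs, self.CFG) == {"g"}

    def test_single_failing_input_excludes(self):
        mrna = frame({"g": (1.5, 0.9)}, ["wt1", "wt2"])
        inputs = frame({"g": (1.1, 0.5, 1.4, 3.0)}, ["i1", "i2", "i3", "i4"])
        assert define_l1(mrna, inputs, self.CFG) == set()

    def test_mean_exactly_at_threshold_excluded(self):
        mrna = frame({"g": (1.0, 1.0)}, ["wt1", "wt2"])
        inputs = frame({"g": (2.0, 2.0, 2.0, 2.0)}, ["i1", "i2", "i3", "i4"])
        assert define_l1(mrna, inputs, self.CFG) == set()

    def test_gene_missing_from_one_table_excluded(self):
        mrna = frame({"g": (2.0, 2.0), "h": (2.0, 2.0)}, ["wt1", "wt2"])
        inputs = frame({"g": (2.0, 2.0, 2.0, 2.0)}, ["i1", "i2", "i3", "i4"])
        assert define_l1(mrna, inputs, self.CFG) == {"g"}

    def test_matches_brute_force_predicate(self, rng):
        genes = [f"g{i}" for i in range(200)]
        mrna = pd.DataFrame(rng.uniform(0, 3, size=(200, 2)), index=genes,
                            columns=["wt1", "wt2"])
        inputs = pd.DataFrame(rng.uniform(0, 3, size=(200, 4)), index=genes,
                              columns=["i1", "i2", "i3", "i4"])
        got = define_l1(mrna, inputs, self.CFG)
        expected = {
            g for g in genes
            if mrna.loc[g].mean() > 1 and (inputs.loc[g] > 1).all()
        }
        assert got == expected


class TestTargetSets:
    def test_peak_in_non_l1_gene_dropped(self):
        genes = [GeneModel("in_l1", "chr1", 0, 100, "+"),
                 GeneModel("not_l1", "chr1", 200, 300, "+")]
        peaks = [Interval("chr1", 210, 260, "p")]
        sets = build_target_sets(peaks, [], {"x"}, genes, l1={"in_l1"})
        assert sets.nsun2 == set()

    def test_subset_invariant_enforced(self):
        with pytest.raises(ValueError):
            TargetSets(nsun2={"a"}, m5c=set(), rorgt=set(), universe=set())

    def test_overlap_fraction_hand_counts(self):
        sets = TargetSets(
            nsun2={"a", "b", "c", "d", "e"},
            m5c={"a", "b", "c", "d", "x"},
            rorgt={"a", "b", "q", "r"},
            universe={"a", "b", "c", "d", "e", "x"},
        )
        out = overlap_fractions(sets)
        assert out["pct_nsun2_with_m5c"] == pytest.approx(80.0)
        # nsun2 & m5c = {a,b,c,d}; rorgt ∩ = {a,b} → 2/4
        assert out["pct_rorgt_with_nsun2_m5c"] == pytest.approx(50.0)

    def test_disjoint_sets_zero_identical_sets_full(self):
        uni = {"a", "b"}
        zero = overlap_fractions(TargetSets({"a"}, {"b"}, {"c"}, uni | {"c"}))
        assert zero["pct_nsun2_with_m5c"] == 0.0
        full = overlap_fractions(TargetSets({"a"}, {"a"}, {"a"}, uni))
        assert full["pct_nsun2_with_m5c"] == 100.0
        assert full["pct_rorgt_with_nsun2_m5c"] == 100.0

    def test_empty_denominator_reported_missing(self):
        out = overlap_fractions(TargetSets(set(), {"a"}, set(), {"a"}))
        assert out["pct_nsun2_with_m5c"] is None

    def test_venn_counts_match_membership_oracle(self, rng):
        ids = [f"g{i}" for i in range(100)]
        for _ in range(20):
            a = set(np.array(ids)[rng.random(100) < 0.3])
            b = set(np.array(ids)[rng.random(100) < 0.3])
            c = set(np.array(ids)[rng.random(100) < 0.3])
            sets = TargetSets(a, b, c, set(ids))
            out = overlap_fractions(sets)
            venn = out["venn"]
            assert sum(venn.values()) == len(a | b | c)
            expected_all3 = sum(1 for g in ids if g in a and g in b and g in c)
            assert venn["all_three"] == expected_all3
            if a:
                assert out["pct_nsun2_with_m5c"] == pytest.approx(100 * len(a & b) / len(a))


class TestGC:
    def test_all_gc_sequence(self):
        assert gc_content("GGCC") == 1.0

    def test_half_gc_sequence(self):
        assert gc_content("ATGC") == 0.5

    def test_background_reproducible_under_fixed_seed(self):
        genome = {"chr1": "ACGT" * 2500, "chr2": "GGCC" * 2500}
        peaks = [Interval("chr1", 0, 100, "p1"), Interval("chr2", 50, 250, "p2")]
        r1 = gc_enrichment(peaks, genome, 5, seed=11)
        r2 = gc_enrichment(peaks, genome, 5, seed=11)
        assert r1["background_intervals"] == r2["background_intervals"]
        assert np.array_equal(r1["background_gc"], r2["background_gc"])

    def test_peaks_as_own_background_give_p_near_one(self):
        rng = np.random.default_rng(3)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 10_000))}
        peaks = [Interval("chr1", int(s), int(s) + 50) for s in rng.integers(0, 9000, 30)]
        observed = np.array([gc_content(genome["chr1"][p.start:p.end]) for p in peaks])
        u, p = rank_sum_test(observed, observed)
        assert p > 0.9

    def test_oversize_peak_rejected(self):
        genome = {"chr1": "ACGT" * 10}
        with pytest.raises(ValueError):
            shuffle_intervals([Interval("chr1", 0, 100)], {"chr1": 40},
                              np.random.default_rng(0))

    def test_out_of_bounds_peak_rejected(self):
        genome = {"chr1": "ACGT" * 10}
        with pytest.raises(ValueError, match="outside"):
            gc_enrichment([Interval("chr1", 30, 60)], genome, 1, seed=0)


class TestTertiles:
    def test_sorted_split_of_nine(self):
        signal = {f"g{i}": float(i) for i in range(1, 10)}
        grouping = tertile_split(set(signal), signal)
        assert grouping.low == ["g1", "g2", "g3"]
        assert grouping.mid == ["g4", "g5", "g6"]
        assert grouping.high == ["g7", "g8", "g9"]

    def test_equal_thirds_partition_3105(self):
        signal = {f"g{i:05d}": float(i % 97) for i in range(3105)}
        grouping = tertile_split(set(signal), signal)
        assert [len(grouping.low), len(grouping.mid), len(grouping.high)] == [1035] * 3

    @pytest.mark.parametrize("n,sizes", [(10, (3, 3, 4)), (11, (3, 4, 4)), (12, (4, 4, 4))])
    def test_remainder_goes_to_high_groups(self, n, sizes):
        signal = {f"g{i}": float(i) for i in range(n)}
        grouping = tertile_split(set(signal), signal)
        assert (len(grouping.low), len(grouping.mid), len(grouping.high)) == sizes

    def test_all_equal_signals_deterministic_under_permutation(self, rng):
        ids = [f"g{i}" for i in range(10)]
        signal = {g: 1.0 for g in ids}
        g1 = tertile_split(ids, signal)
        g2 = tertile_split(list(rng.permutation(ids)), signal)
        assert g1.groups == g2.groups

    def test_partition_property(self, rng):
        ids = [f"g{i}" for i in range(50)]
        signal = {g: float(rng.integers(0, 5)) for g in ids}
        grouping = tertile_split(ids, signal)
        parts = grouping.low + grouping.mid + grouping.high
        assert sorted(parts) == sorted(ids)
        assert len(set(parts)) == len(parts)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            tertile_split({"a", "b"}, {"a": 1.0, "b": 2.0})


class TestRankSum:
    def test_tiny_groups_exact_enumeration(self):
        u, p = rank_sum_test(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_distributions_u_near_half_product(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        u, p = rank_sum_test(x, y)
        assert abs(u - 200 * 200 / 2) < 3000
        assert p > 0.05

    def test_shifted_groups_highly_significant(self, rng):
        x = rng.normal(size=50)
        u, p = rank_sum_test(x, x + 10)
        assert p < 1e-6


class TestGroupEnrichment:
    def test_summary_and_whiskers_on_known_values(self):
        grouping = tertile_split(
            {f"g{i}" for i in range(9)}, {f"g{i}": float(i) for i in range(9)}
        )
        enrichment = {f"g{i}": float(i) for i in range(9)}
        out = compare_group_enrichment(grouping, enrichment)
        low = out["groups"]["low"]
        assert low["median"] == 1.0
        assert low["q1"] == 0.5 and low["q3"] == 1.5
        assert low["whisker_low"] == pytest.approx(0.5 - 1.5)
        assert low["whisker_high"] == pytest.approx(1.5 + 1.5)
        assert "low_vs_high" in out["tests"]

    def test_identical_groups_nonsignificant(self, rng):
        vals = {f"g{i}": float(i % 7) for i in range(30)}
        grouping = tertile_split(set(vals), {g: 0.0 for g in vals})
        # enrichment identical in distribution across arbitrary groups
        out = compare_group_enrichment(grouping, vals)
        assert out["tests"]["low_vs_high"]["p_value"] > 0.01


class TestEnrichmentProxy:
    def test_log_ratio_with_epsilon_and_max_aggregation(self):
        gene_peaks = {"g": ["p1", "p2"]}
        ip = {"p1": 4.0, "p2": 1.0}
        inp = {"p1": 1.0, "p2": 1.0}
        out = peak_enrichment_per_gene(gene_peaks, ip, inp, epsilon=0.0)
        assert out["g"] == pytest.approx(2.0)


class TestMetagene:
    GENES = [GeneModel("gp", "chr1", 10_000, 12_000, "+"),
             GeneModel("gm", "chr1", 30_000, 32_000, "-")]

    def test_constant_track_gives_flat_profile(self):
        track = SignalTrack({"chr1": [(0, 50_000, 3.0)]})
        prof = metagene_profile(track, self.GENES, flank=1000, flank_bin=50, body_bins=20)
        assert np.allclose(prof.upstream, 3.0)
        assert np.allclose(prof.body, 3.0)
        assert np.allclose(prof.downstream, 3.0)

    def test_minus_strand_profile_mirrors_plus(self):
        # ramp rising with coordinate: for a minus-strand gene the upstream
        # flank lies at high coordinates, so its oriented profile must fall
        ramp = [(i * 100, (i + 1) * 100, float(i)) for i in range(500)]
        track = SignalTrack({"chr1": ramp})
        plus = metagene_profile(track, [self.GENES[0]], flank=1000, flank_bin=100, body_bins=20)
        minus_gene = GeneModel("gm", "chr1", 10_000, 12_000, "-")
        minus = metagene_profile(track, [minus_gene], flank=1000, flank_bin=100, body_bins=20)
        assert np.allclose(plus.concatenated(), minus.concatenated()[::-1])

    def test_hand_binned_toy_track(self):
        gene = GeneModel("g", "chr1", 100, 140, "+")
        track = SignalTrack({"chr1": [(100, 120, 2.0), (120, 140, 6.0)]})
        prof = metagene_profile(track, [gene], flank=50, flank_bin=25, body_bins=4)
        assert np.allclose(prof.body, [2.0, 2.0, 6.0, 6.0])
        assert np.allclose(prof.upstream, 0.0)

    def test_linearity_over_track_addition(self):
        t1 = SignalTrack({"chr1": [(0, 50_000, 1.0)]})
        t2 = SignalTrack({"chr1": [(5_000, 20_000, 2.5)]})
        p1 = metagene_profile(t1, self.GENES, flank=1000, flank_bin=50, body_bins=20)
        p2 = metagene_profile(t2, self.GENES, flank=1000, flank_bin=50, body_bins=20)
        p12 = metagene_profile(t1 + t2, self.GENES, flank=1000, flank_bin=50, body_bins=20)
        assert np.allclose(p12.concatenated(), p1.concatenated() + p2.concatenated())

    def test_short_gene_skipped(self):
        short = GeneModel("tiny", "chr1", 100, 110, "+")
        track = SignalTrack({"chr1": [(0, 1000, 1.0)]})
        with pytest.raises(ValueError, match="no usable genes"):
            metagene_profile(track, [short], flank=50, flank_bin=25, body_bins=20)


class TestTssSignal:
    def test_window_mean_against_track_query(self):
        gene = GeneModel("g", "chr1", 10_000, 12_000, "+")
        track = SignalTrack({"chr1": [(9_000, 11_000, 4.0)]})
        sig = tss_signal([gene], track, window=1000)
        # window [9000, 11001): 2000 bases at 4.0 of 2001 total
        assert sig["g"] == pytest.approx(4.0 * 2000 / 2001)


class TestStrata:
    def test_nine_gene_sort_oracle(self):
        mrna = {f"g{i}": float(i) for i in range(9)}
        atac = {f"g{i}": 10.0 * i for i in range(9)}
        out = expression_accessibility_strata(mrna, atac, top_n=9)
        assert list(out.index) == ["low", "mid", "high"]
        assert out.loc["low", "mean_atac_tss_rpkm"] == pytest.approx(10.0)
        assert out.loc["high", "mean_atac_tss_rpkm"] == pytest.approx(70.0)

    def test_planted_monotone_accessibility(self, rng):
        mrna = {f"g{i}": float(rng.uniform(0, 100)) for i in range(300)}
        atac = {g: 0.5 * v for g, v in mrna.items()}
        out = expression_accessibility_strata(mrna, atac, top_n=150)
        means = out["mean_atac_tss_rpkm"].to_numpy()
        assert means[0] < means[1] < means[2]

    def test_top_n_exceeding_gene_count_rejected(self):
        with pytest.raises(ValueError):
            expression_accessibility_strata({"g": 1.0}, {"g": 1.0}, top_n=2)
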