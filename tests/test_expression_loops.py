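import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meioloop import (LoopSet, RegionSet, ValidationError,
                      expression_shift_test, loop_expression_level,
                      loop_overlap_odds_ratio, partition_ssdna, private_loops,
                      promoter_overlap_classes)


def loop_set(*pairs, chrom="chr1"):
    m1, m2 = zip(*pairs)
    return LoopSet(pd.DataFrame({"chrom": chrom, "mid1": m1, "mid2": m2}))


class TestPrivateLoops:
    def test_single_type_all_private(self):
        cat = {"a": loop_set((100_000, 300_000), (500_000, 900_000))}
        priv = private_loops(cat)
        assert len(priv["a"]) == 2

    def test_shared_loop_private_to_neither(self):
        shared = (100_000, 300_000)
        cat = {"a": loop_set(shared, (500_000, 900_000)),
               "b": loop_set(shared)}
        priv = private_loops(cat)
        assert len(priv["a"]) == 1
        assert len(priv["b"]) == 0
        assert priv["a"].df["mid1"].iloc[0] == 500_000

    def test_tolerance_matching(self):
        cat = {"a": loop_set((100_000, 300_000)),
               "b": loop_set((103_000, 297_000))}
        assert len(private_loops(cat, tolerance=5000)["a"]) == 0
        assert len(private_loops(cat, tolerance=1000)["a"]) == 1

    def test_private_sets_disjoint_and_subset(self):
        rng = np.random.default_rng(4)
        def rand_loops(n, seed):
            r = np.random.default_rng(seed)
            m1 = r.integers(0, 1_000_000, n) * 10
            return LoopSet(pd.DataFrame({"chrom": "chr1", "mid1": m1,
                                         "mid2": m1 + 200_000}))
        cat = {"a": rand_loops(50, 1), "b": rand_loops(50, 2),
               "c": rand_loops(50, 3)}
        priv = private_loops(cat)
        for name, loops in priv.items():
            assert len(loops) <= len(cat[name])
            for other in priv:
                if other == name:
                    continue
                merged = pd.merge(loops.df, priv[other].df,
                                  on=["chrom", "mid1", "mid2"])
                assert len(merged) == 0


class TestPromoterClasses:
    def test_tss_at_anchor_is_both(self):
        loops = loop_set((100_000, 300_000))
        tss = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                            "tss": [100_000]})
        out = promoter_overlap_classes(tss, loops)
        assert bool(out["at_anchor"].iloc[0]) and bool(out["in_loop"].iloc[0])
        assert not out["outside"].iloc[0]

    def test_tss_outside_everything(self):
        loops = loop_set((100_000, 300_000))
        tss = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                            "tss": [306_000]})  # 3 kb past the loop end+anchor
        out = promoter_overlap_classes(tss, loops)
        assert bool(out["outside"].iloc[0])

    def test_tss_at_loop_center_in_loop_only(self):
        loops = loop_set((100_000, 200_000))
        tss = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                            "tss": [150_000]})
        out = promoter_overlap_classes(tss, loops)
        assert bool(out["in_loop"].iloc[0]) and not out["at_anchor"].iloc[0]


class TestExpressionShift:
    def test_identical_groups_median_difference_zero(self):
        vals = pd.Series({f"g{i}": v for i, v in
                          enumerate([0.5, -1.0, 2.0, 0.5, -1.0, 2.0])})
        res = expression_shift_test(vals, ["g0", "g1", "g2"],
                                    ["g3", "g4", "g5"])
        assert res["median_a"] == res["median_b"]

    def test_fully_separated_groups_exact_p(self):
        vals = pd.Series({"a1": 1.0, "a2": 2.0, "a3": 3.0,
                          "b1": -3.0, "b2": -2.0, "b3": -1.0})
        res = expression_shift_test(vals, ["a1", "a2", "a3"],
                                    ["b1", "b2", "b3"],
                                    alternative="greater")
        assert res["median_a"] == 2.0 and res["median_b"] == -2.0
        # exact enumeration: 1 of C(6,3)=20 orderings this extreme
        assert res["p"] == pytest.approx(1 / 20)

    def test_singleton_groups_run_with_wide_p(self):
        vals = pd.Series({"a": 1.0, "b": -1.0})
        res = expression_shift_test(vals, ["a"], ["b"])
        assert res["p"] > 0.3

    def test_overlapping_groups_error(self):
        vals = pd.Series({"a": 1.0, "b": -1.0})
        with pytest.raises(ValidationError):
            expression_shift_test(vals, ["a"], ["a", "b"])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            vals = pd.Series(rng.normal(size=40),
                             index=[f"g{i}" for i in range(40)])
            res = expression_shift_test(vals, [f"g{i}" for i in range(20)],
                                        [f"g{i}" for i in range(20, 40)])
            pvals.append(res["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPartition:
    def test_empty_recombination_set(self):
        ss = RegionSet.from_arrays(["chr1"] * 3, [0, 100, 200],
                                   [50, 150, 250])
        part = partition_ssdna(ss, RegionSet())
        assert part.sizes == (0, 3)

    def test_toy_partition(self):
        ss = RegionSet.from_arrays(["chr1"] * 3, [0, 100, 200],
                                   [50, 150, 250])
        rec = RegionSet.from_arrays(["chr1"], [120], [130])
        part = partition_ssdna(ss, rec)
        assert part.sizes == (1, 2)
        assert part.ssdna_rec_pos.df["start"].iloc[0] == 100

    def test_partition_conserves_total(self, dataset):
        part = partition_ssdna(dataset.ssdna, dataset.crossovers)
        assert sum(part.sizes) == len(dataset.ssdna)


class TestOddsRatio:
    def _partition_with_counts(self, a, b, c, d):
        # a/b: rec+ overlapping/not; c/d: rec- overlapping/not.
        # loops cover [0, 1e6); overlapping regions sit inside, others beyond.
        def block(n, inside, offset):
            start = np.arange(n) * 2000 + (0 if inside else 2_000_000) + offset
            return pd.DataFrame({"chrom": "chr1", "start": start,
                                 "end": start + 1000})
        pos = pd.concat([block(a, True, 0), block(b, False, 0)])
        neg = pd.concat([block(c, True, 500), block(d, False, 500)])
        from meioloop.expression_loops import HotspotPartition
        return HotspotPartition(RegionSet(pos), RegionSet(neg))

    def test_balanced_table_or_one(self):
        part = self._partition_with_counts(10, 10, 10, 10)
        loops = loop_set((0 + 1, 1_000_000))
        res = loop_overlap_odds_ratio(part, loops)
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_hand_formula_example(self):
        part = self._partition_with_counts(30, 10, 10, 30)
        loops = loop_set((1, 1_000_000))
        res = loop_overlap_odds_ratio(part, loops)
        assert res["odds_ratio"] == pytest.approx(9.0)
        assert res["ci95"][0] == pytest.approx(3.27, abs=0.05)
        assert res["ci95"][1] == pytest.approx(24.76, abs=0.1)

    def test_zero_cell_continuity_correction(self):
        part = self._partition_with_counts(10, 0, 5, 5)
        loops = loop_set((1, 1_000_000))
        res = loop_overlap_odds_ratio(part, loops)
        assert res["continuity_corrected"]
        assert np.isfinite(res["odds_ratio"])

    def test_planted_or_recovered_within_ci(self):
        # plant OR = 1.4 via overlap probabilities and check CI coverage
        target = 1.4
        p0 = 0.4
        odds1 = target * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        loops = loop_set((1, 10_000_000))
        covered = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            def regions(n, p_in):
                inside = rng.random(n) < p_in
                start = np.where(inside,
                                 rng.integers(0, 9_900_000, n),
                                 rng.integers(20_000_000, 30_000_000, n))
                return pd.DataFrame({"chrom": "chr1", "start": start,
                                     "end": start + 1000})
            from meioloop.expression_loops import HotspotPartition
            part = HotspotPartition(RegionSet(regions(2000, p1)),
                                    RegionSet(regions(2000, p0)))
            res = loop_overlap_odds_ratio(part, loops)
            lo, hi = res["ci95"]
            covered += lo <= target <= hi
        assert covered / n_rep >= 0.90


class TestLoopExpression:
    def _expr(self):
        return pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": ["chr1"] * 2,
                             "tss": [150_000, 180_000],
                             "scaled_expression": [1.0, 3.0]})

    def test_no_tss_scores_zero_flagged(self):
        loops = loop_set((500_000, 700_000))
        out = loop_expression_level(loops, self._expr())
        assert out["expression_level"].iloc[0] == 0.0
        assert not out["has_tss"].iloc[0]

    def test_mean_of_contained_genes(self):
        loops = loop_set((100_000, 300_000))
        out = loop_expression_level(loops, self._expr())
        assert out["expression_level"].iloc[0] == pytest.approx(2.0)
        out_sum = loop_expression_level(loops, self._expr(), stat="sum")
        assert out_sum["expression_level"].iloc[0] == pytest.approx(4.0)

    def test_invariant_to_gene_order(self):
        loops = loop_set((100_000, 300_000))
        e = self._expr()
        out1 = loop_expression_level(loops, e)
        out2 = loop_expression_level(loops, e.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(out1, out2)
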