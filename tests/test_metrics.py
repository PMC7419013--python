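"""Tests for the landscape statistics: levels, enrichment, window variance,
stage transitions, overlaps, paired differences, clustering, metaplots, and
matched-control repeat comparisons."""

import numpy as np
import pandas as pd
import pytest

from clever5fc import FcCallSet, GenomeMap, Interval, WindowGrid
from clever5fc.annotation import MarkedWindows, mark_windows
from clever5fc.errors import ConfigurationError, InvalidParameterError
from clever5fc.genome import AnnotationSet
from clever5fc.metrics import (
    WindowProfile,
    correlation_cluster,
    fc_level,
    matched_repeat_comparison,
    merge_stage,
    paired_difference,
    relative_enrichment,
    rpkm,
    shared_regions,
    signal_profile,
    stage_transition,
    window_profile,
    window_stats,
)


def callset(cell_id, fc_sites, unmod_sites, covered3=None, sequenced=None):
    fc = pd.DataFrame(
        {"nt": 3, "nc": 0, "raw_p": 1e-6, "adj_p": 1e-6},
        index=pd.MultiIndex.from_tuples(list(fc_sites) or [],
                                        names=["chrom", "pos"]),
    )
    if covered3 is None:
        covered3 = frozenset(fc_sites) | frozenset(unmod_sites)
    if sequenced is None:
        sequenced = len(covered3)
    return FcCallSet(cell_id, fc, frozenset(unmod_sites),
                     frozenset(covered3), sequenced)


class TestFcLevel:
    def test_simple(self):
        calls = callset("c", [("chr1", i) for i in (10, 20)],
                        [("chr1", 100 + i) for i in range(8)])
        assert fc_level(calls) == pytest.approx(0.2)

    def test_zero_fc(self):
        calls = callset("c", [], [("chr1", i + 1) for i in range(100)])
        assert fc_level(calls) == 0.0

    def test_scoped_count(self):
        fc = [("chr1", i + 1) for i in range(3)]
        unmod = [("chr1", 1000 + i) for i in range(997)]
        calls = callset("c", fc, unmod)
        level = fc_level(calls, [Interval("chr1", 0, 5000)])
        assert level == pytest.approx(3 / 1000)

    def test_empty_scope_is_nan(self):
        calls = callset("c", [("chr1", 10)], [("chr1", 20)])
        assert np.isnan(fc_level(calls, [Interval("chr2", 0, 100)]))

    def test_partition_identity(self):
        """Whole-genome level equals the count-weighted combination of the
        levels over any partition of the genome."""
        rng = np.random.default_rng(0)
        fc = [("chr1", int(p)) for p in rng.choice(10_000, 40, replace=False) + 1]
        unmod = [("chr1", int(p) + 20_000) for p in
                 rng.choice(10_000, 400, replace=False) + 1]
        calls = callset("c", fc, unmod)
        cuts = [0, 7_000, 15_000, 23_000, 40_000]
        total = n = 0.0
        for lo, hi in zip(cuts, cuts[1:]):
            scope = [Interval("chr1", lo, hi)]
            lvl = fc_level(calls, scope)
            if np.isnan(lvl):
                continue
            k = len([s for s in fc if lo < s[1] <= hi]) + len(
                [s for s in unmod if lo < s[1] <= hi]
            )
            total += lvl * k
            n += k
        assert total / n == pytest.approx(fc_level(calls))


class TestEnrichment:
    def _annotation(self):
        return AnnotationSet({"inA": [Interval("chr1", 0, 1000)],
                              "inB": [Interval("chr1", 1000, 2000)]})

    def test_matched_fraction_zero(self):
        ann = self._annotation()
        bg = frozenset(("chr1", p) for p in range(1, 10_001))
        fc = frozenset(("chr1", p) for p in range(1, 10_001, 10))
        table = relative_enrichment(fc, bg, ann)
        assert table.loc["inA", "log2_enrichment"] == pytest.approx(0.0)

    def test_double_fraction_is_one(self):
        ann = self._annotation()
        bg = frozenset(("chr1", p) for p in range(1, 2001))  # 50% in A
        fc = frozenset(("chr1", p) for p in range(1, 1001))  # 100% in A
        table = relative_enrichment(fc, bg, ann)
        assert table.loc["inA", "log2_enrichment"] == pytest.approx(1.0)

    def test_zero_background_class_is_nan(self):
        ann = AnnotationSet({"empty": [Interval("chr2", 0, 10)]})
        bg = frozenset(("chr1", p) for p in range(1, 100))
        fc = frozenset(("chr1", p) for p in range(1, 10))
        table = relative_enrichment(fc, bg, ann)
        assert np.isnan(table.loc["empty", "log2_enrichment"])

    def test_empty_fc_raises(self):
        with pytest.raises(InvalidParameterError):
            relative_enrichment(frozenset(), frozenset([("chr1", 1)]),
                                self._annotation())

    def test_fc_outside_background_raises(self):
        with pytest.raises(InvalidParameterError):
            relative_enrichment(frozenset([("chr1", 5)]),
                                frozenset([("chr1", 1)]), self._annotation())


class TestWindowStats:
    def _profile(self, owner, levels):
        """levels: {window: (n_fc, n_unmod)}"""
        return WindowProfile(owner, 1000, levels)

    def test_identical_profiles_zero_variance(self):
        counts = {("chr1", 0): (1, 1), ("chr1", 1000): (2, 2)}
        table, _ = window_stats([self._profile("a", counts),
                                 self._profile("b", counts)])
        assert (table["variance"] == 0).all()

    def test_zero_one_levels_give_half(self):
        a = self._profile("a", {("chr1", 0): (0, 5)})
        b = self._profile("b", {("chr1", 0): (5, 0)})
        table, _ = window_stats([a, b])
        assert table.loc[0, "variance"] == pytest.approx(0.5)

    def test_three_cell_sample_variance(self):
        # levels 0.1, 0.2, 0.6 -> sample variance 0.07
        a = self._profile("a", {("chr1", 0): (1, 9)})
        b = self._profile("b", {("chr1", 0): (2, 8)})
        c = self._profile("c", {("chr1", 0): (6, 4)})
        table, _ = window_stats([a, b, c])
        assert table.loc[0, "variance"] == pytest.approx(0.07)

    def test_retention_rule_drops_unmarked_windows(self):
        # window with only unmodified sites in every profile is not retained
        a = self._profile("a", {("chr1", 0): (0, 5), ("chr1", 1000): (1, 4)})
        b = self._profile("b", {("chr1", 0): (0, 5), ("chr1", 1000): (2, 3)})
        table, _ = window_stats([a, b])
        assert set(table["start"]) == {1000}

    def test_single_defined_level_skipped(self):
        a = self._profile("a", {("chr1", 0): (1, 1)})
        b = self._profile("b", {})
        table, _ = window_stats([a, b])
        assert len(table) == 0

    def test_class_medians(self):
        a = self._profile("a", {("chr1", 0): (0, 1), ("chr1", 1000): (0, 1)})
        b = self._profile("b", {("chr1", 0): (1, 0), ("chr1", 1000): (1, 0)})
        # mark both windows via a third profile so retention keeps them
        c = self._profile("c", {("chr1", 0): (1, 1), ("chr1", 1000): (1, 1)})
        cmap = {("chr1", 0): "promoter", ("chr1", 1000): "intron"}
        _, medians = window_stats([a, b, c], cmap)
        assert set(medians.index) == {"promoter", "intron"}


class TestStageTransition:
    def test_three_way_partition(self):
        earlier = merge_stage("e", [
            callset("e1", [("chr1", 10)], [("chr1", 20), ("chr1", 30)]),
        ])
        later = merge_stage("l", [
            callset("l1",
                    [("chr1", 10), ("chr1", 20), ("chr1", 99)],
                    []),
        ])
        counts = stage_transition(earlier, later)
        assert counts == {"inherited": 1, "newly_generated": 1,
                          "undetermined": 1}
        assert sum(counts.values()) == len(later.merged_fc)

    def test_fc_in_both_is_inherited(self):
        earlier = merge_stage("e", [callset("e1", [("chr1", 10)], [])])
        later = merge_stage("l", [callset("l1", [("chr1", 10)], [])])
        assert stage_transition(earlier, later)["inherited"] == 1

    def test_unmodified_earlier_is_newly_generated(self):
        earlier = merge_stage("e", [callset("e1", [], [("chr1", 10)])])
        later = merge_stage("l", [callset("l1", [("chr1", 10)], [])])
        assert stage_transition(earlier, later)["newly_generated"] == 1

    def test_uncovered_earlier_is_undetermined(self):
        earlier = merge_stage("e", [callset("e1", [], [("chr1", 99)])])
        later = merge_stage("l", [callset("l1", [("chr1", 10)], [])])
        assert stage_transition(earlier, later)["undetermined"] == 1


class TestStageMerge:
    def test_merged_and_common(self):
        a = callset("a", [("chr1", 10)], [("chr1", 20)],
                    covered3={("chr1", 10), ("chr1", 20), ("chr1", 30)})
        b = callset("b", [("chr1", 30)], [],
                    covered3={("chr1", 20), ("chr1", 30)})
        stage = merge_stage("s", [a, b])
        assert stage.merged_fc == {("chr1", 10), ("chr1", 30)}
        assert stage.common_covered == {("chr1", 20), ("chr1", 30)}
        # of the 2 commonly covered sites, one (chr1:30) was fc in a cell
        assert stage.stage_fc_fraction == pytest.approx(0.5)


class TestSharedRegions:
    def test_disjoint(self):
        a = MarkedWindows(1000, frozenset(("chr1", i * 1000) for i in range(5)))
        b = MarkedWindows(1000, frozenset(("chr1", i * 1000) for i in range(5, 12)))
        parts = shared_regions(a, b)
        assert parts["n_shared"] == 0
        assert parts["n_a_specific"] == 5 and parts["n_b_specific"] == 7

    def test_identical(self):
        w = frozenset(("chr1", i * 1000) for i in range(5))
        parts = shared_regions(MarkedWindows(1000, w), MarkedWindows(1000, w))
        assert parts["n_shared"] == 5
        assert parts["n_a_specific"] == parts["n_b_specific"] == 0

    def test_partial_overlap(self):
        a = MarkedWindows(1000, frozenset({("chr1", 0), ("chr1", 1000),
                                           ("chr1", 2000)}))
        b = MarkedWindows(1000, frozenset({("chr1", 1000), ("chr1", 3000)}))
        parts = shared_regions(a, b)
        assert (parts["n_shared"], parts["n_a_specific"],
                parts["n_b_specific"]) == (1, 2, 1)

    def test_grid_mismatch(self):
        with pytest.raises(ConfigurationError):
            shared_regions(MarkedWindows(1000, frozenset()),
                           MarkedWindows(10_000, frozenset()))


class TestPairedDifference:
    def test_whole_genome_magnitude(self):
        # levels 0.00106 vs 0.00109 -> difference -3e-5
        male = callset("m", [("chr1", i) for i in range(1, 107)],
                       [("chr1", 10_000 + i) for i in range(100_000 - 106)])
        female = callset("f", [("chr2", i) for i in range(1, 110)],
                         [("chr2", 10_000 + i) for i in range(100_000 - 109)])
        diff = paired_difference(male, female).diffs["whole_genome"]
        assert diff == pytest.approx(106 / 100_000 - 109 / 100_000, rel=1e-9)

    def test_identical_is_zero(self):
        a = callset("a", [("chr1", 10)], [("chr1", 20)])
        diff = paired_difference(a, a, {"s": [Interval("chr1", 0, 100)]})
        assert all(v == 0 for v in diff.diffs.values())

    def test_antisymmetry_exact(self):
        a = callset("a", [("chr1", 10)], [("chr1", 20), ("chr1", 30)])
        b = callset("b", [("chr1", 40), ("chr1", 50)], [("chr1", 60)])
        scopes = {"s": [Interval("chr1", 0, 45)]}
        d_ab = paired_difference(a, b, scopes).diffs
        d_ba = paired_difference(b, a, scopes).diffs
        for k in d_ab:
            assert d_ab[k] == -d_ba[k]


class TestCorrelationCluster:
    def _profiles(self, vectors):
        out = []
        for i, vec in enumerate(vectors):
            counts = {("chr1", j * 1000): (int(round(v * 10)), 10 - int(round(v * 10)))
                      for j, v in enumerate(vec)}
            out.append(WindowProfile(f"p{i}", 1000, counts))
        return out

    def test_identical_profiles(self):
        p = self._profiles([[0.1, 0.2, 0.3, 0.4]] * 2)
        res = correlation_cluster(p)
        assert res.rho.iloc[0, 1] == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        p = self._profiles([[0.1, 0.2, 0.3, 0.4], [0.4, 0.3, 0.2, 0.1]])
        res = correlation_cluster(p)
        assert res.rho.iloc[0, 1] == pytest.approx(-1.0)

    def test_rank_swap_example(self):
        # ranks {1,2,3,4} vs {1,3,2,4} -> rho 0.8
        p = self._profiles([[0.1, 0.2, 0.3, 0.4], [0.1, 0.3, 0.2, 0.4]])
        res = correlation_cluster(p)
        assert res.rho.iloc[0, 1] == pytest.approx(0.8)

    def test_symmetric_unit_diagonal_and_leaf_order(self):
        p = self._profiles([[0.1, 0.2, 0.3, 0.4],
                            [0.1, 0.3, 0.2, 0.4],
                            [0.4, 0.3, 0.2, 0.1]])
        res = correlation_cluster(p)
        mat = res.rho.to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        assert sorted(res.leaf_order) == ["p0", "p1", "p2"]
        # the two positively correlated profiles should be adjacent leaves
        i0, i1 = res.leaf_order.index("p0"), res.leaf_order.index("p1")
        assert abs(i0 - i1) == 1

    def test_too_few_joint_windows_flagged(self):
        a = WindowProfile("a", 1000, {("chr1", 0): (1, 1), ("chr1", 1000): (1, 0)})
        b = WindowProfile("b", 1000, {("chr1", 0): (1, 1), ("chr1", 1000): (0, 2)})
        res = correlation_cluster([a, b])
        assert ("a", "b") in res.undefined_pairs
        assert res.leaf_order is None


class TestSignalProfile:
    GENOME = GenomeMap({"chr1": 100_000}, ())

    def test_constant_track_flat(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                              "end": [100_000], "value": [2.5]})
        prof = signal_profile([("chr1", 5000), ("chr1", 7000)], track,
                              flank=300, n_bins=5, genome=self.GENOME)
        assert np.allclose(prof, 2.5)

    def test_center_peak(self):
        track = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1"],
             "start": [0, 4950, 5050],
             "end": [4950, 5050, 100_000],
             "value": [0.0, 10.0, 0.0]}
        )
        prof = signal_profile([("chr1", 5000)], track, flank=300, n_bins=3,
                              genome=self.GENOME)
        assert prof[1] > prof[0] and prof[1] > prof[2]

    def test_step_track_bin_means(self):
        # step: value 1 on [0, 5000), value 3 on [5000, 100000)
        track = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 5000],
             "end": [5000, 100_000], "value": [1.0, 3.0]}
        )
        # site at 1-based 5000 -> center 4999.5; flank 300, 3 bins of 200 bp:
        # [4699.5, 4899.5) all value 1; [4899.5, 5099.5) mixed; [5099.5, 5299.5) all 3
        prof = signal_profile([("chr1", 5000)], track, flank=300, n_bins=3,
                              genome=self.GENOME)
        assert prof[0] == pytest.approx(1.0)
        mixed = (1.0 * (5000 - 4899.5) + 3.0 * (5099.5 - 5000)) / 200
        assert prof[1] == pytest.approx(mixed)
        assert prof[2] == pytest.approx(3.0)

    def test_empty_track_all_missing(self):
        track = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        prof = signal_profile([("chr1", 5000)], track, flank=300, n_bins=3,
                              genome=self.GENOME)
        assert np.isnan(prof).all()

    def test_even_bins_rejected(self):
        track = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        with pytest.raises(InvalidParameterError):
            signal_profile([], track, flank=300, n_bins=4, genome=self.GENOME)


class TestMatchedRepeatComparison:
    def test_rpkm_formula(self):
        assert rpkm(10, 2000, 1_000_000) == pytest.approx(5.0)

    def test_null_mean_difference_small(self):
        rng = np.random.default_rng(3)
        values = {f"r{i}": float(v) for i, v in enumerate(rng.normal(5, 1, 400))}
        marked = [f"r{i}" for i in range(100)]
        unmarked = [f"r{i}" for i in range(100, 400)]
        res = matched_repeat_comparison(marked, unmarked, values, seed=1)
        assert abs(res.marked_mean - res.control_mean) < 0.5
        assert res.p_value > 0.001

    def test_same_seed_same_controls(self):
        values = {f"r{i}": float(i) for i in range(50)}
        marked = [f"r{i}" for i in range(10)]
        unmarked = [f"r{i}" for i in range(10, 50)]
        a = matched_repeat_comparison(marked, unmarked, values, seed=7)
        b = matched_repeat_comparison(marked, unmarked, values, seed=7)
        assert a.control_ids == b.control_ids

    def test_insufficient_controls(self):
        values = {f"r{i}": 1.0 for i in range(5)}
        with pytest.raises(InvalidParameterError):
            matched_repeat_comparison(["r0", "r1", "r2"], ["r3", "r4"],
                                      values, seed=0)


class TestWindowProfileBuilder:
    def test_counts_aggregated(self):
        grid = WindowGrid(1000, {"chr1": 10_000})
        prof = window_profile(
            [("chr1", 100), ("chr1", 900)], [("chr1", 500), ("chr1", 1500)],
            grid, owner="c",
        )
        assert prof.counts[("chr1", 0)] == (2, 1)
        assert prof.counts[("chr1", 1000)] == (0, 1)
        assert prof.level(("chr1", 0)) == pytest.approx(2 / 3)
        assert np.isnan(prof.level(("chr1", 9000)))
        assert prof.marked_windows() == {("chr1", 0)}
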