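import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gcbias.bias_stats import (
    GCBinTable,
    bias_gc_regression,
    bin_by_gc,
    cgc_curve,
    overall_bias,
)
from gcbias.genome_io import WindowRecord


def W(gc, rel, contig="c", start=0):
    return WindowRecord(contig, start, start + 200, gc, 0, rel)


def brute_force_bins(windows, bin_width=0.5):
    """Independent group-and-average oracle."""
    groups = {}
    for w in windows:
        label = math.floor(w.gc_percent / bin_width + 1e-9) * bin_width
        groups.setdefault(round(label, 10), []).append(w.relative_coverage)
    return {
        label: (len(vals), sum(vals) / len(vals))
        for label, vals in sorted(groups.items())
    }


def brute_force_bias(bins: GCBinTable) -> float:
    """The bias statistic by explicit summation: sum n_i (C_i-1)^2 / (nT N)."""
    total = 0.0
    for n_i, c_i in zip(bins.n, bins.c):
        total += n_i * (c_i - 1.0) ** 2
    return total / (bins.n_total * bins.n_bins)


class TestBinByGC:
    def test_two_windows_same_bin_averaged(self):
        t = bin_by_gc([W(30.0, 0.5), W(30.0, 1.5)])
        assert t.gc_label.tolist() == [30.0]
        assert t.n.tolist() == [2]
        assert t.c.tolist() == [1.0]

    def test_half_percent_apart_distinct_bins(self):
        t = bin_by_gc([W(30.0, 1.0), W(30.5, 1.0)])
        assert t.gc_label.tolist() == [30.0, 30.5]

    def test_no_windows_is_error(self):
        with pytest.raises(ValueError):
            bin_by_gc([])

    def test_unfilled_relative_coverage_is_error(self):
        with pytest.raises(ValueError, match="unfilled"):
            bin_by_gc([WindowRecord("c", 0, 200, 30.0, 0, None)])

    def test_matches_grouping_oracle_on_random_windows(self, rng):
        windows = [
            W(float(g), float(r))
            for g, r in zip(
                rng.integers(40, 140, 1000) * 0.5, rng.uniform(0, 3, 1000)
            )
        ]
        table = bin_by_gc(windows)
        oracle = brute_force_bins(windows)
        assert table.gc_label.tolist() == list(oracle)
        for label, n_i, c_i in zip(table.gc_label, table.n, table.c):
            n_o, c_o = oracle[label]
            assert n_i == n_o
            assert c_i == pytest.approx(c_o, abs=1e-12)

    def test_window_conservation(self, rng):
        windows = [W(float(g) / 2, 1.0) for g in rng.integers(0, 200, 500)]
        assert bin_by_gc(windows).n_total == 500


class TestCgcCurve:
    def test_rare_bin_dropped_at_half_percent_threshold(self):
        # fractions 0.004 / 0.5 / 0.496 of 1000 windows
        windows = (
            [W(20.0, 1.0)] * 4 + [W(40.0, 1.0)] * 500 + [W(60.0, 1.0)] * 496
        )
        curve = cgc_curve(bin_by_gc(windows), min_bin_fraction=0.005)
        assert curve["gc_label"].tolist() == [40.0, 60.0]

    def test_zero_threshold_returns_all_bins(self):
        windows = [W(20.0, 1.0)] * 1 + [W(40.0, 1.0)] * 999
        curve = cgc_curve(bin_by_gc(windows), min_bin_fraction=0.0)
        assert len(curve) == 2

    def test_uniform_coverage_gives_flat_unity_curve(self):
        windows = [W(gc, 1.0) for gc in (30.0, 35.0, 40.0, 45.0)] * 10
        curve = cgc_curve(bin_by_gc(windows))
        assert np.allclose(curve["cgc"], 1.0)

    def test_display_filter_never_touches_bias(self):
        windows = [W(20.0, 9.0)] * 1 + [W(40.0, 1.0)] * 999
        table = bin_by_gc(windows)
        b = overall_bias(table).B
        assert b > 0  # the rare extreme bin still contributes to B
        curve = cgc_curve(table)
        assert 20.0 not in curve["gc_label"].tolist()


class TestOverallBias:
    def test_zero_deviation_both_variants(self):
        t = bin_by_gc([W(30.0, 1.0), W(40.0, 1.0)])
        assert overall_bias(t, "mean_squared").B == 0.0
        assert overall_bias(t, "root").B == 0.0

    def test_hand_evaluated_example(self):
        # two bins, n1=n2=1, C=0.5/1.5 -> (0.25+0.25)/(2*2) = 0.125
        t = bin_by_gc([W(30.0, 0.5), W(40.0, 1.5)])
        assert overall_bias(t).B == pytest.approx(0.125, abs=1e-15)

    def test_root_is_sqrt_of_mean_squared(self):
        t = bin_by_gc([W(30.0, 0.2), W(40.0, 1.5), W(40.0, 2.1)])
        ms = overall_bias(t, "mean_squared").B
        assert overall_bias(t, "root").B == pytest.approx(math.sqrt(ms))

    def test_matches_summation_oracle_on_random_tables(self, rng):
        for _ in range(50):
            k = rng.integers(2, 40)
            t = GCBinTable(
                gc_label=np.arange(k) * 0.5 + 20.0,
                n=rng.integers(1, 500, k),
                c=rng.uniform(0, 3, k),
            )
            assert overall_bias(t).B == pytest.approx(
                brute_force_bias(t), abs=1e-12
            )

    def test_invariant_under_bin_permutation(self, rng):
        """B depends on the multiset of bins, not their GC ordering."""
        k = 10
        n = rng.integers(1, 100, k)
        c = rng.uniform(0, 2, k)
        t1 = GCBinTable(np.arange(k) * 0.5, n, c)
        perm = rng.permutation(k)
        # permute bin contents while keeping labels sorted
        t2 = GCBinTable(np.arange(k) * 0.5, n[perm], c[perm])
        assert overall_bias(t1).B == pytest.approx(overall_bias(t2).B, rel=1e-12)

    def test_bin_width_changes_n_and_b_predictably(self):
        """Halving the bin width splits bins, changing N and hence B."""
        windows = [W(30.0, 0.5), W(30.3, 1.5), W(40.0, 1.0), W(40.3, 1.0)]
        coarse = bin_by_gc(windows, bin_width=0.5)
        fine = bin_by_gc(windows, bin_width=0.25)
        assert coarse.n_bins == 2 and fine.n_bins == 4
        # coarse: bins {30.0: C=1.0, 40.0: C=1.0} -> B = 0
        assert overall_bias(coarse).B == 0.0
        # fine: C = (0.5, 1.5, 1, 1), n_i=1, nT=4, N=4 -> 0.5/(16)
        assert overall_bias(fine).B == pytest.approx(0.5 / 16, abs=1e-15)

    def test_unknown_variant_rejected(self):
        t = bin_by_gc([W(30.0, 1.0), W(40.0, 1.0)])
        with pytest.raises(ValueError, match="variant"):
            overall_bias(t, "median")


class TestBiasGcRegression:
    def test_exact_linear_fit(self):
        gc = np.array([25.0, 30.0, 40.0, 55.0, 70.0])
        pts = list(zip(gc, -0.03 * gc + 2))
        r = bias_gc_regression(pts)
        assert r.slope == pytest.approx(-0.03)
        assert r.intercept == pytest.approx(2.0)
        assert r.r_squared == pytest.approx(1.0)
        assert r.ci95_slope[0] <= r.slope <= r.ci95_slope[1]

    def test_two_points_insufficient(self):
        with pytest.raises(ValueError, match="at least 3"):
            bias_gc_regression([(30.0, 1.0), (40.0, 0.5)])

    def test_constant_gc_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            bias_gc_regression([(30.0, 1.0), (30.0, 0.5), (30.0, 0.2)])

    def test_p_value_small_for_strong_relation(self, rng):
        gc = np.linspace(25, 72, 20)
        b = 2.5 - 0.03 * gc + rng.normal(0, 0.02, 20)
        r = bias_gc_regression(list(zip(gc, b)))
        assert r.p_value_slope < 1e-6
        assert r.slope < 0
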