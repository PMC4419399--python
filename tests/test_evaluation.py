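"""GDT machinery, aggregation, bins, convergence and run comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from classfrag import synthetic
from classfrag.evaluation import (
    GDT_HA_THRESHOLDS,
    GDT_TS_THRESHOLDS,
    DecoySeries,
    EvalSummary,
    compare_runs,
    convergence_index,
    convergence_report,
    gdt_fractions,
    gdt_score,
    is_informative,
    quality_bin,
    relative_speedup,
    score_series,
    top_k_summary,
)
from classfrag.geometry import kabsch_superpose
from classfrag.synthetic import SSSpec


def exhaustive_gdt(mc, nc, thresholds, max_iter=50):
    """Independent oracle: iterate from every contiguous seed of every length."""
    n = len(mc)
    fracs = []
    for thr in thresholds:
        best = 0.0
        for L in range(3, n + 1):
            for s in range(n - L + 1):
                inc = np.zeros(n, bool)
                inc[s:s + L] = True
                for _ in range(max_iter):
                    sup = kabsch_superpose(mc[inc], nc[inc])
                    dist = np.linalg.norm(sup.apply(mc) - nc, axis=1)
                    new = dist < thr
                    best = max(best, float(new.mean()))
                    if new.sum() < 3 or np.array_equal(new, inc):
                        break
                    inc = new
        fracs.append(best)
    return round(100.0 * float(np.mean(fracs)), 2)


class TestGdtFractions:
    def test_closed_form_ts(self):
        fr, score = gdt_fractions([0.4, 1.5, 3.0, 9.0], [1, 2, 4, 8])
        assert fr == pytest.approx([0.25, 0.50, 0.75, 0.75])
        assert score == pytest.approx(56.25)

    def test_closed_form_ha(self):
        _, score = gdt_fractions([0.4, 1.5, 3.0, 9.0], GDT_HA_THRESHOLDS)
        assert score == pytest.approx(43.75)

    def test_all_zero_distances(self):
        _, score = gdt_fractions([0.0] * 5, GDT_TS_THRESHOLDS)
        assert score == pytest.approx(100.0)

    def test_strict_inequality_at_threshold(self):
        fr, _ = gdt_fractions([1.0, 2.0, 4.0, 8.0], [1, 2, 4, 8])
        assert fr == [0.0, 0.25, 0.5, 0.75]  # d == t is NOT within t

    def test_empty_error(self):
        with pytest.raises(ValueError):
            gdt_fractions([], [1, 2, 4, 8])


class TestGdtScore:
    def test_rigid_copy_is_100(self, ideal_helix):
        R = Rotation.from_euler("xyz", [15, -40, 60], degrees=True).as_matrix()
        moved = ideal_helix.transformed(R, np.array([3.0, 4.0, 5.0]))
        assert gdt_score(moved, ideal_helix) == pytest.approx(100.0)

    def test_matches_exhaustive_oracle_small(self):
        rng = np.random.default_rng(0)
        for _ in range(12):
            n = int(rng.integers(8, 16))
            nc = rng.normal(size=(n, 3)) * 4.0
            mc = nc + rng.normal(size=(n, 3)) * rng.uniform(0.3, 3.0)
            assert gdt_score(mc, nc) == pytest.approx(
                exhaustive_gdt(mc, nc, GDT_TS_THRESHOLDS), abs=1e-6)

    def test_single_displaced_residue_toy(self):
        rng = np.random.default_rng(1)
        nc = np.cumsum(rng.normal(size=(20, 3)), axis=0)
        mc = nc.copy()
        mc[7] += np.array([10.0, 0.0, 0.0])
        assert gdt_score(mc, nc) == pytest.approx(
            exhaustive_gdt(mc, nc, GDT_TS_THRESHOLDS), abs=1e-6)

    def test_dominates_single_global_superposition(self):
        rng = np.random.default_rng(2)
        nc = np.cumsum(rng.normal(size=(15, 3)), axis=0)
        mc = nc + rng.normal(size=(15, 3)) * 1.5
        sup = kabsch_superpose(mc, nc)
        dist = np.linalg.norm(sup.apply(mc) - nc, axis=1)
        _, single = gdt_fractions(dist, GDT_TS_THRESHOLDS)
        assert gdt_score(mc, nc) >= single - 1e-9

    def test_symmetry_and_rigid_invariance(self):
        rng = np.random.default_rng(3)
        nc = np.cumsum(rng.normal(size=(12, 3)), axis=0)
        mc = nc + rng.normal(size=(12, 3))
        g = gdt_score(mc, nc)
        assert abs(gdt_score(nc, mc) - g) <= 0.01
        R = Rotation.random(random_state=5).as_matrix()
        assert gdt_score(mc @ R.T + 7.0, nc) == pytest.approx(g, abs=0.01)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            gdt_score(np.zeros((5, 3)), np.zeros((6, 3)))


class TestSeriesAndSummary:
    def test_score_series_order_preserved(self, ideal_helix):
        decoys = synthetic.make_decoys(ideal_helix, sigma=5, n=3, seed=1)
        series = score_series(decoys, ideal_helix)
        assert len(series) == 3
        same = score_series([decoys[0], decoys[0]], ideal_helix)
        assert same.gdt_ts[0] == same.gdt_ts[1]

    def test_empty_error(self, ideal_helix):
        with pytest.raises(ValueError):
            score_series([], ideal_helix)

    def test_top_k_means(self):
        gdt = np.arange(10.0, 101.0, 10.0)  # 10..100
        series = DecoySeries(gdt, gdt, np.arange(1.0, 11.0))
        assert top_k_summary(series, k=10).gdt == pytest.approx(55.0)
        assert top_k_summary(series, k=3).gdt == pytest.approx(90.0)
        assert top_k_summary(series, k=3).rmsd == pytest.approx(2.0)

    def test_single_decoy(self):
        series = DecoySeries([42.0], [30.0], [5.0])
        s = top_k_summary(series)
        assert s.gdt == 42.0 and s.rmsd == 5.0
        assert s.best_gdt == 42.0 and s.best_rmsd == 5.0

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        gdt = rng.uniform(0, 100, 100)
        rmsd = rng.uniform(0, 20, 100)
        series = DecoySeries(gdt, gdt, rmsd)
        s = top_k_summary(series, k=10)
        assert s.gdt == pytest.approx(np.mean(sorted(gdt, reverse=True)[:10]))
        assert s.rmsd == pytest.approx(np.mean(sorted(rmsd)[:10]))

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=50))
    def test_top10_between_best_and_mean(self, gdt):
        arr = np.array(gdt)
        series = DecoySeries(arr, arr, np.ones_like(arr))
        s = top_k_summary(series, k=10)
        assert s.gdt <= s.best_gdt + 1e-9
        assert s.gdt >= arr.mean() - 1e-9

    def test_k_zero_error(self):
        with pytest.raises(ValueError):
            top_k_summary(DecoySeries([1.0], [1.0], [1.0]), k=0)


class TestQualityBins:
    @pytest.mark.parametrize("gdt,bin_", [
        (39.99, "Poor"), (40.0, "Moderate"), (59.99, "Moderate"),
        (60.0, "Good"), (84.99, "Good"), (85.0, "HighQuality"),
        (0.0, "Poor"), (100.0, "HighQuality"),
    ])
    def test_bins(self, gdt, bin_):
        assert quality_bin(gdt) == bin_

    def test_informative_flag(self):
        assert not is_informative(39.99)
        assert is_informative(40.0)

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_monotone_step_function(self, a, b):
        order = ["Poor", "Moderate", "Good", "HighQuality"]
        lo, hi = sorted([a, b])
        assert order.index(quality_bin(lo)) <= order.index(quality_bin(hi))


class TestConvergence:
    def test_first_max(self):
        series = DecoySeries([50, 70, 70, 60], [0, 0, 0, 0], [4, 3, 3, 5])
        ci = convergence_index(series)
        assert ci.first_best_gdt == 2
        assert ci.first_best_rmsd == 2

    def test_monotone_decreasing(self):
        series = DecoySeries([80, 70, 60], [0, 0, 0], [1, 2, 3])
        assert convergence_index(series).first_best_gdt == 1

    def test_both_attained(self):
        gdt = [10, 20, 30, 40, 90, 50]
        rmsd = [9, 8, 7, 6, 1, 5]
        ci = convergence_index(DecoySeries(gdt, gdt, rmsd))
        assert ci.both == 5

    def test_both_sentinel_when_split(self):
        ci = convergence_index(DecoySeries([90, 10], [0, 0], [5, 1]))
        assert ci.both is None

    def test_report_speedups(self):
        base = DecoySeries([1, 2, 3], [0, 0, 0], [3, 2, 1])
        runs = {"std": [base], "fast": [base]}
        df = convergence_report(runs)
        assert df.loc["std", "speedup_vs_fast"] == 0.0

    def test_relative_speedup_formula(self):
        assert relative_speedup(13175, 13560) == 2.8
        assert relative_speedup(12625, 13560) == 6.9


def summaries(ids, gdt, rmsd):
    return [EvalSummary(target_id=i, gdt=g, rmsd=r, best_gdt=g, best_rmsd=r)
            for i, g, r in zip(ids, gdt, rmsd)]


class TestCompareRuns:
    def test_identical_runs(self):
        a = summaries("abcde", [40, 50, 60, 70, 80], [6, 5, 4, 3, 2])
        rep = compare_runs(a, a)
        assert rep["gdt"]["pct_unaffected"] == 100.0
        assert rep["gdt"]["p_value"] == 1.0

    def test_hand_counted_toy(self):
        ids = "abcde"
        a = summaries(ids, [40, 50, 60, 70, 80], [6.0, 5.0, 4.0, 3.0, 2.0])
        b = summaries(ids, [45, 50, 55, 70.04, 81], [5.0, 5.2, 4.0, 2.0, 2.0])
        rep = compare_runs(a, b)
        assert rep["gdt"]["pct_improved"] == 40.0   # a, e
        assert rep["gdt"]["pct_unaffected"] == 40.0  # b, d (1-decimal tie)
        assert rep["gdt"]["pct_worsened"] == 20.0   # c
        assert rep["gdt"]["improved"]["mean_change"] == pytest.approx(3.0)
        assert rep["rmsd"]["pct_improved"] == 40.0   # a, d (lower is better)
        assert rep["rmsd"]["pct_worsened"] == 20.0   # b
        total = (rep["gdt"]["pct_improved"] + rep["gdt"]["pct_unaffected"]
                 + rep["gdt"]["pct_worsened"])
        assert total == pytest.approx(100.0)

    def test_unpaired_error(self):
        a = summaries("ab", [1, 2], [1, 2])
        b = summaries("ac", [1, 2], [1, 2])
        with pytest.raises(ValueError, match="paired"):
            compare_runs(a, b)

    def test_wilcoxon_direction(self):
        ids = [str(i) for i in range(12)]
        a = summaries(ids, np.linspace(40, 60, 12), np.linspace(6, 4, 12))
        b = summaries(ids, np.linspace(40, 60, 12) + 3.0, np.linspace(6, 4, 12))
        rep = compare_runs(a, b)
        assert rep["gdt"]["pct_improved"] == 100.0
        assert rep["gdt"]["p_value"] < 0.01
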