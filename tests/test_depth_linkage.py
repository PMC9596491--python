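"""Depth ratios, IQR thresholds, classification rules, window summaries."""
import numpy as np
import pandas as pd
import pytest

from sexscan import (
    GenomeLayout,
    classify_snps,
    depth_ratio,
    iqr_thresholds,
    window_depth_summary,
)
from sexscan.depth_linkage import (
    CLASS_AUTOSOMAL,
    CLASS_DUP,
    CLASS_UNCLASSIFIED,
    CLASS_X,
    CLASS_Y,
    OutlierThresholds,
    make_windows,
)

from conftest import make_sex_map, make_table


class TestDepthRatio:
    def test_forced_arithmetic(self):
        table = make_table([[0, 0, 0, 0]], depths=[[10, 10, 20, 20]],
                           samples=["m1", "m2", "f1", "f2"])
        r = depth_ratio(table, make_sex_map(2, 2))
        assert r[0] == pytest.approx(0.5)

    def test_equal_depths_unity(self):
        table = make_table([[0, 0, 0, 0]], depths=[[7, 9, 7, 9]],
                           samples=["m1", "m2", "f1", "f2"])
        assert depth_ratio(table, make_sex_map(2, 2))[0] == pytest.approx(1.0)

    def test_zero_female_mean_undefined(self):
        table = make_table([[0, 0, 0, 0]], depths=[[5, 5, 0, 0]],
                           samples=["m1", "m2", "f1", "f2"])
        assert np.isnan(depth_ratio(table, make_sex_map(2, 2))[0])


def quantile_type7(values, p):
    """Independent re-implementation of the type-7 quantile convention."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestIqrThresholds:
    def test_hand_evaluation_one_to_eight(self):
        t = iqr_thresholds(range(1, 9))
        assert t.q1 == pytest.approx(2.75)
        assert t.q3 == pytest.approx(6.25)
        assert t.low == pytest.approx(-2.5)
        assert t.high == pytest.approx(11.5)

    def test_constant_vector(self):
        t = iqr_thresholds([3.0] * 10)
        assert t.iqr == 0
        assert t.low == t.high == 3.0

    def test_matches_independent_quantile_oracle(self):
        rng = np.random.default_rng(5)
        for n in (4, 5, 17, 100):
            v = rng.normal(size=n)
            t = iqr_thresholds(v)
            assert t.q1 == pytest.approx(quantile_type7(v, 0.25), abs=1e-12)
            assert t.q3 == pytest.approx(quantile_type7(v, 0.75), abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_thresholds([1.0, 2.0, 3.0])

    def test_nonfinite_values_ignored(self):
        t_ref = iqr_thresholds([1, 2, 3, 4, 5])
        t = iqr_thresholds([1, 2, 3, 4, 5, np.nan, np.inf])
        assert t == t_ref


def stats_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=["scaffold", "pos", "fisher_p", "tested", "significant",
                 "H_m", "H_f", "delta_H", "depth_ratio_r"],
    )
    return df


class TestClassification:
    thresholds = OutlierThresholds(q1=0.9, q3=1.1)  # low 0.6, high 1.4

    def test_rule_application(self):
        rows = [
            ("s1", 100, 0.5, True, False, 0.0, 0.02, -0.02, 0.45),  # X
            ("s1", 200, 1e-9, True, True, 0.9, 0.0, 0.9, 1.0),      # Y
            ("s1", 300, 1e-9, True, True, 0.9, 0.0, 0.9, 1.6),      # dup
            ("s1", 400, 0.8, True, False, 0.1, 0.1, 0.0, 1.01),     # autosomal
            ("s1", 500, 0.8, True, False, 0.1, 0.1, 0.0, np.nan),   # unclassified
        ]
        out = classify_snps(stats_frame(rows), self.thresholds)
        assert list(out["linkage_class"]) == [
            CLASS_X, CLASS_Y, CLASS_DUP, CLASS_AUTOSOMAL, CLASS_UNCLASSIFIED
        ]

    def test_low_outlier_with_male_het_excess_not_x(self):
        rows = [("s1", 100, 0.5, True, False, 0.5, 0.1, 0.4, 0.45)]
        out = classify_snps(stats_frame(rows), self.thresholds)
        assert out["linkage_class"][0] == CLASS_AUTOSOMAL  # delta_H > 0

    def test_y_takes_precedence_over_x(self):
        # significant AND low-depth outlier with delta_H <= 0: Y wins
        rows = [("s1", 100, 1e-9, True, True, 0.0, 0.0, 0.0, 0.45)]
        out = classify_snps(stats_frame(rows), self.thresholds)
        assert out["linkage_class"][0] == CLASS_Y

    def test_invariant_to_site_order(self):
        rng = np.random.default_rng(8)
        rows = [
            ("s1", 100 * (i + 1), 0.5, True, bool(rng.random() < 0.2),
             0.2, 0.2, rng.normal(0, 0.2), rng.normal(1, 0.3))
            for i in range(50)
        ]
        df = stats_frame(rows)
        out = classify_snps(df, self.thresholds)
        perm = rng.permutation(len(df))
        out_perm = classify_snps(df.iloc[perm].reset_index(drop=True),
                                 self.thresholds)
        merged = out.merge(out_perm, on="pos", suffixes=("_a", "_b"))
        assert (merged["linkage_class_a"] == merged["linkage_class_b"]).all()


class TestWindows:
    layout = GenomeLayout(scaffolds=[("s1", 5_000_000)])

    def test_single_site_log2(self):
        rows = [("s1", 100, 0.5, True, False, 0, 0, 0.0, 0.5)]
        df = classify_snps(stats_frame(rows), OutlierThresholds(0.9, 1.1))
        win = window_depth_summary(df, self.layout)
        first = win.iloc[0]
        assert first["n_snps"] == 1
        assert first["mean_log2_ratio"] == pytest.approx(-1.0)

    def test_empty_window_emitted(self):
        rows = [("s1", 100, 0.5, True, False, 0, 0, 0.0, 1.0)]
        df = classify_snps(stats_frame(rows), OutlierThresholds(0.9, 1.1))
        win = window_depth_summary(df, self.layout)
        tail = win[win["start"] > 2_000_000]
        assert (tail["n_snps"] == 0).all()
        assert tail["mean_log2_ratio"].isna().all()

    def test_overlapping_windows_match_hand_computation(self):
        # sites at 0.4 Mb (r=1), 1.2 Mb (r=2), 2.6 Mb (r=4)
        rows = [
            ("s1", 400_000, 0.5, True, False, 0, 0, 0.0, 1.0),
            ("s1", 1_200_000, 0.5, True, False, 0, 0, 0.0, 2.0),
            ("s1", 2_600_000, 0.5, True, False, 0, 0, 0.0, 4.0),
        ]
        df = classify_snps(stats_frame(rows), OutlierThresholds(0.9, 1.1))
        win = window_depth_summary(df, self.layout, window=2_000_000,
                                   step=500_000)
        w1 = win[(win["start"] == 1)].iloc[0]  # [1, 2 Mb]: sites 1 and 2
        assert w1["n_snps"] == 2
        assert w1["mean_log2_ratio"] == pytest.approx((0 + 1) / 2)
        w2 = win[(win["start"] == 1_000_001)].iloc[0]  # [1, 3 Mb]: sites 2, 3
        assert w2["n_snps"] == 2
        assert w2["mean_log2_ratio"] == pytest.approx((1 + 2) / 2)

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            make_windows(1000, window=100, step=200)

    def test_terminal_partial_window_retained(self):
        wins = make_windows(2_500_000, 2_000_000, 500_000)
        assert wins[-1][1] == 2_500_000
        assert wins[0] == (1, 2_000_000)


def test_autosomal_simulation_produces_few_outlier_calls():
    """Pure-autosomal panels should classify essentially everything
    autosomal: outlier calls are distribution-driven only."""
    from sexscan import apply_filters, compute_site_stats
    from sexscan.synthetic_data import simulate_population

    from conftest import autosomal_sim_config

    for seed in (101, 202):
        sim = simulate_population(autosomal_sim_config(seed=seed))
        filtered, _ = apply_filters(sim.table)
        stats = classify_snps(compute_site_stats(filtered, sim.sex_map))
        frac_nonauto = (
            stats["linkage_class"].isin([CLASS_X, CLASS_Y, CLASS_DUP]).mean()
        )
        assert frac_nonauto <= 0.01
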