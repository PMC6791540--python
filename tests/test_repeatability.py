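import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumourmeter import (
    DataError,
    bland_altman,
    coefficient_of_variation,
    consistency_within,
    icc_by_operator_count,
    precision_band_summary,
    precision_points,
    relative_error_banding,
    welch_one_sided_tests,
)
from tumourmeter.repeatability import holm_adjust, icc2_1


def records_from(rows):
    df = pd.DataFrame(rows)
    for col in ("study_id", "instrument", "height", "area", "weight", "excluded"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def sph(l, w):
    return math.pi / 6 * l * w * w


class TestCV:
    def test_constant_values(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0

    def test_two_values(self):
        # sd = sqrt(2) with n-1 denominator, mean 3
        assert coefficient_of_variation([2, 4]) == pytest.approx(0.4714, abs=5e-5)

    def test_single_value_null(self):
        assert coefficient_of_variation([7]) is None

    def test_nonpositive_mean_null(self):
        assert coefficient_of_variation([-1.0, 1.0]) is None

    @given(
        values=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=10),
        c=st.floats(0.01, 100.0),
    )
    @settings(max_examples=50)
    def test_scale_invariance(self, values, c):
        base = coefficient_of_variation(values)
        scaled = coefficient_of_variation([c * v for v in values])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestPrecisionPoints:
    def test_two_operators_identical(self):
        recs = records_from(
            [
                {"mouse_id": "m1", "day": 1, "operator_id": "a", "length": 10, "width": 8},
                {"mouse_id": "m1", "day": 1, "operator_id": "b", "length": 10, "width": 8},
            ]
        )
        pts = precision_points(recs)
        assert len(pts) == 1
        assert pts.loc[0, "cv"] == 0.0
        assert pts.loc[0, "n_operators"] == 2

    def test_single_operator_no_point(self):
        recs = records_from(
            [{"mouse_id": "m1", "day": 1, "operator_id": "a", "length": 10, "width": 8}]
        )
        assert len(precision_points(recs)) == 0

    def test_three_operator_volumes(self):
        # pick widths so eq1 volumes are exactly 500, 600, 700
        def w_for(v, l=20.0):
            return math.sqrt(6 * v / (math.pi * l))

        recs = records_from(
            [
                {"mouse_id": "m1", "day": 1, "operator_id": op, "length": 20.0,
                 "width": w_for(v)}
                for op, v in zip("abc", (500, 600, 700))
            ]
        )
        pts = precision_points(recs)
        assert pts.loc[0, "cv"] == pytest.approx(100.0 / 600.0, abs=1e-6)

    def test_duplicate_same_operator_averaged_first(self):
        recs = records_from(
            [
                {"mouse_id": "m1", "day": 1, "operator_id": "a", "length": 10, "width": 8},
                {"mouse_id": "m1", "day": 1, "operator_id": "a", "length": 12, "width": 9},
                {"mouse_id": "m1", "day": 1, "operator_id": "b", "length": 11, "width": 8},
            ]
        )
        pts = precision_points(recs)
        va = (sph(10, 8) + sph(12, 9)) / 2
        vb = sph(11, 8)
        expected = np.std([va, vb], ddof=1) / np.mean([va, vb])
        assert pts.loc[0, "cv"] == pytest.approx(expected)

    def test_excluded_rows_dropped(self):
        recs = records_from(
            [
                {"mouse_id": "m1", "day": 1, "operator_id": "a", "length": 10, "width": 8,
                 "excluded": False},
                {"mouse_id": "m1", "day": 1, "operator_id": "b", "length": 10, "width": 8,
                 "excluded": True},
            ]
        )
        assert len(precision_points(recs)) == 0


class TestBandSummary:
    def test_all_below(self):
        pts = pd.DataFrame({"cv": [0.0, 0.1, 0.05]})
        assert precision_band_summary(pts) == (1.0, 0.0, 0.0)

    def test_half_half(self):
        pts = pd.DataFrame({"cv": [0.1, 0.3]})
        assert precision_band_summary(pts) == (0.5, 0.5, 0.0)

    def test_with_nulls(self):
        pts = pd.DataFrame({"cv": [0.1, 0.3, np.nan, np.nan]})
        assert precision_band_summary(pts) == (0.25, 0.25, 0.5)

    def test_empty_errors(self):
        with pytest.raises(DataError):
            precision_band_summary(pd.DataFrame({"cv": []}))

    @given(
        cvs=st.lists(
            st.one_of(st.floats(0.0, 2.0), st.none()), min_size=1, max_size=30
        )
    )
    @settings(max_examples=50)
    def test_fractions_sum_to_one_exactly(self, cvs):
        pts = pd.DataFrame({"cv": [np.nan if c is None else c for c in cvs]})
        below, above, null = precision_band_summary(pts)
        assert below + above + null == pytest.approx(1.0, abs=1e-12)


class TestICC:
    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(50, 10, size=(20, 1)) + rng.normal(0, 3, size=(20, 4))
        icc, lo, hi = icc2_1(y)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 4),
                "rater": np.tile(np.arange(4), 20),
                "score": y.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, "subject", "rater", "score")
        row = ref[ref.Type.isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert icc == pytest.approx(row.ICC, abs=1e-9)
        assert lo == pytest.approx(row.CI95[0], abs=0.01)
        assert hi == pytest.approx(row.CI95[1], abs=0.01)

    def test_zero_within_variance_gives_one(self):
        y = np.tile(np.array([[10.0], [20.0], [30.0]]), (1, 3))
        icc, lo, hi = icc2_1(y)
        assert icc == 1.0

    def test_high_between_to_within_ratio(self, rng):
        # sigma_b^2 : sigma_w^2 = 100 : 1 -> analytic ICC ~ 0.990
        y = rng.normal(0, 10, size=(500, 1)) + rng.normal(0, 1, size=(500, 3))
        icc, _, _ = icc2_1(y)
        assert icc > 0.97

    def test_pure_noise_icc_near_zero(self, rng):
        y = rng.normal(0, 1, size=(500, 3))  # no subject effect
        icc, lo, hi = icc2_1(y)
        assert lo < 0.0 < hi or abs(icc) < 0.1

    def test_variance_component_recovery(self):
        # sigma_b=4, sigma_o=1, sigma_e=2 -> ICC = 16/(16+1+4) = 0.7619;
        # with only k=3 raters the realised operator spread is noisy, so check
        # the Monte-Carlo average over independent datasets plus CI coverage
        n, k = 500, 3
        analytic = 16.0 / 21.0
        estimates, covered = [], 0
        for s in range(5):
            r = np.random.default_rng(900 + s)
            y = (
                r.normal(0, 4, size=(n, 1))
                + r.normal(0, 1, size=(1, k))
                + r.normal(0, 2, size=(n, k))
            )
            icc, lo, hi = icc2_1(y)
            estimates.append(icc)
            covered += lo < analytic < hi
        assert np.mean(estimates) == pytest.approx(analytic, abs=0.05)
        assert covered >= 3


class TestICCByOperatorCount:
    def test_stratification(self):
        rows = []
        rng = np.random.default_rng(7)
        for m in range(10):
            true_w = rng.uniform(6, 14)
            ops = ["a", "b"] if m < 6 else ["a", "b", "c"]
            for op in ops:
                rows.append(
                    {"mouse_id": f"m{m}", "day": 1, "operator_id": op,
                     "length": 1.2 * true_w + rng.normal(0, 0.1),
                     "width": true_w + rng.normal(0, 0.1)}
                )
        out = icc_by_operator_count(records_from(rows))
        assert set(out["n_operators"]) == {2, 3}
        assert (out["n_groups"] == [6, 4]).all()
        assert (out["icc"] > 0.9).all()

    def test_sparse_stratum_skipped(self):
        rows = [
            {"mouse_id": "m0", "day": 1, "operator_id": op, "length": 10, "width": 8}
            for op in "abcd"
        ]
        rows += [
            {"mouse_id": f"m{i}", "day": 1, "operator_id": op, "length": 10 + i,
             "width": 8}
            for i in (1, 2, 3)
            for op in "ab"
        ]
        out = icc_by_operator_count(records_from(rows))
        assert set(out["n_operators"]) == {2}  # single 4-operator group skipped


class TestBlandAltman:
    def test_perfect_agreement(self):
        w = np.array([0.5, 1.0, 1.5, 2.0])
        v = w * 1000.0  # mm^3 at rho = 1
        summary, pts = bland_altman(v, w)
        assert summary.mean_discrepancy == pytest.approx(0.0)
        assert summary.slope_m == pytest.approx(0.0)
        assert np.allclose(pts["difference"], 0.0)

    def test_constant_offset(self):
        w = np.array([0.5, 1.0, 1.5, 2.0])
        v = w * 1000.0 + 100.0
        summary, _ = bland_altman(v, w)
        assert summary.mean_discrepancy == pytest.approx(100.0)
        assert summary.slope_m == pytest.approx(0.0, abs=1e-9)

    def test_proportional_bias_recovered(self, rng):
        # V = 1.5 * Veq  =>  diff = 0.5 * Veq, mean = 1.25 * Veq,
        # closed form slope of diff on mean = 0.4
        w = rng.uniform(0.2, 3.0, 200)
        v = 1.5 * w * 1000.0
        summary, _ = bland_altman(v, w)
        assert summary.slope_m == pytest.approx(0.4, abs=1e-9)
        assert summary.slope_ci[0] < 0.4 < summary.slope_ci[1] or summary.r_squared == 1.0

    def test_mean_difference_identity(self, rng):
        v = rng.uniform(100, 2000, 50)
        w = rng.uniform(0.1, 2.0, 50)
        summary, _ = bland_altman(v, w)
        assert summary.mean_discrepancy == pytest.approx(v.mean() - (w * 1000).mean())

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            bland_altman([1.0, 2.0], [1.0])


class TestRelativeErrorBanding:
    def test_exact_identity(self):
        w = np.array([0.5, 1.0, 2.0])
        v = w * 1000.0
        out = relative_error_banding(v, w)
        assert out["volume_gt_weight"] == 0.0
        assert out["abs_err_lt_0.2"] == 1.0
        assert out["weight_ge_half_volume"] == 1.0

    def test_single_pair_thirty_percent(self):
        out = relative_error_banding([1300.0], [1.0])
        assert out["volume_gt_weight"] == 1.0
        assert out["abs_err_lt_0.5"] == 1.0
        assert out["abs_err_lt_0.2"] == 0.0

    def test_zero_weight_dropped(self):
        out = relative_error_banding([1000.0, 1000.0], [1.0, 0.0])
        assert out["n"] == 1
        assert out["n_dropped"] == 1

    def test_weight_ge_half_volume_band(self):
        # Veq = 2g, weight 1g -> ratio exactly 0.5, counts as >= half
        out = relative_error_banding([2000.0], [1.0])
        assert out["weight_ge_half_volume"] == 1.0
        out = relative_error_banding([2001.0], [1.0])
        assert out["weight_ge_half_volume"] == 0.0


def scan_cal_frames(scan_rows, cal_rows):
    return records_from(scan_rows), records_from(cal_rows)


class TestConsistencyWithin:
    def test_identical_pairs_all_within(self):
        scan, cal = scan_cal_frames(
            [{"mouse_id": "m1", "day": 1, "operator_id": "s", "length": 10, "width": 8}],
            [{"mouse_id": "m1", "day": 1, "operator_id": "c", "length": 10, "width": 8}],
        )
        out = consistency_within(scan, cal, tolerance=0.5)
        assert out["length"]["fraction_within"] == 1.0
        assert out["width"]["fraction_within"] == 1.0

    def test_two_thirds_within_three(self):
        cal_rows = [
            {"mouse_id": f"m{i}", "day": 1, "operator_id": "c", "length": 10.0, "width": 8.0}
            for i in range(3)
        ]
        scan_rows = [
            {"mouse_id": f"m{i}", "day": 1, "operator_id": "s", "length": 10.0 + d,
             "width": 8.0}
            for i, d in enumerate((-2.0, 0.0, 4.0))
        ]
        scan, cal = scan_cal_frames(scan_rows, cal_rows)
        out = consistency_within(scan, cal, tolerance=3.0)
        assert out["length"]["fraction_within"] == pytest.approx(2.0 / 3.0)

    def test_multiple_callipers_averaged(self):
        cal_rows = [
            {"mouse_id": "m1", "day": 1, "operator_id": "c1", "length": 9.0, "width": 8},
            {"mouse_id": "m1", "day": 1, "operator_id": "c2", "length": 11.0, "width": 8},
        ]
        scan_rows = [
            {"mouse_id": "m1", "day": 1, "operator_id": "s", "length": 12.9, "width": 8}
        ]
        scan, cal = scan_cal_frames(scan_rows, cal_rows)
        out = consistency_within(scan, cal, tolerance=3.0)
        assert out["length"]["fraction_within"] == 1.0  # |12.9 - 10| < 3

    def test_unmatched_scans_counted(self):
        scan, cal = scan_cal_frames(
            [
                {"mouse_id": "m1", "day": 1, "operator_id": "s", "length": 10, "width": 8},
                {"mouse_id": "m2", "day": 9, "operator_id": "s", "length": 10, "width": 8},
            ],
            [{"mouse_id": "m1", "day": 1, "operator_id": "c", "length": 10, "width": 8}],
        )
        out = consistency_within(scan, cal)
        assert out["length"]["n_pairs"] == 1
        assert out["length"]["n_unmatched"] == 1

    def test_infinite_tolerance_is_one(self, rng):
        n = 20
        cal_rows = [
            {"mouse_id": f"m{i}", "day": 1, "operator_id": "c",
             "length": rng.uniform(5, 20), "width": rng.uniform(3, 10)}
            for i in range(n)
        ]
        scan_rows = [
            {"mouse_id": f"m{i}", "day": 1, "operator_id": "s",
             "length": rng.uniform(5, 20), "width": rng.uniform(3, 10)}
            for i in range(n)
        ]
        scan, cal = scan_cal_frames(scan_rows, cal_rows)
        out = consistency_within(scan, cal, tolerance=np.inf)
        assert out["length"]["fraction_within"] == 1.0
        assert out["width"]["fraction_within"] == 1.0


class TestWelch:
    def test_null_case_large_n(self, rng):
        a = rng.normal(0, 1, 10_000)
        b = rng.normal(0, 1, 10_000)
        out = welch_one_sided_tests([a], [b], labels=["null"])
        assert out.loc[0, "p_adj"] > 0.05

    def test_five_sigma_separation(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        out = welch_one_sided_tests([a], [b], labels=["sep"], alternative="less")
        assert out.loc[0, "p_adj"] < 1e-6

    def test_single_comparison_equals_raw(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 30)
        out = welch_one_sided_tests([a], [b])
        assert out.loc[0, "p_adj"] == pytest.approx(out.loc[0, "p_raw"])

    def test_degenerate_flagged(self):
        out = welch_one_sided_tests([[3.0, 3.0]], [[3.0, 3.0]])
        assert out.loc[0, "p_raw"] == 1.0
        assert bool(out.loc[0, "degenerate"])

    def test_holm_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(0, 1, 12)
        mine = holm_adjust(p)
        _, ref, _, _ = sm.multipletests(p, method="holm")
        assert np.allclose(mine, ref)
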