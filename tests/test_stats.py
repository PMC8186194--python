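import numpy as np
import pytest

from ctrkit.stats import (
    bland_altman,
    classification_eval,
    compare_series,
    cv_percent,
    find_cutoffs,
    linear_fit_r2,
    paired_t_test,
    r2_category,
    rank_auc,
)

# worked example from the module contract: three pairs, absolute diffs
# (-0.02, 0.02, 0.00), n-1 SD 0.020, grand mean 0.55
HAND_A = [0.50, 0.60, 0.55]
HAND_B = [0.52, 0.58, 0.55]


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert res.bias == 0.0
        assert res.sd_diff == 0.0
        assert (res.loa_lower, res.loa_upper) == (0.0, 0.0)
        assert res.cv == 0.0

    def test_hand_computed_absolute_mode(self):
        res = bland_altman(HAND_A, HAND_B, "absolute")
        assert res.bias == pytest.approx(0.000, abs=1e-12)
        assert res.sd_diff == pytest.approx(0.020, abs=1e-12)
        assert res.cv == pytest.approx(100 * 0.02 / 0.55, abs=1e-9)  # 3.636...%

    def test_hand_computed_percent_mode(self):
        # independent arithmetic: d_i = 100 (a-b) / ((a+b)/2)
        d = [100 * (-0.02) / 0.51, 100 * 0.02 / 0.59, 0.0]
        mean_d = sum(d) / 3
        sd_d = (sum((x - mean_d) ** 2 for x in d) / 2) ** 0.5
        res = bland_altman(HAND_A, HAND_B, "percent_of_pair_mean")
        assert res.bias == pytest.approx(mean_d)
        assert res.sd_diff == pytest.approx(sd_d)
        assert res.loa_lower == pytest.approx(mean_d - 1.96 * sd_d)
        assert res.loa_upper == pytest.approx(mean_d + 1.96 * sd_d)

    def test_scale_invariance_of_percent_mode(self):
        a = np.array([0.45, 0.52, 0.61, 0.58])
        b = np.array([0.44, 0.54, 0.60, 0.57])
        r1 = bland_altman(a, b)
        r2 = bland_altman(3.7 * a, 3.7 * b)
        assert r2.bias == pytest.approx(r1.bias)
        assert r2.sd_diff == pytest.approx(r1.sd_diff)
        assert r2.cv == pytest.approx(r1.cv)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bland_altman([0.5], [0.5])
        with pytest.raises(ValueError):
            bland_altman([0.5, -0.1], [0.5, 0.5])
        with pytest.raises(ValueError):
            bland_altman(HAND_A, HAND_B, "furlongs")


class TestCvPercent:
    def test_identical_pairs_zero(self):
        assert cv_percent([0.5, 0.6], [0.5, 0.6]) == 0.0

    def test_hand_table(self):
        assert cv_percent(HAND_A, HAND_B) == pytest.approx(3.6364, abs=1e-3)

    def test_closed_form_recovery(self):
        # independent relative errors: cv ~= 100 sqrt(s1^2 + s2^2) (constant truth)
        rng = np.random.default_rng(10)
        s1, s2, n = 0.012, 0.02, 200_000
        t = 0.55
        a = t * (1 + rng.normal(0, s1, n))
        b = t * (1 + rng.normal(0, s2, n))
        assert cv_percent(a, b) == pytest.approx(100 * np.hypot(s1, s2), rel=0.01)


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        res = linear_fit_r2(x, 2 * x + 1)
        assert res.r2 == pytest.approx(1.0)
        assert res.category == "excellent"
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_independent_y_near_zero(self):
        rng = np.random.default_rng(11)
        x = rng.random(5000)
        y = rng.random(5000)
        res = linear_fit_r2(x, y)
        assert res.r2 < 0.01
        assert res.category == "poor"

    def test_five_point_normal_equations_oracle(self):
        x = np.array([0.42, 0.51, 0.48, 0.60, 0.55])
        y = np.array([0.44, 0.50, 0.49, 0.58, 0.57])
        # normal equations solved independently
        n = len(x)
        sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        ss_res = float(np.sum((y - slope * x - intercept) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        res = linear_fit_r2(x, y)
        assert res.slope == pytest.approx(slope)
        assert res.intercept == pytest.approx(intercept)
        assert res.r2 == pytest.approx(1 - ss_res / ss_tot)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit_r2([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize(
        "r2,category",
        [(0.49, "poor"), (0.5, "moderate"), (0.75, "moderate"),
         (0.76, "good"), (0.9, "good"), (0.91, "excellent")],
    )
    def test_category_banding(self, r2, category):
        assert r2_category(r2) == category


class TestPairedT:
    def test_equal_series(self):
        res = paired_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_symmetric_differences(self):
        a = np.array([1.0, -1.0, 2.0, -2.0]) + 10
        b = np.full(4, 10.0)
        res = paired_t_test(a, b)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_constant_nonzero_difference_flagged(self):
        res = paired_t_test([1.1, 2.1, 3.1], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isinf(res.t) and res.p == 0.0

    def test_textbook_formula_oracle(self):
        from scipy import stats as sps

        a = np.array([0.52, 0.49, 0.55, 0.61, 0.47, 0.58])
        b = np.array([0.50, 0.51, 0.53, 0.60, 0.49, 0.55])
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t), len(d) - 1)
        res = paired_t_test(a, b)
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(p)


def trapezoid_auc(values, labels):
    """Independent oracle: trapezoidal integration of the empirical ROC."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, int)
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(values))[::-1], [-np.inf]])
    tpr, fpr = [], []
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    for thr in thresholds:
        pred = values > thr
        tpr.append(np.sum(pred & (labels == 1)) / n_pos)
        fpr.append(np.sum(pred & (labels == 0)) / n_neg)
    return float(np.trapezoid(tpr, fpr))


FOUR_POINT = (np.array([0.40, 0.52, 0.48, 0.55]), np.array([0, 0, 1, 1]))


class TestClassification:
    def test_perfect_separation(self):
        values = np.array([0.3, 0.35, 0.7, 0.75])
        labels = np.array([0, 0, 1, 1])
        res = classification_eval(values, labels, 0.5)
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert res.accuracy == 100.0 and res.f1 == 1.0 and res.auc == 1.0

    def test_four_point_hand_example(self):
        values, labels = FOUR_POINT
        res = classification_eval(values, labels, 0.5)
        assert res.sensitivity == 50.0
        assert res.specificity == 50.0
        assert res.accuracy == 50.0
        assert res.f1 == pytest.approx(0.5)
        assert res.auc == pytest.approx(0.75)  # 3 of 4 pos/neg pairs ordered

    def test_cutoff_below_all_values(self):
        values, labels = FOUR_POINT
        res = classification_eval(values, labels, 0.1)
        assert res.sensitivity == 100.0 and res.specificity == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classification_eval([0.4, 0.5], [1, 1], 0.5)

    def test_auc_rank_vs_trapezoid_exhaustive(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            values = rng.choice([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], size=n)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert rank_auc(values, labels) == pytest.approx(trapezoid_auc(values, labels))


class TestFindCutoffs:
    def test_four_point_max_sensitivity(self):
        values, labels = FOUR_POINT
        res = find_cutoffs(values, labels)["max_sensitivity"]
        assert res.cutoff == pytest.approx(0.44)  # midpoint below smallest positive
        assert res.sensitivity == 100.0
        assert res.specificity == 50.0

    def test_four_point_optimum_tiebreak_low(self):
        values, labels = FOUR_POINT
        res = find_cutoffs(values, labels)["optimum"]
        # J ties at 0.5 for candidates {0.44, 0.535}; lowest wins
        assert res.cutoff == pytest.approx(0.44)

    def test_perfectly_separated(self):
        values = np.array([0.3, 0.35, 0.7, 0.75])
        labels = np.array([0, 0, 1, 1])
        cuts = find_cutoffs(values, labels)
        for kind in ("optimum", "max_sensitivity"):
            res = cuts[kind]
            assert 0.35 < res.cutoff < 0.7
            assert res.sensitivity == 100.0 and res.specificity == 100.0

    def test_standard_cutoff_passthrough(self):
        values, labels = FOUR_POINT
        assert find_cutoffs(values, labels)["standard"].cutoff == 0.5

    def test_youden_matches_bruteforce_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            values = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            got = find_cutoffs(values, labels)
            # brute force with independent confusion counting
            uniq = np.sort(np.unique(values))
            candidates = [-np.inf] + [(u + v) / 2 for u, v in zip(uniq, uniq[1:])] + [np.inf]
            best_j, best_cut, ms_cut = -np.inf, None, -np.inf
            for cut in candidates:
                pred = values > cut
                tp = np.sum(pred & (labels == 1))
                fn = np.sum(~pred & (labels == 1))
                tn = np.sum(~pred & (labels == 0))
                fp = np.sum(pred & (labels == 0))
                j = tp / (tp + fn) + tn / (tn + fp) - 1
                if j > best_j + 1e-12:
                    best_j, best_cut = j, cut
                if fn == 0 and cut > ms_cut:
                    ms_cut = cut
            assert got["optimum"].cutoff == pytest.approx(best_cut)
            assert got["max_sensitivity"].cutoff == pytest.approx(ms_cut)


class TestCompareSeries:
    def test_method_vs_itself(self):
        import pandas as pd

        s = pd.Series([0.5, 0.55, 0.6, 0.45], index=list("abcd"))
        row = compare_series(s, s, "self")
        assert row.agreement_pct.bias == 0.0
        assert row.agreement_pct.cv == 0.0
        assert row.correlation.r2 == pytest.approx(1.0)

    def test_missing_cases_excluded_and_counted(self):
        import pandas as pd

        a = pd.Series([0.5, 0.55, 0.6, 0.45], index=list("abcd"))
        b = pd.Series([0.51, np.nan, 0.62, 0.44], index=list("abcd"))
        row = compare_series(a, b, "x")
        assert row.n_pairs == 3 and row.n_excluded == 1

    def test_no_overlap_is_error(self):
        import pandas as pd

        a = pd.Series([0.5], index=["a"])
        b = pd.Series([0.6], index=["b"])
        with pytest.raises(ValueError):
            compare_series(a, b, "x")

    def test_range_restriction_lowers_expected_r2(self):
        # restricting x-range cannot raise expected R^2 for fixed noise
        rng = np.random.default_rng(21)
        full, sub = [], []
        for _ in range(100):
            x = rng.uniform(0.35, 0.85, 400)
            y = x + rng.normal(0, 0.05, 400)
            full.append(linear_fit_r2(x, y).r2)
            keep = x > 0.52
            sub.append(linear_fit_r2(x[keep], y[keep]).r2)
        assert np.mean(sub) < np.mean(full)
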