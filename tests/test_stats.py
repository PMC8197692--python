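import itertools

import numpy as np
import pytest
import scipy.stats as sps

from oracles import spearman_permutation, wilcoxon_enumeration
from robustpet.stats import (
    ComparisonResult,
    PairedSample,
    StatConfig,
    bland_altman,
    build_report,
    classify_feature,
    compare_tables,
    spearman,
    wilcoxon_signed_rank,
)


def _sample(a, b):
    return PairedSample("f", np.asarray(a, float), np.asarray(b, float))


class TestWilcoxon:
    def test_identical_arms_give_p_one(self):
        assert wilcoxon_signed_rank(_sample([1, 2, 3], [1, 2, 3])) == 1.0

    def test_six_positive_differences_exact(self):
        p = wilcoxon_signed_rank(_sample([2, 4, 6, 8, 10, 12],
                                         [1, 2, 3, 4, 5, 6]))
        assert p == pytest.approx(2 / 64)

    @pytest.mark.parametrize("n", range(3, 11))
    def test_exact_p_matches_sign_enumeration(self, n):
        rng = np.random.default_rng(n)
        for rep in range(8):
            d = np.round(rng.normal(size=n), 1)  # rounding creates ties
            d = np.where(d == 0, 0.1, d)
            p_impl = wilcoxon_signed_rank(_sample(d, np.zeros(n)))
            p_oracle = wilcoxon_enumeration(d)
            assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.normal(size=10)
            b = a + rng.normal(size=10)
            p = wilcoxon_signed_rank(_sample(a, b))
            assert p == pytest.approx(
                sps.wilcoxon(a, b, mode="exact").pvalue, abs=1e-12
            )

    def test_normal_approx_close_to_scipy_large_n(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=40)
        b = a + rng.normal(size=40) * 0.5
        p = wilcoxon_signed_rank(_sample(a, b))
        ref = sps.wilcoxon(a, b, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_fp_noise_below_tolerance_treated_as_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a * (1 + 1e-13)  # rounding-level, sign-consistent
        assert wilcoxon_signed_rank(_sample(a, b)) == 1.0

    def test_type_i_error_rate_under_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(size=30)
            b = a + rng.normal(size=30) * 0.1
            rejections += wilcoxon_signed_rank(_sample(a, b)) <= 0.05
        # binomial 95% band around alpha = 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 1.96 * se + 1e-9


class TestSpearman:
    def test_monotone_gives_plus_one(self):
        r, p = spearman(_sample([1, 2, 3, 4, 5], [10, 20, 25, 40, 100]))
        assert r == pytest.approx(1.0)

    def test_antimonotone_gives_minus_one(self):
        r, _ = spearman(_sample([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]))
        assert r == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_n6_matches_720_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        r, p = spearman(_sample(a, b))
        r_ref, p_ref = spearman_permutation(a, b)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_constant_margin_undefined(self):
        r, p = spearman(_sample([1, 1, 1, 1, 1], [1, 2, 3, 4, 5]))
        assert np.isnan(r) and np.isnan(p)

    def test_large_n_t_approximation_close_to_scipy(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=25)
        b = a + rng.normal(size=25)
        r, p = spearman(_sample(a, b))
        ref = sps.spearmanr(a, b)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestBlandAltman:
    def test_identical_samples(self):
        bias, ci, _ = bland_altman(_sample([1, 2, 3], [1, 2, 3]))
        assert bias == 0.0 and ci[0] <= 0.0 <= ci[1]

    def test_doubling_closed_form(self):
        a = np.array([1.0, 2, 3, 4, 5])
        bias, ci, loa = bland_altman(_sample(a, 2 * a))
        assert bias == pytest.approx(-200.0 / 3)
        assert ci[0] == pytest.approx(ci[1])  # SD = 0
        assert loa[0] == pytest.approx(bias)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(1, 2, 10)
        b = rng.uniform(1, 2, 10)
        bias_ab, _, _ = bland_altman(_sample(a, b))
        bias_ba, _, _ = bland_altman(_sample(b, a))
        assert bias_ab == pytest.approx(-bias_ba)

    def test_zero_mean_pairs_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            bias, _, _ = bland_altman(_sample([1.0, 1.0, -2.0], [1.0, 3.0, 2.0]))
        assert np.isfinite(bias)


class TestClassification:
    def _result(self, pw, r, ps, n=27):
        res = ComparisonResult("f", n, wilcoxon_p=pw, spearman_r=r,
                               spearman_p=ps, ba_ci_95=(-1.0, 1.0))
        return res

    def test_robust_and_correlated(self):
        cfg = StatConfig(K=133)
        res = classify_feature(self._result(0.2, 0.95, 1e-6), cfg)
        assert res.robust and res.strongly_correlated

    def test_suvmean_pattern_not_robust_but_correlated(self):
        cfg = StatConfig(K=133)
        res = classify_feature(self._result(0.01, 0.99, 1e-9), cfg)
        assert not res.robust and res.strongly_correlated

    def test_bonferroni_threshold_blocks_weak_p(self):
        cfg = StatConfig(K=133)
        res = classify_feature(self._result(0.5, 0.85, 0.01), cfg)
        assert not res.strongly_correlated  # 0.01 > 0.05/133

    def test_untestable_never_robust(self):
        cfg = StatConfig()
        res = ComparisonResult("f", 3, wilcoxon_p=1.0, testable=False)
        res = classify_feature(res, cfg)
        assert not res.robust


class TestReport:
    def _tables(self, n=8, k=6, seed=0, shift=0.0):
        import pandas as pd

        rng = np.random.default_rng(seed)
        idx = [f"l{i}" for i in range(n)]
        cols = [f"f{j}" for j in range(k)]
        a = pd.DataFrame(rng.uniform(1, 2, (n, k)), index=idx, columns=cols)
        b = a + shift
        return a, b

    def test_identical_tables_fully_robust(self):
        a, b = self._tables()
        report = build_report({"x": (a, b.copy())})
        assert report.robust_set("x") == set(a.columns)
        assert report.intersection() == set(a.columns)

    def test_intersection_subset_of_each_factor(self):
        a, b = self._tables(shift=0.0)
        c, d = self._tables(seed=1, shift=0.5)
        report = build_report({"same": (a, b), "shifted": (c, d)})
        inter = report.intersection()
        assert inter <= report.robust_set("same")
        assert inter <= report.robust_set("shifted")
        assert report.robust_set("shifted") == set()  # systematic shift

    def test_counts_consistent_with_flags(self):
        a, b = self._tables(seed=2, shift=0.3)
        report = build_report({"x": (a, b)})
        s = report.summary()
        assert s["x"]["n_robust"] == len(report.robust_set("x"))
        assert s["x"]["n_strongly_correlated"] == len(report.correlated_set("x"))

    def test_misaligned_ids_hard_error(self):
        a, b = self._tables()
        b = b.iloc[::-1]
        from robustpet.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            compare_tables(a, b)

    def test_k_reset_to_tested_features(self):
        a, b = self._tables(n=8, k=10, seed=3)
        b = a * 1.0
        b.iloc[:, 0] += np.linspace(0.01, 0.1, 8)
        res = compare_tables(a, b)
        assert len(res) == 10
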