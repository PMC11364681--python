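import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import perivene as pv
from perivene.cohort_statistics import (
    compare_groups,
    correct_for_icv,
    correlate,
    icc_2_1,
    ks_normality,
    run_cohort_analysis,
)


class TestCorrectForIcv:
    def test_arithmetic(self):
        assert correct_for_icv(100.0, 1000.0) == pytest.approx(0.1)

    def test_zero_volume(self):
        assert correct_for_icv(0.0, 1234.0) == 0.0

    def test_zero_icv_error(self):
        with pytest.raises(ValueError):
            correct_for_icv(100.0, 0.0)

    def test_vectorized(self):
        out = correct_for_icv(np.array([100.0, 50.0]), np.array([1000.0, 500.0]))
        np.testing.assert_allclose(out, [0.1, 0.1])


class TestKsNormality:
    def test_normal_sample_classified_normal(self):
        x = np.random.default_rng(0).standard_normal(1000)
        res = ks_normality(x)
        assert res.normal and res.p_value >= 0.05
        # oracle: reference Lilliefors implementation on the same draws
        from statsmodels.stats.diagnostic import lilliefors

        d_ref, p_ref = lilliefors(x, dist="norm")
        assert res.estimate == pytest.approx(d_ref, abs=1e-12)
        assert (p_ref >= 0.05) == res.normal

    def test_exponential_sample_classified_nonnormal(self):
        x = np.random.default_rng(1).exponential(1.0, size=1000)
        res = ks_normality(x)
        assert not res.normal and res.p_value < 0.05
        from statsmodels.stats.diagnostic import lilliefors

        _, p_ref = lilliefors(x, dist="norm")
        assert p_ref < 0.05

    def test_constant_sample_error(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(10))

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])


def _spearman_formula(x, y):
    """Oracle: 1 - 6 sum d^2 / (n (n^2 - 1)) on tie-free data."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    return 1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))


class TestCorrelate:
    def test_monotone_transform_rho_one(self):
        x = np.arange(1.0, 9.0)
        res = correlate(x, x**2, method="spearman")
        assert res.estimate == pytest.approx(1.0)

    def test_reversed_rho_minus_one(self):
        x = np.arange(1.0, 9.0)
        res = correlate(x, x[::-1], method="spearman")
        assert res.estimate == pytest.approx(-1.0)

    def test_formula_oracle_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        res = correlate(x, y, method="spearman")
        assert np.sum((stats.rankdata(x) - stats.rankdata(y)) ** 2) == 4
        assert res.estimate == pytest.approx(0.8)
        assert res.estimate == pytest.approx(_spearman_formula(x, y))

    def test_formula_oracle_random_tiefree(self, rng):
        x = rng.permutation(12).astype(float)
        y = rng.permutation(12).astype(float)
        res = correlate(x, y, method="spearman")
        assert res.estimate == pytest.approx(_spearman_formula(x, y), abs=1e-12)

    def test_exact_permutation_p_oracle(self, rng):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.8, 5.0])
        res = correlate(x, y, method="spearman")
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(res.estimate) - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total)

    def test_swap_symmetry(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        for method in ("pearson", "spearman"):
            a = correlate(x, y, method=method)
            b = correlate(y, x, method=method)
            assert a.estimate == pytest.approx(b.estimate)
            assert a.p_value == pytest.approx(b.p_value)

    def test_pearson_matches_scipy(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        res = correlate(x, y, method="pearson")
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.estimate == pytest.approx(r_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_auto_gating(self):
        rng = np.random.default_rng(3)  # seed chosen so the normal draws pass KS
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        assert correlate(x, y, method="auto").method == "pearson"
        assert correlate(x, np.exp(3 * y), method="auto").method == "spearman"

    def test_errors(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [3.0, 4.0])


def _u_stat(x, y):
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)


def _mw_enumeration_p(x, y):
    """Oracle: full enumeration of all C(n+m, n) group assignments (tie-free);
    two-sided p from the symmetric exact U distribution."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = _u_stat(x, y)
    center = n * m / 2.0
    count = total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = _u_stat(xs, ys)
        count += abs(u - center) >= abs(u_obs - center) - 1e-9
        total += 1
    return count / total


class TestCompareGroups:
    def test_enumeration_example(self):
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], method="mann_whitney")
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert _mw_enumeration_p(
            np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        ) == pytest.approx(0.1)

    def test_enumeration_oracle_random(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=6) + 0.8
        res = compare_groups(x, y, method="mann_whitney")
        assert res.p_value == pytest.approx(_mw_enumeration_p(x, y))
        assert res.estimate == pytest.approx(_u_stat(x, y))

    def test_swap_symmetry(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=9)
        a = compare_groups(x, y, method="mann_whitney")
        b = compare_groups(y, x, method="mann_whitney")
        assert a.estimate == pytest.approx(len(x) * len(y) - b.estimate)
        assert a.p_value == pytest.approx(b.p_value)

    def test_ties_use_asymptotic(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 4.0, 4.0, 6.0, 7.0])
        res = compare_groups(x, y, method="mann_whitney")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_t_matches_welch(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=35) + 0.3
        res = compare_groups(x, y, method="t")
        t_ref, p_ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.estimate == pytest.approx(t_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_auto_gating(self):
        rng = np.random.default_rng(3)  # seed chosen so the normal draws pass KS
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        assert compare_groups(x, y, method="auto").method == "t"
        assert compare_groups(np.exp(3 * x), np.exp(3 * y), method="auto").method == "mann_whitney"

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0, 2.0])
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestIcc21:
    def test_identical_raters(self):
        m = np.column_stack([np.arange(1.0, 6.0)] * 2)
        res = icc_2_1(m)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_low <= res.icc <= res.ci_high <= 1.0

    def test_hand_computed_anova_example(self):
        m = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
        res = icc_2_1(m)
        assert res.msr == pytest.approx(10.0 / 3.0)
        assert res.msc == pytest.approx(2.0)
        assert res.mse == pytest.approx(0.0, abs=1e-12)
        assert res.icc == pytest.approx(10.0 / 13.0)

    def test_negative_value_under_ln1p_error(self):
        m = np.array([[1.0, 2.0], [-0.5, 3.0]])
        with pytest.raises(ValueError):
            icc_2_1(m, transform="ln1p")

    def test_incomplete_matrix_error(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError):
            icc_2_1(m)

    def test_ln1p_transform_equals_log_domain(self, rng):
        m = rng.lognormal(4.0, 1.0, size=(12, 2))
        a = icc_2_1(m, transform="ln1p")
        b = icc_2_1(np.log1p(m), transform="none")
        assert a.icc == pytest.approx(b.icc)

    def test_against_pingouin_oracle(self, rng):
        import pingouin as pg

        m = rng.normal(10.0, 2.0, size=(15, 3)) + rng.normal(0, 1.5, size=(15, 1))
        res = icc_2_1(m)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 3),
                "rater": np.tile(np.arange(3), 15),
                "score": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci = row["CI95"] if "CI95" in ref.columns else row["CI95%"]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.ci_low == pytest.approx(ci[0], abs=0.006)  # pingouin rounds the CI
        assert res.ci_high == pytest.approx(ci[1], abs=0.006)

    def test_ci_brackets_estimate(self, rng):
        for _ in range(5):
            m = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1)) * 2
            res = icc_2_1(m)
            assert res.ci_low <= res.icc <= res.ci_high <= 1.0


class TestRunCohortAnalysis:
    def test_report_shape(self):
        cohort = pv.generate_cohort(pv.cohort_params_from_calibration(seed=1))
        report = run_cohort_analysis(cohort)
        assert set(report["analyses"]) == {
            "dv_corrected",
            "dv_uncorrected",
            "psd_corrected",
            "psd_uncorrected",
        }
        assert "cross_correlation" in report
        assert report["n"] == 98

    def test_lognormal_cohort_dispatches_spearman(self):
        cohort = pv.generate_cohort(pv.cohort_params_from_calibration(seed=2))
        report = run_cohort_analysis(cohort)
        for key in report["analyses"]:
            assert report["analyses"][key]["age_association"]["method"] == "spearman"
            assert report["analyses"][key]["sex_comparison"]["method"] == "mann_whitney"
            assert not report["analyses"][key]["ks"]["normal"]

    def test_normal_cohort_dispatches_pearson(self):
        rng = np.random.default_rng(7)
        n = 150
        cohort = pd.DataFrame(
            {
                "id": np.arange(n),
                "age": rng.normal(50.0, 10.0, n),
                "sex": rng.choice(["M", "F"], n),
                "dv_volume": rng.normal(500.0, 20.0, n),
                "psd_volume": rng.normal(800.0, 30.0, n),
                "icv": np.full(n, 1000.0),
            }
        )
        report = run_cohort_analysis(cohort)
        assert report["analyses"]["dv_corrected"]["age_association"]["method"] == "pearson"
        assert report["analyses"]["dv_corrected"]["sex_comparison"]["method"] == "t"

    def test_recovers_configured_spearman_on_large_cohort(self):
        cohort = pv.generate_cohort(pv.cohort_params_from_calibration(n=50_000, seed=3))
        report = run_cohort_analysis(cohort)
        assert report["analyses"]["dv_corrected"]["age_association"]["estimate"] == pytest.approx(
            -0.330, abs=0.05
        )
        assert report["analyses"]["psd_corrected"]["age_association"]["estimate"] == pytest.approx(
            0.385, abs=0.05
        )
        # no built-in association between the two corrected volumes
        assert abs(report["cross_correlation"]["estimate"]) < 0.05

    def test_missing_column_error(self):
        with pytest.raises(ValueError):
            run_cohort_analysis(pd.DataFrame({"age": [1, 2, 3]}))

    def test_nonpositive_icv_error(self):
        cohort = pv.generate_cohort(pv.cohort_params_from_calibration(seed=4))
        cohort.loc[0, "icv"] = 0.0
        with pytest.raises(ValueError):
            run_cohort_analysis(cohort)
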