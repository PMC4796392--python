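import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mmcompare.multi import (
    PValueFamily,
    PerformanceMatrix,
    adjusted_r2,
    anova_oneway,
    chi2_two_methods,
    chi2_vs_expected,
    correlated_chi2,
    f_test_nested,
    fwer,
    grouping_layout,
    hochberg_step_up,
    holm_bonferroni,
    layout_from_matrix,
    studentized_range_quantile,
    tukey_hsd,
    whiten,
    whiten_covariance,
)
from mmcompare.pairwise import two_sample_t
from mmcompare.simulate import gen_performance_matrix
from tests.conftest import PFAMILY_1, PFAMILY_2


class TestFwer:
    def test_five_at_005(self):
        # exact value 0.22622; prints as 0.227 after upstream rounding
        assert fwer(0.05, 5) == pytest.approx(0.227, abs=1e-3)

    def test_five_at_001(self):
        assert fwer(0.01, 5) == pytest.approx(0.049, abs=5e-4)

    def test_single_test_identity(self):
        assert fwer(0.3, 1) == pytest.approx(0.3)


def family(d, alpha=0.05):
    return PValueFamily(tuple(d), tuple(d.values()), alpha)


class TestHolmBonferroni:
    def test_family_one_all_significant(self):
        res = holm_bonferroni(family(PFAMILY_1))
        assert all(res.significant.values())
        assert res.order == ("C", "F", "D", "B", "E")

    def test_family_two_partial(self):
        res = holm_bonferroni(family(PFAMILY_2))
        assert {k for k, v in res.significant.items() if v} == {"D", "B", "F"}

    def test_all_ones_none(self):
        res = holm_bonferroni(family({"a": 1.0, "b": 1.0}))
        assert not any(res.significant.values())

    def test_stop_at_first_failure_even_if_later_pass(self):
        # second p fails its 0.025 threshold; third would pass its own 0.05
        # threshold but the step-down stop rule must block it
        res = holm_bonferroni(family({"x": 0.001, "y": 0.04, "z": 0.03}))
        assert res.significant == {"x": True, "z": False, "y": False}


class TestHochberg:
    def test_family_two_all_significant(self):
        res = hochberg_step_up(family(PFAMILY_2))
        assert all(res.significant.values())

    def test_all_ones_none(self):
        res = hochberg_step_up(family({"a": 1.0, "b": 1.0, "c": 1.0}))
        assert not any(res.significant.values())

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12)
    )
    @settings(max_examples=300)
    def test_rejects_superset_of_holm(self, ps):
        f = PValueFamily(tuple(f"m{i}" for i in range(len(ps))), tuple(ps), 0.05)
        holm = holm_bonferroni(f).significant
        hoch = hochberg_step_up(f).significant
        for label, rejected in holm.items():
            if rejected:
                assert hoch[label]


class TestChi2:
    def test_equal_counts_zero(self):
        res = chi2_two_methods([10, 20, 30], [10, 20, 30])
        assert res.statistic == 0.0

    def test_two_category_matches_binary_rule(self):
        res = chi2_two_methods([70, 50], [50, 70])
        assert res.statistic == pytest.approx(400 / 120)

    def test_matches_textbook_oracle(self, rng):
        e = [23, 17, 40, 20]
        f = [30, 10, 35, 25]
        res = chi2_two_methods(e, f)
        expected = [(a + b) / 2 for a, b in zip(e, f)]
        oracle = sum((a - m) ** 2 / m for a, m in zip(e, expected))
        assert res.statistic == pytest.approx(oracle)
        ref = stats.chisquare(e, expected)
        assert res.statistic == pytest.approx(ref.statistic)

    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chi2_two_methods([10, 10], [10, 11])

    def test_vs_expected_zero(self):
        assert chi2_vs_expected([5, 5], [5.0, 5.0]).statistic == 0.0

    def test_vs_expected_hand_arithmetic(self):
        # uniform expectation of 10 per cell, one displaced pair of counts
        res = chi2_vs_expected([13, 7, 10], [10.0, 10.0, 10.0])
        assert res.statistic == pytest.approx(9 / 10 + 9 / 10)

    def test_vs_expected_two_categories_equals_binary_rule(self):
        res = chi2_vs_expected([70, 50], [60.0, 60.0])
        assert res.statistic == pytest.approx((70 - 50) ** 2 / 120)


class TestAnova:
    def test_benchmark_local_ss_method_a(self, bench_matrix):
        values = bench_matrix.values[0]
        ss_a = float(((values - values.mean()) ** 2).sum())
        assert ss_a == pytest.approx(0.043, abs=1e-12)  # prints as 0.044 elsewhere

    def test_benchmark_rejects_equality(self, bench_matrix):
        res = anova_oneway(bench_matrix)
        assert res.critical == pytest.approx(3.88, abs=0.01)
        assert res.f_statistic > res.critical
        assert res.p_value < 0.01

    def test_matches_scipy(self, bench_matrix):
        res = anova_oneway(bench_matrix)
        ref = stats.f_oneway(*bench_matrix.values)
        assert res.f_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_degenerate_all_equal(self):
        pm = PerformanceMatrix(("a", "b"), ("s1", "s2"), np.full((2, 2), 3.0))
        res = anova_oneway(pm)
        assert res.ss_global == 0.0 and res.ss_local == 0.0
        assert res.f_statistic == 0.0

    def test_ss_and_df_decomposition(self, rng):
        pm = gen_performance_matrix(4, 7, np.zeros(4), np.eye(4), seed=5)
        res = anova_oneway(pm)
        assert res.ss_total == pytest.approx(res.ss_global + res.ss_local)
        assert res.df_total == res.df_global + res.df_local

    def test_unequal_group_sizes_weighted(self, rng):
        groups = [rng.normal(size=4), rng.normal(1.0, 1, size=9), rng.normal(size=6)]
        res = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(ref.statistic)


class TestNestedF:
    def test_identity_with_anova(self, bench_matrix):
        res = anova_oneway(bench_matrix)
        f, _ = f_test_nested(res.ss_total, res.df_total, res.ss_local, res.df_local)
        assert f == pytest.approx(res.f_statistic)

    def test_no_improvement_zero(self):
        f, p = f_test_nested(10.0, 10, 10.0, 8)
        assert f == 0.0 and p == 1.0

    def test_linear_fit_oracle(self, rng):
        # one-parameter (mean only) vs two-parameter (line) on synthetic data
        x = np.linspace(0, 1, 20)
        y = 2.0 + 1.5 * x + rng.normal(0, 0.3, 20)
        ss1 = float(((y - y.mean()) ** 2).sum())
        slope, intercept = np.polyfit(x, y, 1)
        ss2 = float(((y - (intercept + slope * x)) ** 2).sum())
        f, p = f_test_nested(ss1, 19, ss2, 18)
        oracle_f = ((ss1 - ss2) / 1) / (ss2 / 18)
        assert f == pytest.approx(oracle_f)
        # equivalently the squared slope t statistic
        t = stats.linregress(x, y)
        assert f == pytest.approx(t.slope**2 / t.stderr**2, rel=1e-9)


class TestAnovaM2EqualsT2:
    def test_random_matrices(self, rng):
        for _ in range(10):
            values = rng.normal(size=(2, 6))
            pm = PerformanceMatrix(("a", "b"), tuple(f"s{j}" for j in range(6)), values)
            res = anova_oneway(pm)
            t, df = two_sample_t(values[0], values[1], equal_variance=True)
            assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
            assert res.df_local == df

    def test_benchmark_pair(self, bench_matrix):
        values = bench_matrix.values[:2]
        pm = PerformanceMatrix(("A", "B"), bench_matrix.systems, values)
        res = anova_oneway(pm)
        t, _ = two_sample_t(values[0], values[1])
        assert res.f_statistic == pytest.approx(t**2)

    def test_equal_means_both_zero(self):
        v = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        pm = PerformanceMatrix(("a", "b"), ("x", "y", "z"), v)
        assert anova_oneway(pm).f_statistic == pytest.approx(0.0, abs=1e-20)


class TestAdjustedR2:
    def test_perfect_fit(self):
        assert adjusted_r2(1.0, 5, 50) == 1.0

    def test_no_parameters(self):
        assert adjusted_r2(0.7, 0, 50) == 0.7

    def test_direct_arithmetic(self):
        assert adjusted_r2(0.9, 5, 50) == pytest.approx(0.9 - 0.1 * 5 / 44)

    def test_df_underflow(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 10, 11)


class TestWhiten:
    def test_diagonal_covariance(self):
        model = whiten_covariance(np.diag([4.0, 9.0, 16.0]))
        assert model.whitener == pytest.approx(np.diag([0.5, 1 / 3, 0.25]))

    def test_random_spd_identity(self, rng):
        raw = rng.normal(size=(3, 6))
        v = raw @ raw.T
        model = whiten_covariance(v)
        w = model.whitener
        assert w @ v @ w.T == pytest.approx(np.eye(3), abs=1e-10)

    def test_matrix_route(self, rng):
        pm = gen_performance_matrix(3, 40, np.zeros(3),
                                    np.array([[1, 0.5, 0.2], [0.5, 1, 0.1], [0.2, 0.1, 1.0]]),
                                    seed=9)
        model = whiten(pm)
        w = model.whitener
        assert w @ model.covariance @ w.T == pytest.approx(np.eye(3), abs=1e-8)
        # whitened data really has identity covariance
        dev = pm.values - pm.values.mean(axis=1, keepdims=True)
        y = w @ dev
        assert y @ y.T / (pm.n_systems - 1) == pytest.approx(np.eye(3), abs=1e-8)

    def test_duplicated_method_floored(self, rng):
        base = rng.normal(size=8)
        other = rng.normal(size=8)
        pm = PerformanceMatrix(
            ("m1", "m1copy", "m2"),
            tuple(f"s{j}" for j in range(8)),
            np.array([base, base, other]),
        )
        model = whiten(pm)
        assert model.floored  # near-zero eigenvalue was caught

    def test_zero_covariance_rejected(self):
        with pytest.raises(ValueError):
            whiten_covariance(np.zeros((2, 2)))


class TestCorrelatedChi2:
    def test_identity_covariance_reduces_to_sum_of_squares(self):
        means = [1.0, 2.0, 4.0]
        res = correlated_chi2(means, np.eye(3))
        centred = np.array(means) - np.mean(means)
        assert res.statistic == pytest.approx(float((centred**2).sum()))
        assert res.df == 2

    def test_equal_means_zero(self):
        v = np.array([[2.0, 0.5], [0.5, 1.0]])
        assert correlated_chi2([3.0, 3.0], v).statistic == pytest.approx(0.0, abs=1e-20)

    def test_scaled_identity_analytic(self):
        sigma2 = 0.25
        means = [0.1, 0.6, 0.2, 0.5]
        res = correlated_chi2(means, sigma2 * np.eye(4))
        centred = np.array(means) - np.mean(means)
        assert res.statistic == pytest.approx(float((centred**2).sum()) / sigma2)

    def test_null_calibration(self, rng):
        # 5000 equal-mean draws with a nontrivial covariance: the statistic
        # must follow chi-squared with M-1 df
        v = np.array([[1.0, 0.6, 0.3], [0.6, 1.5, 0.4], [0.3, 0.4, 0.8]])
        chol = np.linalg.cholesky(v)
        draws = rng.standard_normal((5000, 3)) @ chol.T + 5.0
        statistics = [correlated_chi2(d, v).statistic for d in draws]
        ks = stats.kstest(statistics, stats.chi2(df=2).cdf)
        assert ks.pvalue > 0.01


class TestTukeyHsd:
    def test_benchmark_statistics(self, bench_matrix):
        res = tukey_hsd(bench_matrix)
        by = {m: i for i, m in enumerate(res.labels)}
        # full-precision recomputation; prints as 5.12/4.94/0.18 when the
        # pooled SD is quoted at 0.034
        assert res.statistics[by["A"], by["B"]] == pytest.approx(5.146, abs=1e-3)
        assert res.statistics[by["A"], by["C"]] == pytest.approx(4.968, abs=1e-3)
        assert res.statistics[by["B"], by["C"]] == pytest.approx(0.177, abs=1e-3)

    def test_benchmark_critical_value(self, bench_matrix):
        res = tukey_hsd(bench_matrix)
        assert res.critical == pytest.approx(3.77, abs=5e-3)
        assert res.significant[0, 1] and res.significant[0, 2]
        assert not res.significant[1, 2]

    def test_quantile_matches_scipy(self):
        assert studentized_range_quantile(0.95, 3, 12) == pytest.approx(
            stats.studentized_range.ppf(0.95, 3, 12)
        )

    def test_identical_methods_zero(self):
        pm = PerformanceMatrix(
            ("a", "b"), ("s1", "s2", "s3"), np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        )
        with pytest.raises(ValueError):
            # identical rows leave nothing to pool against
            tukey_hsd(
                PerformanceMatrix(("a", "b"), ("s1", "s2"), np.array([[1.0, 1.0], [1.0, 1.0]]))
            )
        res = tukey_hsd(pm)
        assert res.statistics[0, 1] == 0.0

    def test_affine_invariance(self, bench_matrix, rng):
        res = tukey_hsd(bench_matrix)
        shifted = PerformanceMatrix(
            bench_matrix.methods,
            bench_matrix.systems,
            bench_matrix.values * 7.3 - 2.0,
        )
        res2 = tukey_hsd(shifted)
        assert np.array_equal(res.significant, res2.significant)
        assert res.statistics == pytest.approx(res2.statistics)


FIG_LABELS = ("F", "E", "A", "B", "D", "C")
FIG_MEANS = [0.9, 0.85, 0.8, 0.75, 0.7, 0.65]


def fig_significance():
    """Pairwise verdicts: F differs from all but E; {E,A,B} and {D,C}
    internally equivalent; B ~ D across the groups; everything else differs."""
    labels = FIG_LABELS
    sig = np.ones((6, 6), dtype=bool)
    np.fill_diagonal(sig, False)
    equiv = [("F", "E"), ("E", "A"), ("E", "B"), ("A", "B"), ("D", "C"), ("B", "D")]
    ix = {l: i for i, l in enumerate(labels)}
    for a, b in equiv:
        sig[ix[a], ix[b]] = sig[ix[b], ix[a]] = False
    return sig


class TestGroupingLayout:
    def test_narrative_fixture(self):
        gl = grouping_layout(FIG_LABELS, FIG_MEANS, fig_significance())
        assert gl.columns == (("F",), ("E", "A", "B"), ("D", "C"))
        assert set(gl.edges) == {("F", "E"), ("B", "D")}

    def test_all_equivalent_single_column(self):
        sig = np.zeros((4, 4), dtype=bool)
        gl = grouping_layout(("w", "x", "y", "z"), [1.0, 4.0, 3.0, 2.0], sig)
        assert gl.columns == (("x", "y", "z", "w"),)
        assert gl.edges == ()

    def test_all_different_singletons(self):
        sig = ~np.eye(3, dtype=bool)
        gl = grouping_layout(("a", "b", "c"), [1.0, 3.0, 2.0], sig)
        assert gl.columns == (("b",), ("c",), ("a",))

    def test_asymmetric_matrix_rejected(self):
        sig = np.zeros((2, 2), dtype=bool)
        sig[0, 1] = True
        with pytest.raises(ValueError):
            grouping_layout(("a", "b"), [1.0, 2.0], sig)

    def test_from_matrix(self, bench_matrix):
        gl = layout_from_matrix(bench_matrix)
        assert gl.columns == (("B", "C"), ("A",))
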