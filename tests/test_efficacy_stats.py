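"""AUC statistic, delta curves and the two-group summary statistics.

Statistics computed from summary inputs are cross-checked against
scipy/numpy oracles; AUC integration is checked against a fine-grid
integral of the same interpolant.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from feverpghd.case_builder import build_cases
from feverpghd.efficacy_stats import (
    auc_from_baseline,
    chi_square,
    cohens_d,
    compute_aucs,
    delta_curve,
    delta_grid,
    mixture_total,
    student_t,
    student_t_from_samples,
    table2_report,
)
from feverpghd.episode_builder import TemperatureSeries

from conftest import random_minute_series


def _case_with_series(times, temps, dose_h):
    s = TemperatureSeries("A", np.asarray(times, float),
                          np.asarray(temps, float))
    case = build_cases("A", [dose_h], ["ACE"], series=s)[0]
    return case, s


class TestAUC:
    def test_constant_at_baseline_gives_zero(self):
        case, s = _case_with_series([0.0, 6.0], [38.5, 38.5], 0.0)
        res = auc_from_baseline(case, s, 6)
        assert res.auc_c_h == pytest.approx(0.0)
        assert not res.truncated

    def test_triangle_plus_rectangle_area(self):
        # delta falls linearly 0 -> -2 C over 2 h, holds -2 C to 6 h:
        # AUC = -(0.5*2*2 + 4*2) = -10 C*h
        case, s = _case_with_series([0.0, 2.0, 6.0], [38.5, 36.5, 36.5], 0.0)
        res = auc_from_baseline(case, s, 6)
        assert res.auc_c_h == pytest.approx(-10.0)

    def test_truncated_series_is_flagged(self):
        case, s = _case_with_series([0.0, 4.0], [38.5, 38.0], 0.0)
        res = auc_from_baseline(case, s, 6)
        assert res.truncated

    def test_nonstandard_horizon_warns_but_computes(self):
        case, s = _case_with_series([0.0, 8.0], [38.5, 38.5], 0.0)
        with pytest.warns(UserWarning):
            res = auc_from_baseline(case, s, 7)
        assert res.auc_c_h == pytest.approx(0.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_horizon_additivity_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        t, y = random_minute_series(rng, n_min=8)
        case, s = _case_with_series(t, y, t[0])
        offs, delta, _ = delta_grid(case, s, 12)
        if offs[-1] < 12:
            return
        a6 = np.trapezoid(delta[offs <= 6], offs[offs <= 6])
        a12 = np.trapezoid(delta, offs)
        mid = np.trapezoid(delta[(offs >= 6)], offs[offs >= 6])
        assert a12 == pytest.approx(a6 + mid, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_hourly_trapezoid_close_to_fine_grid_integral(self, seed):
        # the fine-grid trapezoid is exact for the interpolant (knots on
        # minutes); hourly discretization error is bounded by the total
        # slope change at interior knots times h^2/8
        rng = np.random.default_rng(seed)
        t, y = random_minute_series(rng, n_min=8)
        case, s = _case_with_series(t, y, t[0])
        res = auc_from_baseline(case, s, 6)
        if res.truncated:
            return
        fine = t[0] + np.arange(0, 6 * 60 + 1) / 60.0
        exact = np.trapezoid(s.interpolate(fine) - case.baseline_temp_c,
                             fine - t[0])
        slopes = np.diff(s.temp_c) / np.diff(s.t_h)
        bound = np.abs(np.diff(slopes)).sum() / 8.0 + 1e-9
        assert abs(res.auc_c_h - exact) <= bound


class TestDeltaCurve:
    def test_anchored_at_zero_and_n_nonincreasing(self):
        series = {
            "A": TemperatureSeries("A", np.arange(0, 30.0),
                                   38.5 - 0.05 * np.arange(0, 30.0)),
            "B": TemperatureSeries("B", np.arange(0, 10.0),
                                   np.full(10, 39.0)),
        }
        cases = (build_cases("A", [0.0], ["ACE"], series=series["A"])
                 + build_cases("B", [0.0], ["IBU"], series=series["B"]))
        curves = delta_curve(cases, series, "group", horizon_h=24)
        single = curves[curves.stratum == "single"]
        assert single.loc[single.offset_h == 0, "mean_delta_c"].iloc[0] == 0.0
        assert single["n"].is_monotonic_decreasing

    def test_identical_cases_give_the_common_trace(self):
        s = TemperatureSeries("A", np.arange(0, 25.0),
                              38.5 - 0.1 * np.arange(0, 25.0))
        cases = build_cases("A", [0.0], ["ACE"], series=s) * 3
        curves = delta_curve(cases, {"A": s}, "group", horizon_h=12)
        expected = -0.1 * np.arange(13)
        assert np.allclose(curves["mean_delta_c"], expected)


class TestStudentT:
    def test_equal_means_give_zero_and_p_one(self):
        t, p = student_t(5.0, 1.0, 50, 5.0, 2.0, 60)
        assert t == 0.0 and p == 1.0

    def test_large_n_separation_is_significant(self):
        _, p = student_t(1.0, 1.0, 10_000, 0.0, 1.0, 10_000)
        assert p < 1e-3

    def test_zero_variance_with_unequal_means(self):
        t, p = student_t(1.0, 0.0, 5, 0.0, 0.0, 5)
        assert np.isinf(t) and t > 0 and p == 0.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_scipy_from_stats(self, seed):
        rng = np.random.default_rng(seed)
        m1, m2 = rng.normal(0, 5, 2)
        s1, s2 = rng.uniform(0.5, 4, 2)
        n1, n2 = rng.integers(2, 500, 2)
        t, p = student_t(m1, s1, int(n1), m2, s2, int(n2))
        ref = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                       equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-300)

    def test_from_samples_agrees_with_scipy_on_raw_data(self):
        rng = np.random.default_rng(7)
        x1, x2 = rng.normal(0, 1, 40), rng.normal(0.4, 1.3, 55)
        t, p = student_t_from_samples(x1, x2)
        ref = sps.ttest_ind(x1, x2, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestChiSquare:
    def test_identical_row_distributions_give_zero(self):
        stat, p = chi_square([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_evaluated_2x2(self):
        # E = 20 everywhere; sum (O-E)^2 / E = 4 * 100/20 = 20
        stat, _ = chi_square([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            chi_square([[0, 10], [0, 30]])


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert cohens_d(5.0, 1.0, 5.0, 2.0) == 0.0

    def test_both_zero_sds_raise(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0, 2.0, 0.0)

    def test_shift_and_scale_invariance(self):
        d0 = cohens_d(38.59, 0.53, 38.76, 0.56)
        assert cohens_d(38.59 + 3, 0.53, 38.76 + 3, 0.56) \
            == pytest.approx(d0)
        assert cohens_d(38.59 * 2, 0.53 * 2, 38.76 * 2, 0.56 * 2) \
            == pytest.approx(d0)

    def test_pooled_variant_uses_group_sizes(self):
        d_eq = cohens_d(0.0, 1.0, 1.0, 3.0)
        d_pool = cohens_d(0.0, 1.0, 1.0, 3.0, n1=1000, n2=2, variant="pooled")
        assert d_pool > d_eq  # pooled SD dominated by the large sd1=1 group


class TestMixtureTotal:
    def test_single_component_identity(self):
        assert mixture_total(5.0, 1.5, 10, 99.0, 9.0, 0) == (5.0, 1.5)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_pooled_sample_moments(self, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3),
                        rng.integers(2, 200))
        x2 = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3),
                        rng.integers(2, 200))
        m, sd = mixture_total(x1.mean(), x1.std(), len(x1),
                              x2.mean(), x2.std(), len(x2))
        pooled = np.concatenate([x1, x2])
        assert m == pytest.approx(pooled.mean(), abs=1e-12)
        assert sd == pytest.approx(pooled.std(), abs=1e-12)


class TestReports:
    def test_table2_mixture_identity_and_null_effect(self):
        rng = np.random.default_rng(3)
        series, cases = {}, []
        for i in range(60):
            cid = f"K{i}"
            temps = 38.6 - 0.12 * np.arange(14.0) + rng.normal(0, 0.05, 14)
            series[cid] = TemperatureSeries(cid, np.arange(14.0), temps)
            ing = ["ACE", "IBU"] if i % 2 else ["ACE"]
            cases.extend(build_cases(cid, list(range(len(ing))), ing,
                                     series=series[cid]))
        auc = compute_aucs(cases, series, thresholds=(38.0,), horizons=(6, 8))
        rep = table2_report(auc)
        for h, cell in rep[">=38"].items():
            tm, ts = mixture_total(cell["mean1"], cell["sd1"], cell["n1"],
                                   cell["mean2"], cell["sd2"], cell["n2"])
            assert cell["total_mean"] == pytest.approx(tm, abs=1e-9)
            assert cell["total_sd"] == pytest.approx(ts, abs=1e-9)
            # both groups sample the same defervescence process
            assert cell["cohens_d"] < 0.5
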