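"""Glycaemic outcomes, cohort statistics, Wilcoxon, Granger, CCM, JSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucogan.cohort import make_cohort
from glucogan.validation import (
    GLYCEMIC_METRICS,
    ccm,
    cohort_summary,
    glycemic_outcomes,
    granger_test,
    jsd,
    jsd_traces,
    validation_report,
    wilcoxon_compare,
)


class TestGlycemicOutcomes:
    def test_hand_counted_band_percentages(self):
        o = glycemic_outcomes(np.array([60.0, 80.0, 100.0, 200.0, 300.0]))
        assert o.pct_below54 == 0.0
        assert o.pct_54_69 == 20.0
        assert o.pct_70_140 == 40.0
        assert o.pct_70_180 == 40.0
        assert o.pct_180_250 == 20.0
        assert o.pct_above250 == 20.0
        assert o.mean == pytest.approx(148.0)

    def test_constant_trace(self):
        o = glycemic_outcomes(np.full(10, 100.0))
        assert o.pct_70_140 == o.pct_70_180 == 100.0
        assert o.cv == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            glycemic_outcomes(np.array([]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 500))
    def test_disjoint_bands_partition_any_trace(self, seed, n):
        bg = np.random.default_rng(seed).uniform(21.0, 599.0, n)
        o = glycemic_outcomes(bg)
        total = (o.pct_below54 + o.pct_54_69 + o.pct_70_180 + o.pct_180_250
                 + o.pct_above250)
        assert total == pytest.approx(100.0)
        assert o.pct_70_140 <= o.pct_70_180
        assert o.cv == pytest.approx(100.0 * o.std / o.mean)


class TestCohortSummary:
    def test_single_patient_degenerate_iqr(self):
        o = glycemic_outcomes(np.full(5, 100.0))
        s = cohort_summary([o])
        assert s.loc["mean", "median"] == 100.0
        assert s.loc["mean", "q1"] == s.loc["mean", "q3"] == 100.0

    def test_median_of_five(self):
        outcomes = [glycemic_outcomes(np.full(3, v))
                    for v in (100.0, 110.0, 120.0, 130.0, 140.0)]
        assert cohort_summary(outcomes).loc["mean", "median"] == 120.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        outcomes = [glycemic_outcomes(rng.uniform(60, 250, 50))
                    for _ in range(6)]
        a = cohort_summary(outcomes)
        b = cohort_summary(outcomes[::-1])
        assert a.drop(columns="display").equals(b.drop(columns="display"))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])


class TestWilcoxon:
    def _outcomes(self, traces):
        return [glycemic_outcomes(t) for t in traces]

    def test_identical_cohorts_report_p_one(self):
        rng = np.random.default_rng(1)
        traces = [rng.uniform(60, 250, 100) for _ in range(6)]
        real = self._outcomes(traces)
        p = wilcoxon_compare(real, real)
        assert (p == 1.0).all()

    def test_exact_p_for_six_positive_differences(self):
        """All-positive paired differences, n=6: exact two-sided p = 2/64."""
        base = [np.full(10, 100.0 + k) for k in range(6)]
        shifted = [b + d for b, d in zip(base, (1, 2, 3, 4, 5, 6))]
        p = wilcoxon_compare(self._outcomes(base), self._outcomes(shifted))
        assert p["mean"] == pytest.approx(2 / 64)

    def test_unpaired_cohorts_rejected(self):
        o = self._outcomes([np.full(5, 100.0)])
        with pytest.raises(ValueError):
            wilcoxon_compare(o, o * 2)

    def test_qualification_threshold_is_5_percent(self):
        rng = np.random.default_rng(2)
        traces = [rng.uniform(80, 200, 200) for _ in range(8)]
        perturbed = [t + rng.normal(0, 0.5, t.size) for t in traces]
        p = wilcoxon_compare(self._outcomes(traces), self._outcomes(perturbed))
        # near-identical cohorts must qualify (p >= 0.05) on most metrics
        assert (p >= 0.05).sum() >= 7


class TestGranger:
    def test_detects_lagged_driving(self):
        """y_t = 0.9 x_{t-1} + noise must be detected in >= 95/100 runs."""
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            x = rng.standard_normal(501)
            y = np.zeros(501)
            y[1:] = 0.9 * x[:-1] + 0.3 * rng.standard_normal(500)
            hits += granger_test(x[1:], y[1:], max_lag=5) < 0.01
        assert hits >= 95

    def test_type_one_error_calibrated_on_white_noise(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            granger_test(rng.standard_normal(400), rng.standard_normal(400),
                         max_lag=5) < 0.05
            for _ in range(200)
        )
        assert 0.02 <= rejections / 200 <= 0.09

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError):
            granger_test(np.ones(200), np.random.default_rng(0).normal(size=200),
                         max_lag=2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            granger_test(np.arange(30.0), np.arange(30.0), max_lag=18)

    def test_agrees_with_statsmodels_reference_at_fixed_lag(self):
        """Dual route: our OLS F-test vs statsmodels grangercausalitytests."""
        from statsmodels.tsa.stattools import grangercausalitytests

        rng = np.random.default_rng(3)
        x = rng.standard_normal(300)
        y = np.zeros(300)
        y[1:] = 0.5 * x[:-1] + rng.standard_normal(299)
        ours = granger_test(x, y, max_lag=1)
        ref = grangercausalitytests(
            np.column_stack([y, x]), maxlag=[1], verbose=False
        )[1][0]["ssr_ftest"][1]
        assert ours == pytest.approx(ref, rel=1e-6)


class TestCCM:
    def test_self_map_skill_approaches_one(self):
        rng = np.random.default_rng(0)
        x = np.sin(np.linspace(0, 60, 600)) + 0.1 * rng.standard_normal(600)
        res = ccm(x, x, library_sizes=[100, 300, 500], n_boot=10, seed=0)
        assert res.skill > 0.95

    def test_detects_unidirectional_coupling(self, coupled_logistic_maps):
        x, y = coupled_logistic_maps
        fwd = ccm(x, y, n_boot=20, seed=0)  # x drives y: y cross-maps x
        rev = ccm(y, x, n_boot=20, seed=0)
        assert fwd.skill > 0.9
        assert fwd.convergent
        assert rev.skill < 0.3
        assert not rev.convergent

    def test_independent_noise_has_no_skill(self):
        rng = np.random.default_rng(5)
        res = ccm(rng.standard_normal(800), rng.standard_normal(800),
                  n_boot=10, seed=0)
        assert abs(res.skill) < 0.15
        assert not res.convergent

    def test_skill_monotone_for_self_map(self):
        rng = np.random.default_rng(2)
        x = np.sin(np.linspace(0, 80, 800)) + 0.05 * rng.standard_normal(800)
        res = ccm(x, x, library_sizes=[100, 300, 500, 700], n_boot=10, seed=1)
        assert np.all(np.diff(res.skills) > -0.02)  # within bootstrap noise

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ccm(np.arange(50.0), np.arange(50.0), library_sizes=[100])


class TestJSD:
    def test_identical_distributions(self):
        assert jsd([0.25, 0.75], [0.25, 0.75]) == 0.0

    def test_disjoint_support_is_exactly_one(self):
        assert jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_hand_evaluated_mixture(self):
        assert jsd([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.311278, abs=1e-5)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            jsd([0.5, 0.2], [0.5, 0.5])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 30))
    def test_symmetric_and_bounded(self, seed, k):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k))
        q = rng.dirichlet(np.ones(k))
        d = jsd(p, q)
        assert d == pytest.approx(jsd(q, p), abs=1e-12)
        assert -1e-12 <= d <= 1.0 + 1e-12


class TestValidationReport:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        return make_cohort(2, 2, seed=21)

    def test_self_comparison_is_perfect(self, small_cohort):
        report = validation_report(
            small_cohort, small_cohort,
            ccm_kwargs={"n_boot": 3, "library_sizes": [100, 200, 300]},
            granger_max_lag=4, ccm_subsample=400,
        )
        assert (report.wilcoxon_p == 1.0).all()
        assert (report.causality["jsd"] == 0.0).all()

    def test_report_covers_nine_metrics_per_cohort(self, small_cohort):
        report = validation_report(
            small_cohort, small_cohort,
            ccm_kwargs={"n_boot": 2, "library_sizes": [100, 200]},
            granger_max_lag=2, ccm_subsample=300,
        )
        assert list(report.summary_real.index) == list(GLYCEMIC_METRICS)
        assert len(report.summary_real) == 9
        assert set(report.wilcoxon_p.index) == set(GLYCEMIC_METRICS)
        md = report.to_markdown()
        assert "Glycaemic outcomes" in md

    def test_mismatched_cohorts_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            validation_report(small_cohort, small_cohort[:1])


def test_jsd_traces_on_shared_histogram_grid():
    rng = np.random.default_rng(0)
    a = rng.normal(150, 30, 2000)
    b = rng.normal(155, 32, 2000)
    d = jsd_traces(a, b)
    assert 0.0 < d < 0.2
    assert jsd_traces(a, a) == 0.0
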