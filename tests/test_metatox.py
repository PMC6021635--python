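import numpy as np
import pytest

from polybtdm import (
    PKParameters,
    PopulationPKModel,
    StudyRecord,
    derive_upper_bound,
    fit_exposure_toxicity,
    harmonize_grades,
    load_study_table,
    simulate_study_auc,
    summarize_percentile_column,
    weighted_regression,
)
from polybtdm.metatox import regression_frame, unweighted_regression
from polybtdm.pkcore import InvalidParameterError


class TestHarmonizeGrades:
    def test_pooled_upper_grades_accumulate(self):
        # 20/73 at risk plus 24/73 at injury-or-failure: everyone at or
        # above risk counts in the >=25% grade -> 44/73 = 60.3%
        ge25, ge50, ge75 = harmonize_grades(73, risk=20, injury_or_failure=24)
        assert ge25 == pytest.approx(100 * 44 / 73, rel=1e-12)
        assert ge50 == pytest.approx(100 * 24 / 73, rel=1e-12)
        assert ge75 is None

    def test_full_rifle_report(self):
        ge25, ge50, ge75 = harmonize_grades(115, risk=55, injury=36, failure=19)
        assert ge25 == pytest.approx(100 * 110 / 115)
        assert ge50 == pytest.approx(100 * 55 / 115)
        assert ge75 == pytest.approx(100 * 19 / 115)

    def test_all_zero_counts(self):
        assert harmonize_grades(50, risk=0, injury=0, failure=0) == (0.0, 0.0, 0.0)

    def test_unmappable_report_gives_absent_not_zero(self):
        # a study reporting only "any nephrotoxicity" has no RIFLE mapping
        ge25, ge50, ge75 = harmonize_grades(50)
        assert ge25 is None and ge50 is None and ge75 is None

    def test_counts_exceeding_n_rejected(self):
        with pytest.raises(InvalidParameterError):
            harmonize_grades(30, risk=20, injury=15)


class TestStudyTable:
    def test_fixture_shape(self):
        studies = load_study_table()
        assert len(studies) == 18
        missing = [s for s in studies if s.tox_pct_ge25 is None]
        assert len(missing) == 2  # the two cohorts without a mappable mild grade
        frame = regression_frame(studies)
        assert len(frame) == 16

    def test_cumulative_grade_monotonicity_everywhere(self):
        for s in load_study_table():
            grades = [s.tox_pct_ge25, s.tox_pct_ge50, s.tox_pct_ge75]
            present = [g for g in grades if g is not None]
            assert all(a >= b - 1e-9 for a, b in zip(present, present[1:]))

    def test_grade_validation(self):
        with pytest.raises(InvalidParameterError):
            StudyRecord("bad", 10, 100.0, tox_pct_ge25=10.0, tox_pct_ge50=20.0)


class TestWeightedRegression:
    def test_collinear_points_exact(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        y = 2.0 * x + 1.0
        fit = weighted_regression(x, y, [1.0, 4.0, 2.0, 7.0])
        assert fit.slope == pytest.approx(2.0, rel=1e-10)
        assert fit.intercept == pytest.approx(1.0, rel=1e-10)

    def test_equal_weights_match_ols_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(50, 120, 10)
        y = 0.3 * x + 5 + rng.normal(0, 3, 10)
        fit = weighted_regression(x, y, np.ones(10))
        dx, dy = x - x.mean(), y - y.mean()
        slope = np.sum(dx * dy) / np.sum(dx * dx)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(y.mean() - slope * x.mean(), rel=1e-10)

    def test_invariant_to_weight_rescaling(self):
        studies = load_study_table()
        frame = regression_frame(studies)
        a = weighted_regression(frame["x"], frame["y"], frame["w"])
        b = weighted_regression(frame["x"], frame["y"], 1000.0 * frame["w"].to_numpy())
        assert a.slope == pytest.approx(b.slope, rel=1e-10)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-8)

    def test_line_passes_through_weighted_means(self):
        frame = regression_frame(load_study_table())
        fit = weighted_regression(frame["x"], frame["y"], frame["w"])
        w = frame["w"].to_numpy()
        xbar = np.average(frame["x"], weights=w)
        ybar = np.average(frame["y"], weights=w)
        assert fit.predict(xbar) == pytest.approx(ybar, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidParameterError):
            weighted_regression([1, 2], [1, 2], [1, 1])

    def test_unweighted_comparator_differs(self):
        fitw = fit_exposure_toxicity()
        fitu = fit_exposure_toxicity(weighted=False)
        assert fitu.slope != pytest.approx(fitw.slope, rel=1e-4)


class TestHeadlineFit:
    def test_slope_intercept_p(self):
        fit = fit_exposure_toxicity()
        assert fit.n_studies == 16
        assert fit.slope == pytest.approx(0.3465, rel=0.005)
        assert fit.intercept == pytest.approx(5.59, rel=0.01)
        assert fit.p_value == pytest.approx(0.0475, abs=0.005)
        assert fit.p_value < 0.05

    def test_upper_bound_inversion(self):
        fit = fit_exposure_toxicity()
        bound = derive_upper_bound(fit, max_acceptable_rate=40.0)
        assert bound.raw == pytest.approx(99.3, abs=0.7)
        assert bound.rounded == 100.0
        # round-trip: predicted rate at the raw bound is the cap exactly
        assert fit.predict(bound.raw) == pytest.approx(40.0, abs=1e-10)

    def test_intercept_equal_to_rate_gives_zero_bound(self):
        fit = fit_exposure_toxicity()
        assert derive_upper_bound(fit, max_acceptable_rate=fit.intercept).raw == pytest.approx(
            0.0, abs=1e-10
        )

    def test_nonpositive_slope_rejected(self):
        from polybtdm import WeightedRegressionResult

        flat = WeightedRegressionResult(-0.1, 5.0, 0.1, -1.0, 0.3, 5, (1.0,) * 5)
        with pytest.raises(InvalidParameterError):
            derive_upper_bound(flat)


class TestPercentileSummaries:
    def test_p75_median_and_range(self):
        med, lo, hi = summarize_percentile_column(load_study_table(), 75)
        assert med == pytest.approx(80.4, abs=0.05)
        assert (lo, hi) == (58.9, 117.0)

    def test_p50_median_by_direct_sort(self):
        studies = load_study_table()
        med, _, _ = summarize_percentile_column(studies, 50)
        vals = sorted(s.ssauc_p50 for s in studies)
        assert med == pytest.approx((vals[8] + vals[9]) / 2, rel=1e-12)
        assert round(med, 1) == pytest.approx(61.0, abs=0.051)

    def test_single_study_degenerate(self):
        s = StudyRecord("only", 10, 100.0, ssauc_p25=40.0, ssauc_p50=50.0, ssauc_p75=60.0)
        assert summarize_percentile_column([s], 75) == (60.0, 60.0, 60.0)


class TestStudySimulation:
    def test_zero_bsv_collapses_percentiles(self):
        m = PopulationPKModel(
            typical_per_kg=PKParameters(0.0276, 0.25, 0.06, 0.25),
            bsv_cv=(0.0, 0.3, 0.3, 0.3),
        )
        s = StudyRecord("fixed", 50, 150.0, weight_kg=66.0)
        r = simulate_study_auc(s, m, n=500, rng=1)
        expected = 150.0 / (0.0276 * 66.0)
        assert r.ssauc_p25 == pytest.approx(expected, rel=1e-9)
        assert r.ssauc_p75 == pytest.approx(expected, rel=1e-9)

    def test_median_matches_lognormal_closed_form(self, model):
        # median ssAUC = dose / (typical CL * weight * exp(-omega^2/2))
        from polybtdm.population import lognormal_sigma

        s = StudyRecord("Rigatto-like", 410, 150.0, weight_kg=66.0)
        r = simulate_study_auc(s, model, n=40000, rng=2)
        omega = lognormal_sigma(0.324)
        closed = 150.0 / (0.0276 * 66.0 * np.exp(-(omega**2) / 2))
        assert r.ssauc_p50 == pytest.approx(closed, rel=0.02)

    def test_percentile_ordering(self, model):
        for s in load_study_table()[:5]:
            r = simulate_study_auc(s, model, n=2000, rng=3)
            assert r.ssauc_p25 <= r.ssauc_p50 <= r.ssauc_p75

    def test_missing_dose_rejected(self, model):
        s = StudyRecord("nodose", 10, float("nan"))
        with pytest.raises(InvalidParameterError):
            simulate_study_auc(s, model, n=10, rng=0)
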