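"""Regression engine: least squares, leverage, intervals, AD criteria."""

import numpy as np
import pytest

from qsarprofiler.base import (
    CriterionStatus,
    DescriptorSpec,
    MissingDescriptorError,
    TrainingRecord,
    ValidationError,
)
from qsarprofiler.fixtures import FixtureConfig, make_mlr_fixture
from qsarprofiler.mlr import (
    MlrRegressor,
    endpoint_ad_check,
    fit_mlr,
    leverage,
    leverage_cutoff,
    prediction_interval,
    standardized_residuals,
    structural_ad_check,
)

SPEC_X = [DescriptorSpec(name="x", source="supplied")]


def _records(x, y):
    return [
        TrainingRecord(id=f"c{i}", descriptor_values=(float(xi),), y=float(yi))
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


class TestFit:
    def test_noiseless_line_is_exact(self, simple_line_model):
        m = simple_line_model
        assert m.beta == pytest.approx([1.0, 2.0], abs=1e-10)
        assert m.s == pytest.approx(0.0, abs=1e-10)
        assert m.r2 == pytest.approx(1.0)

    def test_zero_residual_degree_of_freedom_rejected(self):
        # n = p + 1 leaves df = 0: s is undefined
        with pytest.raises(ValidationError, match="p \\+ 2"):
            fit_mlr(SPEC_X, _records([1.0, 2.0], [1.0, 2.0]))

    def test_residuals_sum_to_zero_and_hat_trace(self, mlr_fixture):
        m, _ = mlr_fixture
        assert np.sum(m.residuals) == pytest.approx(0.0, abs=1e-8)
        assert np.sum(m.hat_diag) == pytest.approx(m.p + 1, abs=1e-8)
        assert np.all(m.hat_diag >= 1.0 / m.n - 1e-12)
        assert np.all(m.hat_diag <= 1.0)

    def test_duplicated_descriptor_column_is_a_hard_error(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        specs = [DescriptorSpec(name="a", source="supplied"),
                 DescriptorSpec(name="b", source="supplied")]
        recs = [TrainingRecord(id=f"c{i}", descriptor_values=(xi, 2.0 * xi), y=xi)
                for i, xi in enumerate(x)]
        with pytest.raises(ValidationError, match="rank deficient"):
            fit_mlr(specs, recs)

    def test_arity_mismatch_names_the_record(self):
        recs = _records([1, 2, 3, 4], [1, 2, 3, 4])
        bad = TrainingRecord(id="odd", descriptor_values=(1.0, 2.0), y=0.0)
        with pytest.raises(ValidationError, match="odd"):
            fit_mlr(SPEC_X, recs + [bad])


class TestLeverage:
    def test_simple_regression_closed_form(self):
        # training x = 1..4; h(x0) = 1/n + (x0 - x̄)² / Σ(x - x̄)²
        m = fit_mlr(SPEC_X, _records([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.9]))
        assert leverage(m, [1.0]) == pytest.approx(0.7)
        assert leverage(m, [2.5]) == pytest.approx(0.25)  # centroid -> 1/n

    def test_training_row_leverage_matches_hat_diagonal(self, mlr_fixture):
        m, _ = mlr_fixture
        for i in (0, 7, 29):
            h = leverage(m, m.training[i].descriptor_values)
            assert h == pytest.approx(m.hat_diag[i], abs=1e-10)

    def test_centroid_leverage_is_one_over_n(self, mlr_fixture):
        m, _ = mlr_fixture
        centroid = m.training_matrix().mean(axis=0)
        assert leverage(m, centroid) == pytest.approx(1.0 / m.n, abs=1e-10)

    @pytest.mark.parametrize("p,n,expected", [(1, 4, 1.5), (3, 30, 0.4)])
    def test_cutoff_formula(self, p, n, expected):
        cfg = FixtureConfig(n=n, p=p, seed=3, n_queries=0)
        m, _ = make_mlr_fixture(cfg)
        assert leverage_cutoff(m) == pytest.approx(expected)

    def test_cutoff_above_one_warns(self):
        with pytest.warns(UserWarning, match="cutoff"):
            fit_mlr(SPEC_X, _records([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.9]))


class TestPredictionInterval:
    def test_exact_fit_has_zero_halfwidth(self, simple_line_model):
        pred = prediction_interval(simple_line_model, [3.0])
        assert pred.value == pytest.approx(7.0)
        assert pred.halfwidth == pytest.approx(0.0, abs=1e-12)

    def test_halfwidth_is_minimal_at_the_centroid(self, mlr_fixture):
        m, _ = mlr_fixture
        centroid = m.training_matrix().mean(axis=0)
        hw0 = prediction_interval(m, centroid).halfwidth
        rng = np.random.default_rng(5)
        for _ in range(50):
            hw = prediction_interval(m, centroid + rng.normal(0, 2, m.p)).halfwidth
            assert hw >= hw0

    def test_prediction_at_training_point_matches_fitted_value(self, mlr_fixture):
        m, _ = mlr_fixture
        i = 4
        pred = prediction_interval(m, m.training[i].descriptor_values)
        fitted = m.training[i].y - m.residuals[i]
        assert pred.value == pytest.approx(fitted, abs=1e-10)
        from scipy import stats

        tq = stats.t.ppf(0.975, m.df)
        assert pred.halfwidth == pytest.approx(
            tq * m.s * np.sqrt(1 + m.hat_diag[i]), abs=1e-10
        )

    def test_missing_descriptor_value_names_it(self, mlr_fixture):
        m, _ = mlr_fixture
        with pytest.raises(MissingDescriptorError, match="d2"):
            prediction_interval(m, [0.0, np.nan, 0.0])


class TestStructuralAD:
    def test_boundary_leverage_is_out(self, mlr_fixture):
        m, _ = mlr_fixture
        # synthesize a query exactly at the cutoff by radial scaling
        centroid = m.training_matrix().mean(axis=0)
        direction = np.ones(m.p)
        lo, hi = 0.0, 50.0
        for _ in range(200):
            mid = (lo + hi) / 2
            h = leverage(m, centroid + mid * direction)
            if h < m.leverage_cutoff:
                lo = mid
            else:
                hi = mid
        x = centroid + hi * direction
        v = structural_ad_check(m, x)
        assert leverage(m, x) >= m.leverage_cutoff
        assert not v.in_ad

    def test_centroid_query_passes(self, mlr_fixture):
        m, _ = mlr_fixture
        centroid = m.training_matrix().mean(axis=0)
        assert structural_ad_check(m, centroid).in_ad

    def test_far_extrapolation_fails(self, mlr_fixture):
        m, queries = mlr_fixture
        extrapolated = [q for q in queries if q.label == "extrapolated"]
        assert extrapolated
        for q in extrapolated:
            v = structural_ad_check(m, q.values)
            assert not v.in_ad
            assert v.details["leverage"] >= v.details["leverage_cutoff"]


class TestEndpointAD:
    def test_in_range_prediction_passes_without_observed_y(self, mlr_fixture):
        m, _ = mlr_fixture
        centroid = m.training_matrix().mean(axis=0)
        pred = prediction_interval(m, centroid)
        v = pred.endpoint_verdict
        assert v.criteria["standardized_residual"] is CriterionStatus.NOT_APPLICABLE
        assert v.criteria["experimental_range"] is CriterionStatus.PASS

    def test_out_of_range_value_and_halfwidth_fail_with_both_reasons(self, mlr_fixture):
        m, _ = mlr_fixture
        far = m.training_matrix().mean(axis=0) + 8.0
        pred = prediction_interval(m, far)
        v = pred.endpoint_verdict
        assert not v.in_ad
        assert v.criteria["experimental_range"] is CriterionStatus.FAIL
        assert v.criteria["interval_range"] is CriterionStatus.FAIL
        assert len(v.reasons) == 2

    def test_training_point_residual_matches_direct_formula(self, mlr_fixture):
        m, _ = mlr_fixture
        r_std = standardized_residuals(m)
        for i in (0, 11, 29):
            pred = prediction_interval(m, m.training[i].descriptor_values)
            v = endpoint_ad_check(m, pred, y_observed=m.training[i].y)
            oracle = m.residuals[i] / (m.s * np.sqrt(1 - m.hat_diag[i]))
            assert v.details["standardized_residual"] == pytest.approx(oracle, abs=1e-10)
            assert r_std[i] == pytest.approx(oracle, abs=1e-10)

    def test_residual_boundary_is_in_ad(self, mlr_fixture):
        m, _ = mlr_fixture
        centroid = m.training_matrix().mean(axis=0)
        pred = prediction_interval(m, centroid)
        h = pred.leverage
        y_at_25 = pred.value + 2.5 * m.s * np.sqrt(1 - h)
        v = endpoint_ad_check(m, pred, y_observed=y_at_25)
        assert v.criteria["standardized_residual"] is CriterionStatus.PASS
        y_beyond = pred.value + 2.5000001 * m.s * np.sqrt(1 - h)
        v2 = endpoint_ad_check(m, pred, y_observed=y_beyond)
        assert v2.criteria["standardized_residual"] is CriterionStatus.FAIL

    def test_strict_and_requires_both_residual_and_range(self, mlr_fixture):
        m, _ = mlr_fixture
        # a training point: its halfwidth lies inside the training range by
        # construction, so only the residual criterion can fail
        pred = prediction_interval(m, m.training[3].descriptor_values)
        # huge residual but prediction inside the experimental range
        y_far = pred.value + 10.0 * m.s
        v_any = endpoint_ad_check(m, pred, y_observed=y_far, strict_and=False)
        v_and = endpoint_ad_check(m, pred, y_observed=y_far, strict_and=True)
        assert not v_any.in_ad
        assert v_and.in_ad  # range criterion passes, so the conjunction does too

    def test_zero_residual_standardizes_to_zero(self, simple_line_model):
        assert standardized_residuals(simple_line_model) == pytest.approx(
            np.zeros(5), abs=1e-12
        )


def test_loo_q2_close_to_r2_on_clean_fixture(mlr_fixture):
    m, _ = mlr_fixture
    q2 = m.estimator.loo_q2()
    assert 0.0 < q2 <= m.r2
    assert q2 == pytest.approx(m.r2, abs=0.1)
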