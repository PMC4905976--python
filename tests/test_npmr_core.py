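import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cnpmr import (
    KernelConfig,
    NPMRError,
    cross_r2,
    kernel_weights,
    npmr_predict,
    tolerance_from_range,
)
from cnpmr.embedding import EmbeddedDesign

from conftest import naive_npmr_predictions


def make_design(y, X):
    X = np.atleast_2d(np.asarray(X, float))
    labels = tuple(("p", j + 1) for j in range(X.shape[1]))
    return EmbeddedDesign(
        response=np.asarray(y, float), predictors=X, labels=labels,
        tau=1, dim_d=X.shape[1], t_offset=0,
    )


class TestKernelWeights:
    def test_closed_forms(self):
        w = kernel_weights([0.0, 1.0, 2.0], 0.0, 1.0)
        np.testing.assert_allclose(w, [1.0, np.exp(-0.5), np.exp(-2.0)], rtol=1e-12)
        assert w[1] == pytest.approx(0.60653, abs=1e-5)

    def test_unit_weight_only_at_zero_distance(self):
        w = kernel_weights([3.0, 3.0 + 1e-6], 3.0, 0.5)
        assert w[0] == 1.0
        assert w[1] < 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(NPMRError):
            kernel_weights([np.nan, 1.0], 0.0, 1.0)


class TestNpmrPredict:
    def test_constant_predictors_give_loo_mean(self, rng):
        y = rng.standard_normal(12)
        fit = npmr_predict(make_design(y, np.ones((12, 2))))
        loo = (y.sum() - y) / (len(y) - 1)
        np.testing.assert_allclose(fit.predictions, loo, rtol=1e-12)

    def test_flat_kernel_limit_is_loo_mean(self, rng):
        y = rng.standard_normal(15)
        X = rng.standard_normal((15, 3))
        fit = npmr_predict(make_design(y, X), KernelConfig(1e6))
        loo = (y.sum() - y) / (len(y) - 1)
        np.testing.assert_allclose(fit.predictions, loo, atol=1e-6)

    def test_matches_naive_loop_small_design(self):
        y = np.array([1.0, -0.5, 2.0, 0.3, -1.2, 0.8])
        X = np.array([[0.1, 1.0], [0.5, -1.0], [1.2, 0.2], [-0.3, 0.7], [0.9, -0.4], [0.0, 0.0]])
        fit = npmr_predict(make_design(y, X), KernelConfig([0.7, 1.3]))
        oracle = naive_npmr_predictions(y, X, [0.7, 1.3])
        np.testing.assert_allclose(fit.predictions, oracle, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(
        y=arrays(np.float64, 20, elements=st.floats(-5, 5)),
        X=arrays(np.float64, (20, 4), elements=st.floats(-3, 3)),
    )
    def test_oracle_equivalence_property(self, y, X):
        """Vectorized predictions equal the literal double loop."""
        # keep the response comfortably non-degenerate (subnormal-only
        # draws would underflow the total sum of squares)
        y = y + np.linspace(0, 1, 20)
        fit = npmr_predict(make_design(y, X))
        oracle = naive_npmr_predictions(y, X, 1.0)
        np.testing.assert_allclose(fit.predictions, oracle, atol=1e-10)

    def test_predictions_are_convex_combinations(self, rng):
        y = rng.standard_normal(40)
        X = rng.standard_normal((40, 3)) * 2
        fit = npmr_predict(make_design(y, X))
        for t in np.flatnonzero(fit.valid_mask):
            others = np.delete(y, t)
            assert others.min() - 1e-12 <= fit.predictions[t] <= others.max() + 1e-12

    def test_shift_invariance(self, rng):
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 2))
        fit = npmr_predict(make_design(y, X))
        fit_shifted = npmr_predict(make_design(y, X + np.array([5.0, -11.0])))
        np.testing.assert_allclose(fit_shifted.predictions, fit.predictions, atol=1e-10)
        assert fit_shifted.error_variance == pytest.approx(fit.error_variance, rel=1e-10)

    def test_scale_tolerance_equivalence(self, rng):
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 2))
        fit = npmr_predict(make_design(y, X), KernelConfig([1.0, 2.0]))
        Xs = X * np.array([3.0, 0.25])
        fit_s = npmr_predict(make_design(y, Xs), KernelConfig([3.0, 0.5]))
        np.testing.assert_allclose(fit_s.predictions, fit.predictions, atol=1e-10)

    def test_underflow_points_flagged_or_error(self):
        # far-separated singletons: every LOO denominator underflows
        y = np.arange(5.0)
        X = (np.arange(5.0) * 1e4).reshape(-1, 1)
        with pytest.raises(NPMRError, match="z-score|tolerance"):
            npmr_predict(make_design(y, X), KernelConfig(1.0))


class TestCrossR2:
    def test_perfect_fit(self, rng):
        y = rng.standard_normal(10)
        assert cross_r2(y, y) == 1.0

    def test_mean_predictor_is_zero(self, rng):
        y = rng.standard_normal(10)
        assert cross_r2(y, np.full(10, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_rss_twice_tss_is_minus_one(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        # predictions chosen so RSS = 2 * TSS
        yhat = y - np.sqrt(2.0) * y
        assert cross_r2(y, yhat) == pytest.approx(-1.0, rel=1e-12)

    def test_constant_response_rejected(self):
        with pytest.raises(NPMRError, match="constant"):
            cross_r2(np.ones(5), np.zeros(5))


class TestToleranceFromRange:
    @pytest.mark.parametrize("lo,hi", [(0.0, 6.0), (-3.0, 3.0)])
    def test_six_sd_heuristic(self, lo, hi):
        col = np.linspace(lo, hi, 11)
        assert tolerance_from_range(col) == pytest.approx(1.0)

    def test_affine_scaling(self, rng):
        col = rng.standard_normal(50)
        base = tolerance_from_range(col)
        assert tolerance_from_range(-2.5 * col + 7) == pytest.approx(2.5 * base, rel=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(NPMRError):
            tolerance_from_range(np.full(5, 3.3))
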