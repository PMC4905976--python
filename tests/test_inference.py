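import numpy as np
import pytest

from cnpmr import (
    KernelConfig,
    SimulationSpec,
    SurrogateConfig,
    TimeSeriesSet,
    build_design,
    sensitivity_all,
    sensitivity_profile,
    sensitivity_q,
    significance_test,
    simulate,
    surrogate_count,
    time_shift_surrogate,
)
from cnpmr.embedding import EmbeddedDesign

from conftest import naive_npmr_predictions


class TestSurrogateCount:
    @pytest.mark.parametrize("alpha,expected", [(0.05, 19), (0.01, 99), (0.5, 1), (0.3, 3)])
    def test_formula(self, alpha, expected):
        assert surrogate_count(alpha) == expected

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 2.0])
    def test_alpha_out_of_range(self, alpha):
        with pytest.raises(ValueError):
            surrogate_count(alpha)


class TestTimeShiftSurrogate:
    def test_is_permutation(self, rng):
        x = rng.standard_normal(100)
        s = time_shift_surrogate(x, SurrogateConfig(), rng)
        np.testing.assert_array_equal(np.sort(s), np.sort(x))

    def test_shift_bound_over_many_draws(self, rng):
        x = np.arange(90.0)
        lo = int(np.ceil(90 / 3))
        for _ in range(1000):
            s = time_shift_surrogate(x, SurrogateConfig(), rng)
            shift = (90 - int(s[0])) % 90  # rolled identity reveals the offset
            assert lo <= shift <= 89

    def test_circular_autocorrelation_preserved(self, rng):
        x = rng.standard_normal(128)
        s = time_shift_surrogate(x, SurrogateConfig(), rng)
        # circular autocorrelation via FFT is shift-invariant
        ac_x = np.real(np.fft.ifft(np.abs(np.fft.fft(x)) ** 2))
        ac_s = np.real(np.fft.ifft(np.abs(np.fft.fft(s)) ** 2))
        np.testing.assert_allclose(ac_s, ac_x, rtol=1e-10)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            time_shift_surrogate(np.arange(4.0), SurrogateConfig(), rng)


class TestSignificanceTest:
    def test_reproducible_threshold(self, white_noise_pair):
        cfg = SurrogateConfig(seed=5)
        r1 = significance_test(white_noise_pair, "a", "b", surrogate_cfg=cfg)
        r2 = significance_test(white_noise_pair, "a", "b", surrogate_cfg=cfg)
        assert r1.threshold == r2.threshold
        assert r1.value_raw == r2.value_raw

    def test_true_coupling_detected_null_rejected(self):
        spec = SimulationSpec(model_id="ds1_unidir_nonlinear", n_samples=1000, seed=21)
        hits_fwd = 0
        hits_rev = 0
        n = 10
        for r in range(n):
            ts = simulate(spec, realization=r)
            cfg = SurrogateConfig(seed=100 + r)
            hits_fwd += significance_test(ts, "x2", "x1", surrogate_cfg=cfg).significant
            hits_rev += significance_test(ts, "x1", "x2", surrogate_cfg=cfg).significant
        assert hits_fwd >= 9
        assert hits_rev <= 1

    def test_insignificant_result_clips_to_zero(self, white_noise_pair):
        res = significance_test(white_noise_pair, "a", "b", surrogate_cfg=SurrogateConfig(seed=2))
        if res.value_raw < 0:
            assert res.value == 0.0
        assert res.significant == (res.value_raw > res.threshold)


def make_design(y, X):
    X = np.atleast_2d(np.asarray(X, float))
    return EmbeddedDesign(
        response=np.asarray(y, float), predictors=X,
        labels=tuple(("p", j + 1) for j in range(X.shape[1])),
        tau=1, dim_d=X.shape[1], t_offset=0,
    )


class TestSensitivityQ:
    def test_matches_finite_difference_oracle(self, rng):
        y = rng.standard_normal(10)
        X = rng.standard_normal((10, 2))
        delta = 0.05
        q = sensitivity_q(make_design(y, X), KernelConfig(), predictor_index=1, delta=delta)
        # oracle: recompute the weighted mean at nudged query points
        base = naive_npmr_predictions(y, X, 1.0)
        col = X[:, 1]
        d_abs = delta * (col.max() - col.min())
        up, dn = X.copy(), X.copy()
        up[:, 1] += d_abs
        dn[:, 1] -= d_abs
        y_up = naive_npmr_predictions(y, X, 1.0, queries=up)
        y_dn = naive_npmr_predictions(y, X, 1.0, queries=dn)
        expected = np.sum(np.abs(y_up - base) + np.abs(y_dn - base)) / (
            2 * len(y) * (y.max() - y.min()) * delta
        )
        assert q == pytest.approx(expected, abs=1e-10)

    def test_flat_kernel_predictor_has_zero_sensitivity(self, rng):
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 2))
        q = sensitivity_q(make_design(y, X), KernelConfig([1.0, 1e9]), predictor_index=1)
        assert q == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_predictor_offset(self, rng):
        y = rng.standard_normal(25)
        X = rng.standard_normal((25, 2))
        q0 = sensitivity_q(make_design(y, X), predictor_index=0)
        X2 = X + np.array([100.0, 0.0])
        q1 = sensitivity_q(make_design(y, X2), predictor_index=0)
        assert q1 == pytest.approx(q0, rel=1e-10)

    def test_constant_column_rejected(self, rng):
        y = rng.standard_normal(10)
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        with pytest.raises(Exception, match="constant"):
            sensitivity_q(make_design(y, X), predictor_index=0)


class TestSensitivityProfile:
    @pytest.fixture
    def coupled_ts(self):
        return simulate(SimulationSpec(model_id="ds1_unidir_nonlinear", n_samples=600, seed=31))

    def test_empty_profile_without_significant_links(self, white_noise_pair):
        from cnpmr import CausalityResult

        results = {
            ("a", "b"): CausalityResult("a", "b", (), -0.1, 1.0, 1.1, significant=False, threshold=0.1)
        }
        prof = sensitivity_profile(white_noise_pair, "b", results)
        assert prof.entries == ()

    def test_gated_entries_cover_significant_sources(self, coupled_ts):
        res = significance_test(coupled_ts, "x2", "x1", surrogate_cfg=SurrogateConfig(seed=4))
        assert res.significant  # strong true edge
        prof = sensitivity_profile(coupled_ts, "x1", {("x2", "x1"): res})
        assert [(ch, lag) for ch, lag, _ in prof.entries] == [("x2", 1), ("x2", 2), ("x2", 3)]
        assert all(q > 0 for _, _, q in prof.entries)

    def test_zero_gating_keeps_rows(self, white_noise_pair):
        from cnpmr import CausalityResult

        results = {
            ("a", "b"): CausalityResult("a", "b", (), -0.1, 1.0, 1.1, significant=False, threshold=0.1)
        }
        prof = sensitivity_profile(white_noise_pair, "b", results, gate="zero")
        assert [(ch, lag, q) for ch, lag, q in prof.entries] == [("a", 1, 0.0), ("a", 2, 0.0), ("a", 3, 0.0)]
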