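import numpy as np
import pytest

from posturedyn import (EmbeddingParams, RunConfig, delay_embed,
                        detect_heel_strikes, false_nearest_neighbors,
                        fit_lambda_star, lambda_for_trial,
                        mutual_information_delay, mutual_information_profile,
                        rosenstein_curve)
from posturedyn.errors import EstimationError, FitError, ParameterError


class TestDelayEmbed:
    def test_basic_shape_and_first_row(self):
        st = delay_embed(np.arange(1.0, 11.0), EmbeddingParams(delay=3, dim=2))
        assert st.shape == (7, 2)
        np.testing.assert_array_equal(st[0], [1.0, 4.0])

    def test_dim_one_is_identity_column(self):
        x = np.arange(5.0)
        st = delay_embed(x, EmbeddingParams(delay=2, dim=1))
        np.testing.assert_array_equal(st[:, 0], x)

    def test_columns_are_shifted_copies(self, rng):
        x = rng.normal(size=100)
        p = EmbeddingParams(delay=4, dim=3)
        st = delay_embed(x, p)
        for j in range(p.dim):
            np.testing.assert_array_equal(st[:, j], x[4 * j:4 * j + st.shape[0]])

    def test_too_short(self):
        with pytest.raises(ParameterError):
            delay_embed(np.arange(5.0), EmbeddingParams(delay=3, dim=3))


class TestMutualInformation:
    def test_sine_first_minimum_near_quarter_period(self):
        t = np.arange(9000)
        x = np.sin(2 * np.pi * t / 300)
        delay, det = mutual_information_delay(x, 150, return_details=True)
        assert det["method"] == "local_min"
        assert 300 / 4 * 0.9 <= delay <= 300 / 4 * 1.1

    def test_white_noise_falls_back(self, rng):
        delay, det = mutual_information_delay(rng.normal(size=8000), 100,
                                              return_details=True)
        assert det["method"] != "local_min"
        assert delay >= 1

    def test_constant_series_rejected(self):
        with pytest.raises(EstimationError):
            mutual_information_profile(np.ones(1000), 10)

    def test_lag_zero_never_returned(self, rng):
        x = np.sin(np.arange(5000) * 0.1) + 0.01 * rng.normal(size=5000)
        assert mutual_information_delay(x, 80) >= 1


class TestFNN:
    def test_lorenz_unfolds_by_dimension_three(self, lorenz_x):
        delay = mutual_information_delay(lorenz_x, 200)
        fr = false_nearest_neighbors(lorenz_x, delay, dims=(1, 2, 3))
        assert fr[3] < 0.05

    def test_sine_unfolds_by_dimension_two(self):
        x = np.sin(2 * np.pi * np.arange(6000) / 300)
        fr = false_nearest_neighbors(x, 75, dims=(1, 2))
        assert fr[2] < 0.01

    def test_iid_noise_stays_high(self, rng, lorenz_x):
        delay = mutual_information_delay(lorenz_x, 200)
        fr_det = false_nearest_neighbors(lorenz_x, delay, dims=(3,))
        noise = rng.normal(size=6000)
        fr_noise = false_nearest_neighbors(noise, 1, dims=(3,))
        assert fr_noise[3] > fr_det[3]


class TestRosensteinCurve:
    def test_translated_twin_trajectories_stay_at_offset(self, rng):
        # two copies of the same trajectory offset by a constant: the
        # nearest cross-copy neighbour stays at exactly that offset, so
        # the log-distance curve is flat at log(c * sqrt(dim))
        from posturedyn.preprocess import moving_average
        x = moving_average(np.cumsum(rng.normal(size=400)), 15)
        emb = delay_embed(x, EmbeddingParams(delay=5, dim=3))
        c = 1e-3
        states = np.vstack([emb, emb + c])
        lags, curve = rosenstein_curve(states, theiler=3, max_lag=50)
        expected = np.log(c * np.sqrt(3))
        half = emb.shape[0]
        # restrict to lags where all pairs are still twin-aligned
        np.testing.assert_allclose(curve[:10], expected, atol=1e-6)

    def test_too_few_states(self):
        with pytest.raises(EstimationError):
            rosenstein_curve(np.zeros((50, 3)), theiler=1, max_lag=10)

    def test_theiler_too_wide(self, rng):
        states = rng.normal(size=(120, 3))
        with pytest.raises(EstimationError):
            rosenstein_curve(states, theiler=119, max_lag=5)


class TestFitLambdaStar:
    def test_exact_linear_curve_any_bounds(self):
        lags = np.arange(101)
        y = lags / 100.0
        for lo, hi in [(0.1, 0.9), (0.2, 0.7), (0.05, 0.95)]:
            res = fit_lambda_star(lags, y, lo, hi, samples_per_unit=200)
            assert res.lambda_star == pytest.approx(2.0, abs=1e-9)

    def test_shift_invariance(self, rng):
        lags = np.arange(200)
        y = np.log1p(lags / 30.0) + 0.01 * rng.normal(size=200)
        a = fit_lambda_star(lags, y, samples_per_unit=200)
        b = fit_lambda_star(lags, y + 5.0, samples_per_unit=200)
        assert a.lambda_star == pytest.approx(b.lambda_star, abs=1e-12)
        assert (a.fit_lo_idx, a.fit_hi_idx) == (b.fit_lo_idx, b.fit_hi_idx)

    def test_saturating_curve_slope_between_tangents(self):
        tau = 30.0
        lags = np.arange(300)
        y = 1.0 - np.exp(-lags / tau)
        res = fit_lambda_star(lags, y, 0.1, 0.9, samples_per_unit=1)
        # tangent slopes of 1-exp(-t/tau) at the lo and hi levels
        slope_at_lo = (1 - 0.1) / tau
        slope_at_hi = (1 - 0.9) / tau
        assert slope_at_hi < res.lambda_star < slope_at_lo

    def test_flat_curve_reports_zero(self):
        res = fit_lambda_star(np.arange(50), np.full(50, -7.0))
        assert res.lambda_star == 0.0
        assert "flat_curve" in res.flags

    def test_too_small_region(self):
        y = np.array([0.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.raises(FitError):
            fit_lambda_star(np.arange(5), y, 0.1, 0.9)


@pytest.fixture(scope="module")
def gait_trial_events(small_gait):
    rec, truth = small_gait
    return rec, detect_heel_strikes(rec)


class TestLambdaPipeline:
    CFG = RunConfig(n_strides=50, div_max_strides=5.0)

    def test_deterministic_to_the_last_bit(self, gait_trial_events):
        rec, ev = gait_trial_events
        a = lambda_for_trial(rec, ev, ("fz",), self.CFG)["fz"]
        b = lambda_for_trial(rec, ev, ("fz",), self.CFG)["fz"]
        assert a.lambda_star == b.lambda_star
        np.testing.assert_array_equal(a.mean_log_div, b.mean_log_div)

    def test_positive_rescaling_invariance(self, gait_trial_events):
        rec, ev = gait_trial_events
        a = lambda_for_trial(rec, ev, ("copx",), self.CFG)["copx"]
        scaled = rec.replace(copx=rec.copx * 2.0)
        b = lambda_for_trial(scaled, ev, ("copx",), self.CFG)["copx"]
        assert abs(a.lambda_star - b.lambda_star) <= 1e-9

    def test_channels_embedded_separately(self, gait_trial_events):
        rec, ev = gait_trial_events
        out = lambda_for_trial(rec, ev, ("fz", "copx"), self.CFG)
        assert out["fz"].params.delay != out["copx"].params.delay
        assert out["fz"].params.dim == out["copx"].params.dim == 5
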