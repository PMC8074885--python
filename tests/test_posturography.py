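import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturedyn import (MSDCurve, SwaySpec, detect_critical_point,
                        fit_short_term_coefficients, gen_sway,
                        mean_square_displacement, sway_summary)
from posturedyn.errors import FitError, ParameterError


def brute_force_msd(x, y, fs, max_dt):
    """O(N^2) literal evaluation of the displacement average."""
    n = len(x)
    max_m = int(np.floor(max_dt * fs))
    mx, my = [], []
    for m in range(1, max_m + 1):
        sx = sum((x[i + m] - x[i]) ** 2 for i in range(n - m))
        sy = sum((y[i + m] - y[i]) ** 2 for i in range(n - m))
        mx.append(sx / (n - m))
        my.append(sy / (n - m))
    return np.array(mx), np.array(my)


class TestMSD:
    def test_constant_trajectory_is_zero(self):
        x = np.full(100, 5.0)
        curve = mean_square_displacement(x, x, fs=100.0, max_dt=0.5)
        assert np.all(curve.msd_r == 0)

    def test_hand_example(self):
        # positions 0,1,2 at 1 Hz: m=1 -> (1+1)/2 = 1 ; m=2 -> 4/1 = 4
        x = np.array([0.0, 1.0, 2.0])
        y = np.zeros(3)
        curve = mean_square_displacement(x, y, fs=1.0, max_dt=2.0)
        np.testing.assert_allclose(curve.msd_x, [1.0, 4.0])
        np.testing.assert_allclose(curve.msd_r, [1.0, 4.0])
        np.testing.assert_array_equal(curve.n_pairs, [2, 1])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(50, 300))
            x = np.cumsum(rng.normal(size=n))
            y = np.cumsum(rng.normal(size=n))
            curve = mean_square_displacement(x, y, fs=100.0, max_dt=0.2)
            bx, by = brute_force_msd(x, y, 100.0, 0.2)
            np.testing.assert_allclose(curve.msd_x, bx, atol=1e-9)
            np.testing.assert_allclose(curve.msd_y, by, atol=1e-9)

    def test_planar_additivity_is_exact(self, rng):
        x = np.cumsum(rng.normal(size=500))
        y = np.cumsum(rng.normal(size=500))
        curve = mean_square_displacement(x, y, fs=100.0, max_dt=1.0)
        np.testing.assert_allclose(curve.msd_r, curve.msd_x + curve.msd_y,
                                   atol=1e-9)

    def test_bad_max_dt(self):
        with pytest.raises(ParameterError):
            mean_square_displacement(np.zeros(50), np.zeros(50), 100.0,
                                     max_dt=10.0)


class TestFit:
    def test_exact_linear_curve_recovers_d(self):
        fs = 100.0
        dt = np.arange(1, 101) / fs
        msd = 2 * 3.0 * dt  # D = 3
        curve = MSDCurve(dt=dt, msd_x=msd, msd_y=np.zeros_like(msd),
                         msd_r=msd, n_pairs=np.full(100, 10))
        res = fit_short_term_coefficients(curve, (0.02, 0.5))
        assert res.dxs == pytest.approx(3.0, abs=1e-9)
        assert res.dys == pytest.approx(0.0, abs=1e-9)
        assert res.drs == pytest.approx(3.0, abs=1e-9)

    def test_planar_coefficient_adds(self, rng):
        x = np.cumsum(rng.normal(size=2000))
        y = np.cumsum(rng.normal(size=2000))
        curve = mean_square_displacement(x, y, fs=100.0, max_dt=1.0)
        res = fit_short_term_coefficients(curve)
        assert res.drs == pytest.approx(res.dxs + res.dys, abs=1e-9)

    def test_too_few_points(self):
        dt = np.array([0.01, 0.02, 0.03])
        curve = MSDCurve(dt=dt, msd_x=dt, msd_y=dt, msd_r=2 * dt,
                         n_pairs=np.array([9, 8, 7]))
        with pytest.raises(FitError):
            fit_short_term_coefficients(curve, (0.5, 1.0))

    def test_negative_slope_flagged_not_clamped(self):
        dt = np.arange(1, 60) / 100.0
        msd = 1.0 - 0.5 * dt
        curve = MSDCurve(dt=dt, msd_x=msd, msd_y=np.zeros_like(dt),
                         msd_r=msd, n_pairs=np.full(59, 5))
        res = fit_short_term_coefficients(curve)
        assert res.dxs < 0
        assert any("negative_slope" in f for f in res.flags)


class TestCriticalPoint:
    @staticmethod
    def _curve(y, fs=100.0):
        dt = np.arange(1, len(y) + 1) / fs
        return MSDCurve(dt=dt, msd_x=y / 2, msd_y=y / 2, msd_r=y,
                        n_pairs=np.full(len(y), 100))

    def test_exact_piecewise_break_recovered(self):
        dt = np.arange(1, 201) / 100.0
        y = np.where(dt <= 1.0, 4.0 * dt, 4.0 + 0.5 * (dt - 1.0))
        b = detect_critical_point(self._curve(y))
        assert b == pytest.approx(1.0, abs=0.011)

    def test_straight_line_gives_none(self):
        dt = np.arange(1, 201) / 100.0
        assert detect_critical_point(self._curve(4.0 * dt)) is None

    def test_two_regime_sway_breakpoint_recovery(self):
        # OU sway calibrated to break at 0.8 s: the breakpoint estimated
        # from finite trials should agree with the programmed regime
        # switch within +/- 0.3 s on average
        target = 0.8
        est = []
        for seed in range(20):
            rec = gen_sway(SwaySpec(d_ml=2.0, d_ap=2.0, regime_switch=target,
                                    seed=seed))
            curve = mean_square_displacement(rec.copx, rec.copy, rec.fs, 2.0)
            b = detect_critical_point(curve)
            if b is not None:
                est.append(b)
        assert len(est) >= 15
        assert abs(np.mean(est) - target) < 0.3


class TestSwaySummary:
    @staticmethod
    def _diff():
        from posturedyn import DiffusionResult
        return DiffusionResult(dxs=2.0, dys=1.0, drs=3.0,
                               fit_window=(0.02, 0.5),
                               r2_x=1, r2_y=1, r2_r=1)

    def test_circle_is_isotropic(self):
        th = np.linspace(0, 2 * np.pi, 1000)
        s = sway_summary(5 * np.cos(th), 5 * np.sin(th), self._diff())
        assert s.range_ml == pytest.approx(10.0, abs=1e-3)
        assert s.range_ap == pytest.approx(10.0, abs=1e-3)
        assert s.srd == pytest.approx(0.0, abs=1e-3)

    def test_ellipse_srd(self):
        th = np.linspace(0, 2 * np.pi, 2000)
        s = sway_summary(6 * np.cos(th), 2 * np.sin(th), self._diff())
        assert s.srd == pytest.approx(8.0, abs=1e-3)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_ranges_match_direct_scan(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=200), r.normal(size=200)
        s = sway_summary(x, y, self._diff())
        assert s.range_ml == x.max() - x.min()
        assert s.range_ap == y.max() - y.min()
        assert s.srd == s.range_ml - s.range_ap

    def test_ln_transform_and_nonpositive_flag(self):
        from posturedyn import DiffusionResult
        d = DiffusionResult(dxs=2.0, dys=-0.1, drs=1.9,
                            fit_window=(0.02, 0.5), r2_x=1, r2_y=1, r2_r=1)
        s = sway_summary(np.array([0.0, 1.0]), np.array([0.0, 1.0]), d)
        assert s.ln_dxs == pytest.approx(np.log(2.0))
        assert np.isnan(s.ln_dys)
        assert any("ln_skipped" in f for f in s.flags)
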