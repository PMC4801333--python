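import numpy as np
import pytest

from canaloflow import (build_mask, classify_filling, downsample,
                        extract_half_max, fit_all, fit_curve, generate,
                        normalize_percent)
from conftest import make_small_spec


TIMES = 30.0 * np.arange(41)


def brute_force_half_max(fit, t_first, t_last, step):
    """Independent oracle: plain dense scan, no interpolation."""
    tt = np.arange(t_first, t_last + step / 2, step)
    vv = np.asarray(fit(tt), dtype=float)
    I_max = vv.max()
    return I_max, I_max / 2, tt[np.nonzero(vv >= I_max / 2)[0][0]]


class TestFitCurve:
    def test_linear_ramp_recovered(self):
        fit = fit_curve(TIMES, TIMES.copy())
        np.testing.assert_allclose(fit(TIMES), TIMES, rtol=1e-6,
                                   atol=1e-6 * TIMES[-1])

    def test_constant_series_stays_constant(self):
        fit = fit_curve(TIMES, np.full(41, 42.0))
        np.testing.assert_allclose(fit(TIMES), 42.0, rtol=1e-8)

    def test_noiseless_logistic_within_2pct(self):
        truth = 100.0 / (1.0 + np.exp(-(TIMES - 300.0) / 60.0))
        fit = fit_curve(TIMES, truth)
        interior = slice(1, -1)
        np.testing.assert_allclose(fit(TIMES[interior]), truth[interior],
                                   rtol=0.02, atol=0.02 * 100)

    def test_matches_independent_gam_backend(self):
        """Cross-check against statsmodels GLMGam (penalized B-splines,
        GCV-selected penalty) on a noisy logistic: the two smooths agree
        within 2% of the amplitude at every observation."""
        from statsmodels.gam.api import BSplines, GLMGam

        rng = np.random.default_rng(0)
        y = 20 + 1000 / (1 + np.exp(-(TIMES - 300) / 60.0))
        y = y + rng.normal(0, 25, TIMES.size)
        bs = BSplines(TIMES[:, None], df=[10], degree=[3])
        gam = GLMGam(y, np.ones((TIMES.size, 1)), smoother=bs)
        gam.fit()
        alpha = gam.select_penweight()[0]
        ref = GLMGam(y, np.ones((TIMES.size, 1)), smoother=bs,
                     alpha=alpha).fit().fittedvalues
        mine = fit_curve(TIMES, y)(TIMES)
        assert np.max(np.abs(mine - ref)) <= 0.02 * 1000

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_curve(TIMES[:3], np.ones(3))

    def test_non_finite_rejected(self):
        y = np.ones(41)
        y[5] = np.nan
        with pytest.raises(ValueError):
            fit_curve(TIMES, y)

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        y = rng.random(41) * 50
        a = fit_curve(TIMES, y)
        b = fit_curve(TIMES, y)
        np.testing.assert_array_equal(a.coef, b.coef)
        assert a.lam == b.lam


class TestExtractHalfMax:
    def test_identity_ramp(self):
        I_max, I_half, t_half = extract_half_max(lambda t: np.asarray(t),
                                                 0.0, 1200.0, 3.0)
        assert I_max == pytest.approx(1200.0)
        assert I_half == pytest.approx(600.0)
        assert t_half == pytest.approx(600.0, abs=1e-6)

    def test_plateau_crossing_matches_fine_scan(self):
        """Curve plateauing at 80 from t=300: the analytic crossing of 40
        is reproduced against a brute-force 0.01 s scan."""
        curve = lambda t: np.minimum(np.asarray(t, dtype=float) * 80 / 300, 80.0)
        I_max, I_half, t_half = extract_half_max(curve, 0.0, 1200.0, 3.0)
        assert I_half == pytest.approx(40.0)
        _, _, t_ref = brute_force_half_max(curve, 0.0, 1200.0, 0.01)
        assert t_half == pytest.approx(150.0, abs=0.05)
        assert abs(t_half - t_ref) <= 0.01 + 1e-9

    def test_earliest_crossing_wins(self):
        """Non-monotone curve crossing half-max at 200 s and 700 s."""
        def curve(t):
            t = np.asarray(t, dtype=float)
            bump = 60 * np.exp(-((t - 250) / 60.0) ** 2)
            rise = 100 / (1 + np.exp(-(t - 750) / 40.0))
            return bump + rise
        _, I_half, t_half = extract_half_max(curve, 0.0, 1200.0, 3.0)
        assert t_half < 300.0

    def test_oracle_equivalence_on_random_smooth_curves(self):
        """t_half agrees with a 10x finer brute-force scan within one
        coarse grid step, over 100 random smooth curves."""
        rng = np.random.default_rng(42)
        coarse = 3.0
        for _ in range(100):
            a = rng.uniform(20, 120)
            t50 = rng.uniform(100, 1000)
            tau = rng.uniform(20, 200)
            b = rng.uniform(0, 10)
            w = rng.uniform(5, 30)
            ph = rng.uniform(0, 2 * np.pi)
            curve = lambda t: (b + a / (1 + np.exp(-(np.asarray(t) - t50) / tau))
                               + w * np.sin(np.asarray(t) / 200.0 + ph))
            _, _, t_half = extract_half_max(curve, 0.0, 1200.0, coarse)
            _, _, t_ref = brute_force_half_max(curve, 0.0, 1200.0, coarse / 10)
            assert abs(t_half - t_ref) <= coarse


class TestClassifyFilling:
    def test_flat_series_not_filling(self):
        assert not classify_filling(0.0, 5.0, 5.0, global_max=100.0)

    def test_strong_riser_filling(self):
        assert classify_filling(80.0, 2.0, 82.0, global_max=100.0)

    def test_decaying_curve_not_filling(self):
        assert not classify_filling(50.0, 90.0, 40.0, global_max=100.0)

    def test_subthreshold_range_not_filling(self):
        assert not classify_filling(3.0, 0.0, 3.0, global_max=100.0,
                                    noise_floor=5.0)


class TestFitAll:
    def test_unmasked_grid_fits_everything(self):
        spec = make_small_spec(seed=11, noise_sd=0.0)
        stack, _ = generate(spec, grid_rows=16, grid_cols=16)
        series = normalize_percent(downsample(stack, 16, 16))
        fits = fit_all(series)
        assert len(fits) == 256
        assert fits.n_included == 256

    def test_masked_grid_fit_count_matches_mask(self):
        spec = make_small_spec(seed=11, noise_sd=0.0)
        stack, _ = generate(spec, grid_rows=16, grid_cols=16)
        series = normalize_percent(downsample(stack, 16, 16))
        pa = build_mask(spec.geometry(), series)
        fits = fit_all(series, pa)
        assert fits.n_included == pa.n_included < 256
        assert all((f.curve is None) == (not f.included) for f in fits)

    def test_identical_series_identical_kinetics(self):
        spec = make_small_spec(seed=11, noise_sd=0.0)
        stack, _ = generate(spec, grid_rows=16, grid_cols=16)
        series = normalize_percent(downsample(stack, 16, 16))
        series.intensity[:, 3, 3] = series.intensity[:, 3, 4]
        fits = fit_all(series)
        a, b = fits.get(3, 3), fits.get(3, 4)
        assert a.I_max == b.I_max
        assert a.t_half_s == b.t_half_s

    def test_scaling_values_scales_intensities_not_times(self):
        """Scaling all values by c leaves t_half unchanged and scales
        I_max, I_half and filling rate by c."""
        spec = make_small_spec(seed=13, noise_sd=0.0)
        stack, _ = generate(spec, grid_rows=16, grid_cols=16)
        series = downsample(stack, 16, 16)
        fits1 = fit_all(series)
        series2 = downsample(stack, 16, 16)
        series2.intensity *= 3.0
        fits2 = fit_all(series2)
        for f1, f2 in zip(fits1, fits2):
            if not (f1.filling and f2.filling):
                continue
            assert f2.I_max == pytest.approx(3.0 * f1.I_max, rel=1e-9)
            assert f2.I_half == pytest.approx(3.0 * f1.I_half, rel=1e-9)
            assert f2.t_half_s == pytest.approx(f1.t_half_s, abs=1e-6)
            assert f2.filling_rate == pytest.approx(3.0 * f1.filling_rate,
                                                    rel=1e-9)

    def test_half_max_recovery_on_noisy_logistics(self, whole_eye_run):
        """On the whole-eye preset (41 frames, 30 s, SNR >= 10), at least
        95% of filling macropixels recover t_half within one frame
        interval of the analytic logistic half-crossing."""
        _, _, truth, result = whole_eye_run
        errs = []
        for f in result.fits:
            if f.included and f.filling and truth.filling[f.grid_row, f.grid_col]:
                errs.append(abs(f.t_half_s - truth.t_half_s[f.grid_row,
                                                            f.grid_col]))
        errs = np.asarray(errs)
        assert errs.size > 300
        assert np.mean(errs <= 30.0) >= 0.95
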