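import numpy as np
import pytest

from lexosc.containers import TFR
from lexosc.spectral import (SpectralError, band_power, baseline_normalize,
                             condition_average, fit_fractal, morlet_tfr,
                             subtract_fractal)

from conftest import make_epochs

SFREQ = 500.0


def tone_epochs(freqs_amps, n_trials=2, seconds=4.0, tmin=-2.0):
    t = tmin + np.arange(int(seconds * SFREQ)) / SFREQ
    sig = sum(a * np.cos(2 * np.pi * f * t) for f, a in freqs_amps)
    data = np.tile(sig, (n_trials, 1, 1))
    return make_epochs(data, tmin=tmin)


def raw_tfr(power, freqs, times):
    return TFR(power=power, freqs=freqs, times=times, channels=["ch0"],
               stage="raw")


class TestMorlet:
    def test_frequency_localization(self):
        ds = tone_epochs([(10.0, 1.0)])
        tfr = morlet_tfr(ds, freqs=np.arange(2.0, 30.0), tmin=-0.5, tmax=0.5)
        peak = tfr.freqs[tfr.power.mean(axis=(0, 1, 3)).argmax()]
        assert peak == 10.0

    def test_quadratic_amplitude_scaling(self):
        f = np.arange(5.0, 20.0)
        p1 = morlet_tfr(tone_epochs([(10.0, 1.0)]), freqs=f,
                        tmin=0, tmax=0).power.max()
        p2 = morlet_tfr(tone_epochs([(10.0, 2.0)]), freqs=f,
                        tmin=0, tmax=0).power.max()
        assert abs(p2 / p1 - 4.0) < 0.01

    def test_two_tone_peaks(self):
        ds = tone_epochs([(6.0, 1.0), (30.0, 1.0)])
        tfr = morlet_tfr(ds, freqs=np.arange(2.0, 41.0), tmin=-0.3, tmax=0.3)
        spec = tfr.power.mean(axis=(0, 1, 3))
        low = tfr.freqs[np.argmax(spec * (tfr.freqs < 15))]
        high = tfr.freqs[np.argmax(spec * (tfr.freqs > 15))]
        assert abs(low - 6.0) <= 1.0 and abs(high - 30.0) <= 1.0

    def test_rejects_frequencies_above_nyquist(self):
        with pytest.raises(SpectralError, match="Nyquist"):
            morlet_tfr(tone_epochs([(10.0, 1.0)]), freqs=np.array([300.0]))

    def test_matches_mne_reference_implementation(self, rng):
        """Independent oracle: mne's Morlet TFR on the same data."""
        from mne.time_frequency import tfr_array_morlet

        data = rng.normal(size=(3, 2, 3000))
        ds = make_epochs(data, tmin=-3.0)
        freqs = np.arange(5.0, 41.0, 5.0)
        ours = morlet_tfr(ds, freqs=freqs, tmin=-1.0, tmax=1.0)
        theirs = tfr_array_morlet(data, SFREQ, freqs, n_cycles=5.0,
                                  output="power", zero_mean=False,
                                  verbose="error")
        centers = np.round((ours.times + 3.0) * SFREQ).astype(int)
        theirs_sub = theirs[..., centers]
        a, b = np.log(ours.power.ravel()), np.log(theirs_sub.ravel())
        assert np.corrcoef(a, b)[0, 1] > 0.99

    def test_wavelet_power_additive_across_orthogonal_bands(self):
        f = np.arange(2.0, 41.0)
        kw = dict(freqs=f, tmin=-0.3, tmax=0.3)
        p6 = morlet_tfr(tone_epochs([(6.0, 1.0)]), **kw).power
        p30 = morlet_tfr(tone_epochs([(30.0, 1.0)]), **kw).power
        both = morlet_tfr(tone_epochs([(6.0, 1.0), (30.0, 1.0)]), **kw).power
        resid = np.abs(both - (p6 + p30)).max()
        assert resid < 0.05 * both.max()


class TestFractalFit:
    freqs = np.arange(1.0, 41.0)
    times = np.array([0.0, 0.02])

    def _power_law(self, c, exponent):
        p = c * self.freqs ** (-exponent)
        return np.tile(p[None, None, :, None], (1, 1, 1, 2))

    def test_exact_power_law_recovered(self):
        tfr = raw_tfr(self._power_law(2.0, 1.5), self.freqs, self.times)
        fit = fit_fractal(tfr)
        np.testing.assert_allclose(fit.slope, -1.5, atol=1e-8)
        np.testing.assert_allclose(fit.intercept, np.log(2.0), atol=1e-8)
        corrected = subtract_fractal(tfr, fit)
        assert np.abs(corrected.power).max() < 1e-6

    def test_white_spectrum_zero_slope(self):
        tfr = raw_tfr(self._power_law(3.0, 0.0), self.freqs, self.times)
        fit = fit_fractal(tfr)
        np.testing.assert_allclose(fit.slope, 0.0, atol=1e-8)

    def test_bump_excluded_and_slope_preserved(self):
        p = self._power_law(1.0, 1.0)
        bump = 5.0 * np.exp(-(self.freqs - 10.0) ** 2 / 2.0)
        p = p * (1 + bump[None, None, :, None])
        tfr = raw_tfr(p, self.freqs, self.times)
        fit = fit_fractal(tfr)
        assert np.all(np.abs(fit.slope + 1.0) < 0.1)
        excluded = ~fit.included[0, 0, :, 0]
        assert excluded[self.freqs == 10.0][0]

    def test_corrected_bump_positive_only_at_oscillation(self):
        p = self._power_law(1.0, 1.0)
        bump = 5.0 * np.exp(-(self.freqs - 10.0) ** 2 / 2.0)
        p = p * (1 + bump[None, None, :, None])
        tfr = raw_tfr(p, self.freqs, self.times)
        corrected = subtract_fractal(tfr, fit_fractal(tfr))
        prof = corrected.power[0, 0, :, 0]
        assert prof[self.freqs == 10.0][0] > 1.0
        away = np.abs(self.freqs - 10.0) > 6
        assert np.abs(prof[away]).max() < 0.1

    def test_subtraction_idempotent_for_aperiodic_removal(self):
        tfr = raw_tfr(self._power_law(2.0, 1.2), self.freqs, self.times)
        corrected = subtract_fractal(tfr, fit_fractal(tfr))
        relin = TFR(power=np.exp(corrected.power), freqs=self.freqs,
                    times=self.times, channels=["ch0"], stage="raw")
        refit = fit_fractal(relin)
        np.testing.assert_allclose(refit.slope, 0.0, atol=1e-6)

    def test_grid_mismatch_rejected(self):
        tfr = raw_tfr(self._power_law(1.0, 1.0), self.freqs, self.times)
        fit = fit_fractal(tfr)
        other = raw_tfr(self._power_law(1.0, 1.0)[:, :, :20],
                        self.freqs[:20], self.times)
        with pytest.raises(SpectralError):
            subtract_fractal(other, fit)

    def test_exponent_recovery_from_synthetic_background(self):
        """End-to-end: 1/f backgrounds in {0.5, 1.0, 1.5} recovered within
        +-0.1 by the wavelet + iterative-fit chain (mean over 20 seeds)."""
        from lexosc.simulate import generate_background_1f

        for exponent in (0.5, 1.0, 1.5):
            slopes = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                sig = np.stack([
                    generate_background_1f(2000, SFREQ, exponent, 1.0, rng)
                    for _ in range(32)])
                ds = make_epochs(sig[:, None, :], tmin=-2.0)
                tfr = morlet_tfr(ds, freqs=np.arange(3.0, 41.0),
                                 out_times=[-0.2, 0.0, 0.2])
                fit = fit_fractal(tfr, share_trials=True, share_times=True)
                slopes.append(float(fit.slope[0, 0, 0]))
            assert abs(np.mean(slopes) + exponent) < 0.1


class TestBaselineNormalize:
    freqs = np.arange(25.0, 36.0)
    times = np.arange(-0.7, 0.5, 0.02)

    def _tfr_with_ratio(self, ratio):
        power = np.ones((1, 1, len(self.freqs), len(self.times)))
        power[..., self.times > 0.1] = ratio
        return raw_tfr(power, self.freqs, self.times)

    def test_stationary_signal_normalizes_to_zero(self):
        norm = baseline_normalize(self._tfr_with_ratio(1.0))
        assert np.abs(norm.power).max() < 1e-12

    def test_relative_change_definition(self):
        norm = baseline_normalize(self._tfr_with_ratio(0.79))
        val = norm.power[0, 0, :, self.times > 0.1]
        np.testing.assert_allclose(val, -0.21, atol=1e-9)

    def test_scale_invariance(self, rng):
        power = np.abs(rng.normal(size=(2, 1, len(self.freqs),
                                        len(self.times)))) + 0.1
        a = baseline_normalize(raw_tfr(power, self.freqs, self.times))
        b = baseline_normalize(raw_tfr(power * 37.5, self.freqs, self.times))
        np.testing.assert_allclose(a.power, b.power, rtol=1e-6)

    def test_double_normalization_rejected(self):
        norm = baseline_normalize(self._tfr_with_ratio(0.9))
        with pytest.raises(SpectralError):
            baseline_normalize(norm)


class TestBandPower:
    def test_constant_field_returns_value(self):
        freqs = np.arange(25.0, 36.0)
        times = np.arange(-0.1, 0.4, 0.02)
        tfr = TFR(power=np.full((3, 2, len(freqs), len(times)), 0.42),
                  freqs=freqs, times=times, channels=["a", "b"],
                  stage="baseline_normalized")
        out = band_power(tfr, (25, 35), (0.0, 0.3), channels=["a", "b"])
        np.testing.assert_allclose(out, 0.42, atol=1e-12)

    def test_averaging_order_identity(self, rng):
        freqs = np.arange(25.0, 36.0)
        times = np.arange(0.0, 0.3, 0.02)
        power = rng.normal(size=(2, 3, len(freqs), len(times)))
        tfr = TFR(power=power, freqs=freqs, times=times,
                  channels=list("abc"), stage="baseline_normalized")
        ours = band_power(tfr, (25, 35), (0.0, 0.28))
        flat = power.reshape(2, -1).mean(axis=1)
        np.testing.assert_allclose(ours, flat, rtol=1e-6)

    def test_empty_selection_rejected(self):
        freqs = np.arange(25.0, 36.0)
        times = np.arange(0.0, 0.3, 0.02)
        tfr = TFR(power=np.zeros((1, 1, len(freqs), len(times))), freqs=freqs,
                  times=times, channels=["a"], stage="baseline_normalized")
        with pytest.raises(SpectralError):
            band_power(tfr, (100, 120), (0.0, 0.2), channels=["a"])


class TestConditionAverage:
    def test_requires_usable_trials_per_condition(self, rng):
        ds = make_epochs(rng.normal(size=(4, 1, 3000)), tmin=-3.0,
                         task=["naming"] * 4,
                         cognate=["noncognate"] * 4)
        tfr = morlet_tfr(ds, freqs=np.arange(5.0, 11.0), tmin=0, tmax=0.2)
        with pytest.raises(SpectralError, match="no usable trials"):
            condition_average(tfr, ds)
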