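import numpy as np
import pytest
from scipy import signal as sps

from lexosc.config import CONDITION_KEYS, SyntheticConfig
from lexosc.pac import extraction_segment, modulation_index, phase_amplitude_series
from lexosc.simulate import (SimulationError, band_dilution,
                             calibrate_coupling, draw_subject_effects,
                             generate_background_1f, generate_behavior_table,
                             generate_cohort, inject_oscillation_effect,
                             inject_pac, solve_effect_step,
                             synthesize_condition_trials)


def fitted_loglog_slope(signals, sfreq, fmin=1.0, fmax=100.0):
    """Least-squares log-log slope of the mean periodogram (oracle)."""
    freqs, psd = sps.periodogram(signals, fs=sfreq, axis=-1)
    psd = psd.mean(axis=0)
    sel = (freqs >= fmin) & (freqs <= fmax)
    return np.polyfit(np.log(freqs[sel]), np.log(psd[sel]), 1)[0]


class TestBackground1f:
    @pytest.mark.parametrize("exponent", [0.0, 1.0])
    def test_spectral_slope_matches_exponent(self, exponent):
        rng = np.random.default_rng(7)
        sig = np.stack([generate_background_1f(2000, 500.0, exponent, 1.0, rng)
                        for _ in range(50)])
        slope = fitted_loglog_slope(sig, 500.0)
        assert abs(slope - (-exponent)) < 0.1

    def test_same_seed_is_deterministic(self):
        a = generate_background_1f(1000, 500.0, 1.0, 1.0,
                                   np.random.default_rng(3))
        b = generate_background_1f(1000, 500.0, 1.0, 1.0,
                                   np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_too_short_raises(self):
        with pytest.raises(SimulationError):
            generate_background_1f(1, 500.0, 1.0, 1.0,
                                   np.random.default_rng(0))


class TestInjectOscillation:
    times = -1.0 + np.arange(1000) / 500.0

    def band_power_oracle(self, epoch, band, mask):
        """Direct band power via Butterworth band-pass variance."""
        sos = sps.butter(4, band, btype="bandpass", fs=500.0, output="sos")
        filtered = sps.sosfiltfilt(sos, epoch, axis=-1)
        return (filtered[..., mask] ** 2).mean()

    def test_null_injection_leaves_band_power_flat(self, rng):
        epoch = np.zeros((1, 1000))
        out = inject_oscillation_effect(epoch, 500.0, self.times, (25, 35),
                                        (0.2, 0.6), 0.0, 2.0, rng)
        w = (self.times >= 0.2) & (self.times <= 0.6)
        b = (self.times >= -0.8) & (self.times <= -0.3)
        ratio = self.band_power_oracle(out, (25, 35), w) / \
            self.band_power_oracle(out, (25, 35), b)
        assert abs(ratio - 1) < 0.05

    def test_rel_change_three_quadruples_band_power(self, rng):
        epoch = np.zeros((1, 1000))
        out = inject_oscillation_effect(epoch, 500.0, self.times, (25, 35),
                                        (0.1, 0.7), 3.0, 2.0, rng)
        w = (self.times >= 0.2) & (self.times <= 0.6)
        b = (self.times >= -0.8) & (self.times <= -0.3)
        ratio = self.band_power_oracle(out, (25, 35), w) / \
            self.band_power_oracle(out, (25, 35), b)
        assert abs(ratio - 4.0) < 0.4

    def test_band_outside_nyquist_raises(self, rng):
        with pytest.raises(SimulationError):
            inject_oscillation_effect(np.zeros((1, 1000)), 500.0, self.times,
                                      (100, 300), (0, 0.5), 0.1, 1.0, rng)


class TestInjectPac:
    times = -1.0 + np.arange(2000) / 500.0

    def _mi_of(self, epoch, m=None):
        phase, amp = phase_amplitude_series(epoch[0], 500.0, 5.0, 30.0)
        mi, prof = modulation_index(phase, amp)
        return mi, prof

    def test_uncoupled_matches_noise_floor(self, rng):
        noise = rng.normal(0, 0.1, size=(1, 2000))
        mi0, _ = self._mi_of(inject_pac(noise.copy(), 500.0, self.times,
                                        5.0, 30.0, 0.0, rng))
        assert mi0 < 0.01

    def test_mi_monotone_in_coupling(self):
        ms = [0.0, 0.2, 0.5, 0.8]
        means = []
        for m in ms:
            rng = np.random.default_rng(11)
            vals = []
            for _ in range(200):
                noise = rng.normal(0, 0.3, size=(1, 2000))
                epoch = inject_pac(noise, 500.0, self.times, 5.0, 30.0, m, rng)
                vals.append(self._mi_of(epoch)[0])
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_invalid_coupling_or_frequencies_raise(self, rng):
        with pytest.raises(SimulationError):
            inject_pac(np.zeros((1, 2000)), 500.0, self.times, 5, 30, 1.5, rng)
        with pytest.raises(SimulationError):
            inject_pac(np.zeros((1, 2000)), 500.0, self.times, 30, 5, 0.5, rng)


class TestEffectStepSolver:
    def test_coherent_solution_satisfies_quadratic(self):
        times = -1.0 + np.arange(1000) / 500.0
        h, box = solve_effect_step(-0.21, times, 500.0, (0.16, 0.26), 29.8)
        from lexosc.simulate import _smoothed_boxcar, _wavelet_sigma_t
        sigma = _wavelet_sigma_t(29.8)
        sup = (times[box > 0][0], times[box > 0][-1])
        g = _smoothed_boxcar(times, sup, sigma, 500.0)
        w = (times >= 0.16) & (times <= 0.26)
        b = (times >= -0.7) & (times <= -0.2)
        lhs = ((1 + h * g[w]) ** 2).mean() / ((1 + h * g[b]) ** 2).mean()
        assert abs(lhs - (1 - 0.21)) < 1e-9

    def test_unreachable_change_raises(self):
        times = -1.0 + np.arange(1000) / 500.0
        with pytest.raises(SimulationError):
            solve_effect_step(-0.9999, times, 500.0, (0.16, 0.26), 5.0,
                              carrier="incoherent")

    def test_band_dilution_in_unit_interval(self):
        cfg = SyntheticConfig()
        for band in ("theta", "beta"):
            d = band_dilution(cfg, band, 29.8)
            assert 0.5 < d <= 1.0


class TestCoupledTrials:
    def test_beta_amplitude_tracks_theta_phase(self):
        cfg = SyntheticConfig(trial_power_jitter_sd=0.0)
        rng = np.random.default_rng(2)
        trials = synthesize_condition_trials(
            cfg, rng, 8, 1, "naming", "naming_nc", beta_rel=0.0,
            theta_rel=0.0, coupling_m=0.9, beta_carrier=29.8)
        seg = extraction_segment((0.16, 0.26), 5.0, cfg.times)
        mis = []
        for tr in trials[:, 0]:
            phase, amp = phase_amplitude_series(tr, 500.0, 5.0, 29.8)
            mis.append(modulation_index(phase[seg], amp[seg])[0])
        uncoupled = synthesize_condition_trials(
            cfg, np.random.default_rng(2), 8, 1, "naming", "naming_nc",
            beta_rel=0.0, theta_rel=0.0, coupling_m=0.0, beta_carrier=29.8)
        mis0 = []
        for tr in uncoupled[:, 0]:
            phase, amp = phase_amplitude_series(tr, 500.0, 5.0, 29.8)
            mis0.append(modulation_index(phase[seg], amp[seg])[0])
        assert np.mean(mis) > 5 * np.mean(mis0)


class TestCalibrateCoupling:
    def test_monotone_targets_give_monotone_coupling(self):
        cfg = SyntheticConfig(rng_seed=4, pac_calibration_trials=48)
        m_low, _ = calibrate_coupling(0.028, cfg, "size_nc")
        m_high, _ = calibrate_coupling(0.032, cfg, "size_nc")
        assert m_high > m_low

    def test_unreachable_target_reports_range(self):
        cfg = SyntheticConfig(rng_seed=4, pac_calibration_trials=32)
        with pytest.raises(SimulationError, match="achievable"):
            calibrate_coupling(0.25, cfg, "size_nc")


class TestCohort:
    def test_shapes_labels_and_balance(self, tiny_synth, montage):
        datasets, behavior, meta = generate_cohort(
            tiny_synth, montage, calibrate=False,
            effect_scales={k: (1.0, 1.0) for k in CONDITION_KEYS})
        assert len(datasets) == 2
        ds = datasets[0]
        assert ds.data.shape == (32, 38, 1000)
        for task in ("naming", "size"):
            for cog in ("noncognate", "cognate"):
                assert ((ds.task == task) & (ds.cognate == cog)).sum() == 8
        assert len(behavior) == 2 * 32

    def test_same_seed_bit_identical(self, tiny_synth, montage):
        kwargs = dict(calibrate=False,
                      effect_scales={k: (1.0, 1.0) for k in CONDITION_KEYS})
        a, beh_a, _ = generate_cohort(tiny_synth, montage, **kwargs)
        b, beh_b, _ = generate_cohort(tiny_synth, montage, **kwargs)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        assert (beh_a["rt_ms"] == beh_b["rt_ms"]).all()

    def test_subject_effects_reproducible(self, tiny_synth):
        a = draw_subject_effects(tiny_synth, 1)
        b = draw_subject_effects(tiny_synth, 1)
        assert a.beta_rel == b.beta_rel
        assert a.rt_mean_ms == b.rt_mean_ms

    def test_baseline_band_power_condition_independent(self, montage):
        """Expected pre-stimulus band power carries no condition effect."""
        cfg = SyntheticConfig(trial_power_jitter_sd=0.0, rng_seed=8)
        sos = sps.butter(4, (25, 35), btype="bandpass", fs=500.0, output="sos")
        base = cfg.times < -0.2
        powers = []
        for key, r in (("naming_nc", -0.13), ("naming_c", -0.21)):
            rng = np.random.default_rng(77)
            trials = synthesize_condition_trials(
                cfg, rng, 30, 1, "naming", key, beta_rel=r, theta_rel=0.47,
                coupling_m=0.5, beta_carrier=29.8)
            f = sps.sosfiltfilt(sos, trials[:, 0], axis=-1)
            powers.append((f[:, base] ** 2).mean())
        assert abs(powers[0] / powers[1] - 1) < 0.02


class TestBehaviorGenerator:
    def test_accuracy_calibration_over_seed_panel(self):
        """Generated accuracies track the configured condition means: the
        cross-condition grand mean stays within +-0.03 in nearly every seed,
        and most individual condition cells do as well (single cells carry
        irreducible Bernoulli noise of ~0.017 SD)."""
        grand_hits, cell_hits, cells = 0, 0, 0
        seeds = range(100, 130)
        for seed in seeds:
            cfg = SyntheticConfig(rng_seed=seed)
            table = generate_behavior_table(cfg)
            devs = []
            for (task, cog), grp in table.groupby(["task", "cognate"]):
                key = f"{task}_{'nc' if cog == 'noncognate' else 'c'}"
                dev = grp["correct"].mean() - cfg.accuracy_mean[key]
                devs.append(dev)
                cells += 1
                cell_hits += abs(dev) <= 0.03
            grand_hits += abs(np.mean(devs)) <= 0.03
        assert grand_hits >= 28
        assert cell_hits / cells >= 0.85

    def test_rt_truncation_floor(self):
        cfg = SyntheticConfig(rng_seed=2)
        table = generate_behavior_table(cfg)
        assert (table["rt_ms"] >= cfg.rt_floor_ms).all()

    def test_cognate_advantage_in_naming_rts(self):
        cfg = SyntheticConfig(rng_seed=3)
        table = generate_behavior_table(cfg)
        naming = table[(table.task == "naming") & table.correct]
        nc = naming[naming.cognate == "noncognate"]["rt_ms"].mean()
        c = naming[naming.cognate == "cognate"]["rt_ms"].mean()
        assert nc > c
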