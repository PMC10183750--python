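"""Synthetic EEG cohorts and behavioral tables with the statistical structure
the analysis pipeline assumes.

Every channel carries: a 1/f (aperiodic) background, white sensor noise, an
ongoing theta component (narrowband noise around 5 Hz) and an ongoing beta
tone (~29.5-29.8 Hz) whose instantaneous amplitude is coupled to the local
theta phase.  Condition effects are multiplicative amplitude steps on the
ROI channels inside task-specific post-stimulus windows: beta power
decreases (desynchronization) and theta power increases, with the injected
relative power change calibrated analytically so that the *pipeline-measured*
window-mean change equals the configured value despite the temporal smoothing
of the 5-cycle wavelet (sigma_t = 5 / (2 pi f), i.e. ~159 ms at 5 Hz —
comparable to the 100 ms analysis windows, so uncorrected boxcar injection
would under-recover by design, not by accident).

Oscillation amplitudes are set from the configured in-band
oscillation-to-background power ratio, so that after 1/f subtraction the
residual aperiodic power dilutes relative changes by under ~2%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.stats import truncnorm

from .config import CONDITION_KEYS, SyntheticConfig
from .containers import CONDITIONS, EpochedDataset
from .montage import Montage, load_montage

__all__ = [
    "SubjectEffects", "generate_background_1f", "inject_oscillation_effect",
    "inject_pac", "calibrate_coupling", "generate_cohort",
]

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    pass


# --------------------------------------------------------------------------
# building blocks
# --------------------------------------------------------------------------

def _background_psd(freqs: np.ndarray, exponent: float, amplitude: float,
                    sensor_noise_sd: float, sfreq: float) -> np.ndarray:
    """One-sided PSD (uV^2/Hz) of background + white noise; flat below 1 Hz."""
    f = np.maximum(freqs, 1.0)
    psd = amplitude ** 2 / f ** exponent
    psd = psd + 2.0 * sensor_noise_sd ** 2 / sfreq
    return psd


def _shaped_noise(rng, n_signals: int, n_samples: int, sfreq: float,
                  spectrum_fn, analytic: bool = False) -> np.ndarray:
    """Gaussian noise with one-sided PSD ``spectrum_fn(f)``; optionally the
    analytic (complex) signal, for phase extraction."""
    if n_samples < 2:
        raise SimulationError("need at least 2 samples")
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.sqrt(spectrum_fn(freqs) * sfreq * n_samples / 2.0)
    scale[0] = 0.0
    z = rng.standard_normal((n_signals, freqs.size)) + \
        1j * rng.standard_normal((n_signals, freqs.size))
    spec = z / np.sqrt(2.0) * scale
    if analytic:
        full = np.zeros((n_signals, n_samples), dtype=complex)
        full[:, :freqs.size] = 2.0 * spec
        if n_samples % 2 == 0:
            full[:, n_samples // 2] *= 0.5
        return np.fft.ifft(full, axis=1)
    return np.fft.irfft(spec, n=n_samples, axis=1)


def generate_background_1f(n_samples: int, sfreq: float, exponent: float,
                           amplitude: float, rng) -> np.ndarray:
    """Single-channel aperiodic background with spectrum ~ 1/f**exponent."""
    if exponent < 0:
        raise SimulationError("exponent must be >= 0")
    if n_samples < 2:
        raise SimulationError("need at least 2 samples")

    def psd(f):
        return amplitude ** 2 / np.maximum(f, 1.0) ** exponent

    return _shaped_noise(rng, 1, n_samples, sfreq, psd)[0]


def _wavelet_sigma_t(freq: float, n_cycles: float = 5.0) -> float:
    return n_cycles / (2.0 * np.pi * freq)


def _theta_psd_fn(cfg: SyntheticConfig, total_power: float):
    sd = cfg.theta_spectral_sd

    def psd(f):
        return total_power / np.sqrt(2 * np.pi * sd ** 2) * \
            np.exp(-(f - cfg.theta_freq) ** 2 / (2 * sd ** 2))

    return psd


def _component_amplitudes(cfg: SyntheticConfig, beta_carrier: float):
    """Theta total power and beta tone amplitude realizing the configured
    in-band oscillation-to-background ratios at the carrier's wavelet bin."""
    def bg(f):
        return _background_psd(np.atleast_1d(float(f)), cfg.aperiodic_exponent,
                               cfg.aperiodic_amplitude, cfg.sensor_noise_sd,
                               cfg.sfreq)[0]

    # The 5-cycle wavelet's power transfer |H(f)|^2 around analysis bin f0 is
    # exp(-(f - f0)^2 / sigma_f^2) with sigma_f = f0 / 5; its equivalent noise
    # bandwidth is sigma_f * sqrt(pi).
    # Theta (narrowband Gaussian noise, spectral SD s_o, total power P):
    #   bin power = P * sigma_f / sqrt(sigma_f^2 + 2 s_o^2)
    # so  P = S * PSD_bg(f0) * sqrt(pi) * sqrt(sigma_f^2 + 2 s_o^2).
    f_t = cfg.theta_freq
    sigma_f_t = f_t / 5.0
    s_o = cfg.theta_spectral_sd
    theta_power = cfg.osc_background_ratio["theta"] * bg(f_t) * \
        np.sqrt(np.pi) * np.sqrt(sigma_f_t ** 2 + 2 * s_o ** 2)
    # Beta (deterministic tone, amplitude A): bin power = A^2 / 2, so
    #   A = sqrt(2 * S * PSD_bg(f0) * sigma_f * sqrt(pi)).
    f_b = beta_carrier
    sigma_f_b = f_b / 5.0
    beta_amp = np.sqrt(2.0 * cfg.osc_background_ratio["beta"] * bg(f_b) *
                       sigma_f_b * np.sqrt(np.pi))
    return theta_power, beta_amp


def band_dilution(cfg: SyntheticConfig, band: str, beta_carrier: float,
                  coupling_m: float = 0.0) -> float:
    """Expected attenuation of the band-mean normalized power change caused
    by residual aperiodic background under the oscillation.

    After 1/f subtraction the corrected power at bin f is the ratio
    (P_bg + P_osc) / P_bg = 1 + S_f, so a true relative oscillation-power
    change r is measured as r * S_f / (1 + S_f) at that bin; the band
    average dilutes accordingly.  All quantities follow from the generator's
    own parameters, so the injected step can compensate exactly.
    """
    lo, hi = cfg.measure_bands[band]
    bins = np.arange(np.ceil(lo), np.floor(hi) + 1)
    sigma_f = bins / 5.0
    psd_bg = _background_psd(bins, cfg.aperiodic_exponent,
                             cfg.aperiodic_amplitude, cfg.sensor_noise_sd,
                             cfg.sfreq)
    if band == "beta":
        a2_half = cfg.osc_background_ratio["beta"] * \
            _background_psd(np.atleast_1d(beta_carrier), cfg.aperiodic_exponent,
                            cfg.aperiodic_amplitude, cfg.sensor_noise_sd,
                            cfg.sfreq)[0] * (beta_carrier / 5.0) * np.sqrt(np.pi)
        # power-normalized theta-phase modulation redistributes carrier power
        # into sidebands at +- theta_freq without changing the total
        m = coupling_m
        norm = 1.0 + m ** 2 / 2.0
        resp = (np.exp(-(bins - beta_carrier) ** 2 / sigma_f ** 2) +
                (m ** 2 / 4.0) *
                (np.exp(-(bins - beta_carrier + cfg.theta_freq) ** 2 / sigma_f ** 2) +
                 np.exp(-(bins - beta_carrier - cfg.theta_freq) ** 2 / sigma_f ** 2)))
        p_osc = a2_half * resp / norm
    else:
        p_tot = _component_amplitudes(cfg, beta_carrier)[0]
        s_o = cfg.theta_spectral_sd
        var = sigma_f ** 2 + 2 * s_o ** 2
        p_osc = p_tot * sigma_f / np.sqrt(var) * \
            np.exp(-(bins - cfg.theta_freq) ** 2 / var)
    s_f = p_osc / (psd_bg * sigma_f * np.sqrt(np.pi))
    return float(np.mean(s_f / (1.0 + s_f)))


def _smoothed_boxcar(times: np.ndarray, support: tuple[float, float],
                     sigma_s: float, sfreq: float) -> np.ndarray:
    box = ((times >= support[0]) & (times <= support[1])).astype(float)
    return gaussian_filter1d(box, sigma=sigma_s * sfreq, mode="constant")


def solve_effect_step(rel_change: float, times: np.ndarray, sfreq: float,
                      window: tuple[float, float], band_center: float,
                      baseline: tuple[float, float] = (-0.700, -0.200),
                      onset_floor: float = 0.0,
                      n_cycles: float = 5.0,
                      carrier: str = "coherent") -> tuple[float, np.ndarray]:
    """Amplitude step ``h`` such that the wavelet-smoothed window-mean power
    change relative to baseline equals ``rel_change``.

    Returns (h, boxcar support indicator on the time grid).  The effect
    support is the analysis window padded by 2 sigma_t on each side (clipped
    to post-stimulus onset), so the smoothed response plateaus inside the
    window as far as the onset allows; the residual shortfall and baseline
    leakage are absorbed into ``h`` exactly.

    For a deterministic (``coherent``) carrier the wavelet smooths the
    amplitude envelope (Gaussian kernel, SD sigma_t); for a random-phase
    narrowband (``incoherent``) carrier it smooths *power* with the wavelet's
    squared envelope (SD sigma_t / sqrt(2)).
    """
    sigma_t = _wavelet_sigma_t(band_center, n_cycles)
    support = (max(window[0] - 2 * sigma_t, onset_floor),
               min(window[1] + 2 * sigma_t, times[-1] - 0.1))
    wmask = (times >= window[0]) & (times <= window[1])
    bmask = (times >= baseline[0]) & (times <= baseline[1])
    r = rel_change
    if carrier == "coherent":
        g = _smoothed_boxcar(times, support, sigma_t, sfreq)
        mw1, mw2 = g[wmask].mean(), (g[wmask] ** 2).mean()
        mb1, mb2 = g[bmask].mean(), (g[bmask] ** 2).mean()
        # mean_w (1 + h g)^2 = (1 + r) * mean_b (1 + h g)^2
        a = mw2 - (1 + r) * mb2
        b = 2 * (mw1 - (1 + r) * mb1)
        c = -r
        if abs(a) < 1e-12:
            h = -c / b
        else:
            disc = b * b - 4 * a * c
            if disc < 0:
                raise SimulationError(f"unreachable relative change {r}")
            roots = [(-b + np.sqrt(disc)) / (2 * a),
                     (-b - np.sqrt(disc)) / (2 * a)]
            roots = [x for x in roots if x * r >= 0 or r == 0]
            if not roots:
                raise SimulationError(f"unreachable relative change {r}")
            h = min(roots, key=abs)
    elif carrier == "incoherent":
        g = _smoothed_boxcar(times, support, sigma_t / np.sqrt(2.0), sfreq)
        mw1, mb1 = g[wmask].mean(), g[bmask].mean()
        # power step q = 2h + h^2: (1 + q mw1) = (1 + r)(1 + q mb1)
        denom = mw1 - (1 + r) * mb1
        if denom <= 0:
            raise SimulationError(f"unreachable relative change {r}")
        q = r / denom
        if q <= -1:
            raise SimulationError(f"unreachable relative change {r}")
        h = np.sqrt(1.0 + q) - 1.0
    else:
        raise SimulationError(f"unknown carrier kind {carrier!r}")
    box = ((times >= support[0]) & (times <= support[1])).astype(float)
    return float(h), box


def inject_oscillation_effect(
    epoch: np.ndarray, sfreq: float, times: np.ndarray,
    band: tuple[float, float], window: tuple[float, float],
    rel_change: float, baseline_amp: float, rng,
    roi_mask: np.ndarray | None = None,
    montage: Montage | None = None,
    neighbor_falloff: float = 0.5,
) -> np.ndarray:
    """Add a band-limited oscillation with a boxcar power step in ``window``.

    The oscillation amplitude is ``baseline_amp`` outside the window and
    ``baseline_amp * sqrt(1 + rel_change)`` inside it, so the baseline-relative
    power change equals ``rel_change`` in expectation.  With ``roi_mask`` set,
    it is applied at full amplitude to ROI channels and at
    ``neighbor_falloff`` amplitude to their immediate neighbors.
    """
    lo, hi = band
    if not (0 < lo < hi < sfreq / 2):
        raise SimulationError(f"band {band} outside (0, Nyquist)")
    if rel_change <= -1:
        raise SimulationError("rel_change must be > -1")
    if not (times[0] <= window[0] < window[1] <= times[-1]):
        raise SimulationError("effect window outside the epoch")
    epoch = np.asarray(epoch, dtype=float)
    n_ch, n_samp = epoch.shape
    f0 = 0.5 * (lo + hi)
    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    carrier = np.cos(2 * np.pi * f0 * times[None, :] + phases[:, None])
    env = np.where((times >= window[0]) & (times <= window[1]),
                   np.sqrt(1.0 + rel_change), 1.0)
    if roi_mask is None:
        weights = np.ones(n_ch)
    else:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        weights = roi_mask.astype(float)
        if montage is not None:
            nbr = montage.neighbors[:, roi_mask].any(axis=1) & ~roi_mask
            weights[nbr] = neighbor_falloff
    return epoch + baseline_amp * weights[:, None] * env[None, :] * carrier


def pac_modulation(theta_phase: np.ndarray, coupling_m: float,
                   normalization: str = "peak") -> np.ndarray:
    """Theta-phase amplitude-modulation profile (1 + m cos(phase)).

    ``peak`` normalization divides by (1 + m) (unit peak); ``power``
    normalization divides by sqrt(1 + m^2/2) so the mean-square amplitude —
    hence the band power — is independent of the coupling strength.  The
    cohort generator uses ``power`` so that coupling and band-power effects
    stay orthogonal.
    """
    prof = 1.0 + coupling_m * np.cos(theta_phase)
    if normalization == "peak":
        return prof / (1.0 + coupling_m)
    if normalization == "power":
        return prof / np.sqrt(1.0 + coupling_m ** 2 / 2.0)
    raise SimulationError(f"unknown normalization {normalization!r}")


def inject_pac(
    epoch: np.ndarray, sfreq: float, times: np.ndarray,
    theta_freq: float, beta_freq: float, coupling_m: float, rng,
    theta_amp: float = 5.0, beta_amp: float = 3.0,
) -> np.ndarray:
    """Add a theta tone and a beta carrier whose instantaneous amplitude
    follows ``beta_amp * (1 + m cos(phi_theta)) / (1 + m)``."""
    if not (0 <= coupling_m <= 1):
        raise SimulationError("coupling_m must be in [0, 1]")
    if theta_freq >= beta_freq:
        raise SimulationError("theta_freq must be below beta_freq")
    epoch = np.asarray(epoch, dtype=float)
    n_ch = epoch.shape[0]
    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    theta_phase = 2 * np.pi * theta_freq * times[None, :] + phases[:, None]
    theta = theta_amp * np.cos(theta_phase)
    beta_phase0 = rng.uniform(0, 2 * np.pi, size=n_ch)
    beta = beta_amp * pac_modulation(theta_phase, coupling_m) * \
        np.cos(2 * np.pi * beta_freq * times[None, :] + beta_phase0[:, None])
    return epoch + theta + beta


# --------------------------------------------------------------------------
# subject-level realization
# --------------------------------------------------------------------------

@dataclass
class SubjectEffects:
    """Realized per-subject condition parameters, reproducible from
    (rng_seed, subject index)."""

    beta_rel: dict
    theta_rel: dict
    accuracy: dict
    rt_mean_ms: dict
    beta_carrier: dict        # per task, Hz
    coupling_scale: float     # multiplies the calibrated coupling


def draw_subject_effects(cfg: SyntheticConfig, subject: int) -> SubjectEffects:
    rng = np.random.default_rng([cfg.rng_seed, 77, subject])
    sc = cfg.between_subject_scale
    rho = cfg.effect_correlation
    beta_rel, theta_rel, accuracy, rt_mean = {}, {}, {}, {}
    u_rt = rng.normal(0.0, cfg.rt_subject_sd_ms)
    u_acc = rng.normal(0.0, cfg.accuracy_subject_sd)
    # subjects differ mostly in overall oscillatory reactivity: condition
    # effects share a per-band subject component (correlation rho), which
    # keeps within-subject condition differences tighter than the marginal
    # between-subject SDs
    z_beta_shared = rng.normal()
    z_theta_shared = rng.normal()
    for key in CONDITION_KEYS:
        zb = np.sqrt(rho) * z_beta_shared + np.sqrt(1 - rho) * rng.normal()
        zt = np.sqrt(rho) * z_theta_shared + np.sqrt(1 - rho) * rng.normal()
        beta_rel[key] = max(
            cfg.beta_rel_change[key] + sc * cfg.beta_rel_sd[key] * zb, -0.95)
        theta_rel[key] = max(
            cfg.theta_rel_change[key] + sc * cfg.theta_rel_sd[key] * zt, -0.95)
        accuracy[key] = float(np.clip(cfg.accuracy_mean[key] + u_acc, 0.30, 1.0))
        rt_mean[key] = cfg.rt_mean_ms[key] + u_rt + \
            rng.normal(0.0, cfg.rt_condition_sd_ms)
    carrier = {
        task: float(np.clip(rng.normal(cfg.beta_freq[task],
                                       cfg.beta_freq_subject_sd), 28.5, 29.9))
        for task in ("naming", "size")
    }
    return SubjectEffects(
        beta_rel=beta_rel, theta_rel=theta_rel, accuracy=accuracy,
        rt_mean_ms=rt_mean, beta_carrier=carrier,
        coupling_scale=float(np.clip(rng.normal(1.0, 0.03), 0.85, 1.15)))


def _condition_key(task: str, cognate: str) -> str:
    return f"{task}_{'nc' if cognate == 'noncognate' else 'c'}"


def synthesize_condition_trials(
    cfg: SyntheticConfig, rng, n_trials: int, n_channels: int,
    task: str, cond_key: str,
    beta_rel: float, theta_rel: float, coupling_m: float,
    beta_carrier: float, effect_weights: np.ndarray | None = None,
    effect_scales: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Trials x channels x samples for one condition cell.

    ``effect_weights`` scales the amplitude *step* per channel (1 on ROI,
    falloff on neighbors, 0 elsewhere); the ongoing oscillations themselves
    are present on every channel.
    """
    times = cfg.times
    n = cfg.n_samples
    n_sig = n_trials * n_channels
    if effect_weights is None:
        effect_weights = np.ones(n_channels)
    window = cfg.effect_windows[task]

    theta_power, beta_amp = _component_amplitudes(cfg, beta_carrier)
    # compensate the residual-background dilution of the band average and the
    # wavelet's temporal smoothing of the amplitude step; ``effect_scales``
    # carries the empirical fixed-point correction from calibrate_band_effects
    th_scale, b_scale = effect_scales
    h_theta, box_theta = solve_effect_step(
        theta_rel * th_scale / band_dilution(cfg, "theta", beta_carrier),
        times, cfg.sfreq, window, cfg.theta_freq, carrier="incoherent")
    h_beta, box_beta = solve_effect_step(
        beta_rel * b_scale / band_dilution(cfg, "beta", beta_carrier,
                                           coupling_m=coupling_m),
        times, cfg.sfreq, window, beta_carrier, carrier="coherent")

    def bg_psd(f):
        return _background_psd(f, cfg.aperiodic_exponent,
                               cfg.aperiodic_amplitude, 0.0, cfg.sfreq)

    bg = _shaped_noise(rng, n_sig, n, cfg.sfreq, bg_psd)
    white = rng.normal(0.0, cfg.sensor_noise_sd, size=(n_sig, n))

    z_theta = _shaped_noise(rng, n_sig, n, cfg.sfreq,
                            _theta_psd_fn(cfg, theta_power), analytic=True)
    # Constant-envelope theta: keep the narrowband phase dynamics but fix the
    # envelope at the RMS level.  Trial-to-trial power variability is carried
    # by the explicit unit-mean jitter below (which, being constant within a
    # trial, cancels in baseline-relative power measures), not by Rayleigh
    # envelope statistics that would make single-trial window power an
    # exponential draw.
    env = np.abs(z_theta)
    z_theta = z_theta / np.maximum(env, 1e-12) * np.sqrt(2.0 * theta_power)
    # Beta amplitude couples to the narrowband core of the theta rhythm (the
    # component the phase-extraction filter isolates), not to the broadband
    # theta envelope noise.
    freqs_fft = np.fft.fftfreq(n, d=1.0 / cfg.sfreq)
    core_gain = np.exp(-(freqs_fft - cfg.theta_freq) ** 2 / (2 * 0.5 ** 2))
    core_gain[freqs_fft < 0] = 0.0
    z_core = np.fft.ifft(np.fft.fft(z_theta, axis=1) * core_gain[None, :],
                         axis=1)
    theta_phase = np.angle(z_core)
    w = np.tile(effect_weights, n_trials)[:, None]
    theta_env = 1.0 + (h_theta * box_theta)[None, :] * w
    # unit-mean-square power jitter, log-normal, per trial-channel
    jit_sd = cfg.trial_power_jitter_sd
    if jit_sd > 0:
        sig2 = np.log(1.0 + jit_sd ** 2)
        jt = np.exp(rng.normal(-sig2 / 2, np.sqrt(sig2), size=(n_sig, 1)) / 2)
        jb = np.exp(rng.normal(-sig2 / 2, np.sqrt(sig2), size=(n_sig, 1)) / 2)
    else:
        jt = jb = 1.0
    theta = z_theta.real * theta_env * jt

    beta_env = 1.0 + (h_beta * box_beta)[None, :] * w
    phi0 = rng.uniform(0, 2 * np.pi, size=(n_sig, 1))
    beta = beta_amp * beta_env * jb * \
        pac_modulation(theta_phase, coupling_m, normalization="power") * \
        np.cos(2 * np.pi * beta_carrier * times[None, :] + phi0)

    out = bg + white + theta + beta
    return out.reshape(n_trials, n_channels, n)


def _measure_band_changes(cfg: SyntheticConfig, cond_key: str, task: str,
                          coupling_m: float, scales: tuple[float, float],
                          seed, montage: Montage, n_trials: int = 64,
                          zero_effect: bool = False):
    """Cohort-scale measurement of the recovered (theta, beta) relative
    changes for one condition, through the actual analysis chain (full
    montage with ROI-weighted effects, average reference, zero-padding,
    Morlet + 1/f + baseline normalization, ROI/window band means).

    With ``zero_effect`` the same random draws are used but no effect step is
    injected; the pair acts as a control variate that cancels the shared
    sampling noise."""
    from .containers import EpochedDataset
    from .preprocess import rereference_average, zero_pad_epochs
    from .spectral import (band_power, baseline_normalize, fit_fractal,
                           morlet_tfr, subtract_fractal)

    rng = np.random.default_rng(seed)
    n_ch = len(montage.names)
    roi = [c for c in cfg.effect_rois[task] if c in montage.names]
    roi_idx = montage.index(roi)
    roi_mask = np.zeros(n_ch, dtype=bool)
    roi_mask[roi_idx] = True
    weights = roi_mask.astype(float)
    nbr = montage.neighbors[:, roi_mask].any(axis=1) & ~roi_mask
    weights[nbr] = 0.5
    data = synthesize_condition_trials(
        cfg, rng, n_trials, n_ch, task, cond_key,
        beta_rel=0.0 if zero_effect else cfg.beta_rel_change[cond_key],
        theta_rel=0.0 if zero_effect else cfg.theta_rel_change[cond_key],
        coupling_m=coupling_m, beta_carrier=cfg.beta_freq[task],
        effect_weights=weights, effect_scales=scales)
    n = n_trials
    ds = EpochedDataset(
        data=data, sfreq=cfg.sfreq, times=cfg.times,
        channels=list(montage.names), task=np.array([task] * n),
        cognate=np.array(["cognate"] * n), correct=np.ones(n, dtype=bool))
    ds = rereference_average(ds)
    ds = zero_pad_epochs(ds, pad_to=5.0)
    window = cfg.effect_windows[task]
    step = 0.02
    baseline = (-0.7, -0.2)
    pts = []
    for lo, hi in (baseline, window):
        k0, k1 = int(np.ceil(lo / step)), int(np.floor(hi / step + 1e-9))
        pts.extend(np.arange(k0, k1 + 1) * step)
    tfr = morlet_tfr(ds, out_times=np.unique(np.round(pts, 6)), picks=roi)
    fit = fit_fractal(tfr, share_trials=True, share_exclusion=True,
                      share_times=True)
    corr = subtract_fractal(tfr, fit)
    corr.power = np.nanmean(corr.power, axis=0, keepdims=True)
    norm = baseline_normalize(corr, baseline=baseline)
    beta = band_power(norm, cfg.measure_bands["beta"], window, channels=roi)[0]
    theta = band_power(norm, cfg.measure_bands["theta"], window, channels=roi)[0]
    return float(theta), float(beta)


def calibrate_band_effects(cfg: SyntheticConfig, coupling: dict,
                           montage: Montage, n_iter: int = 2) -> dict:
    """Fixed-point calibration of the injected effect steps per condition.

    The analytic compensations (wavelet smoothing, background dilution) leave
    residual coupling between the bands through the per-time aperiodic fit;
    this measures each condition's recovered (theta, beta) changes through
    the actual spectral chain with common random numbers and rescales the
    injected steps multiplicatively until the recovered values match the
    configured means.  Returns {condition: (theta_scale, beta_scale)}.
    """
    n_probe = 96
    # Measurement-chain offset under zero injected effects (e.g. slight
    # baseline attenuation where the long theta wavelet overlaps the padding
    # edge).  It is a property of the task's window geometry, shared by both
    # conditions of a task, and part of what the pipeline measures, so the
    # calibration targets offset + effect response = configured value.
    nulls_by_task = {}
    for ti, task in enumerate(("naming", "size")):
        key_nc = f"{task}_nc"
        seed_base = [cfg.rng_seed, 307, ti]
        draws = [_measure_band_changes(
            cfg, key_nc, task, coupling[key_nc], (1.0, 1.0), seed_base + [d],
            montage, n_trials=n_probe, zero_effect=True) for d in range(6)]
        nulls_by_task[task] = {
            "draws": draws, "seed_base": seed_base,
            "theta": float(np.mean([d[0] for d in draws])),
            "beta": float(np.mean([d[1] for d in draws]))}
    scales = {}
    for key in CONDITION_KEYS:
        task = key.rsplit("_", 1)[0]
        tgt_t = cfg.theta_rel_change[key]
        tgt_b = cfg.beta_rel_change[key]
        nulls = nulls_by_task[task]
        s_t, s_b = 1.0, 1.0
        seed = nulls["seed_base"] + [0]
        # the paired twin (first null draw) shares every random draw with the
        # probe, so the multiplicative response (1 + measured) / (1 + twin)
        # is nearly noise-free; match it to the response implied by the
        # target and the mean offset
        want_t = (1.0 + tgt_t) / (1.0 + nulls["theta"]) - 1.0
        want_b = (1.0 + tgt_b) / (1.0 + nulls["beta"]) - 1.0
        for _ in range(n_iter):
            got_t, got_b = _measure_band_changes(
                cfg, key, task, coupling[key], (s_t, s_b), seed, montage,
                n_trials=n_probe)
            resp_t = (1.0 + got_t) / (1.0 + nulls["draws"][0][0]) - 1.0
            resp_b = (1.0 + got_b) / (1.0 + nulls["draws"][0][1]) - 1.0
            if want_t != 0 and resp_t * want_t > 0:
                s_t *= float(np.clip(want_t / resp_t, 0.5, 2.0))
            if want_b != 0 and resp_b * want_b > 0:
                s_b *= float(np.clip(want_b / resp_b, 0.5, 2.0))
        scales[key] = (s_t, s_b)
        logger.info("band-effect calibration %s: theta x%.3f beta x%.3f",
                    key, s_t, s_b)
    return scales


# --------------------------------------------------------------------------
# coupling calibration
# --------------------------------------------------------------------------

def _mi_estimate(cfg: SyntheticConfig, cond_key: str, task: str,
                 coupling_m: float, n_trials: int, seed,
                 theta_filter_sd: float = 0.5, beta_filter_sd: float = 5.0,
                 n_bins: int = 12, n_channels: int = 24,
                 n_electrodes: int = 8) -> float:
    """Mean single-trial MI of simulated trials, using the same estimator as
    the PAC pipeline (multi-channel with average reference, MI averaged over
    a subset of electrodes, matching the cohort measurement conditions)."""
    from .pac import extraction_segment, modulation_index, phase_amplitude_series

    rng = np.random.default_rng(seed)
    trials = synthesize_condition_trials(
        cfg, rng, n_trials, n_channels, task, cond_key,
        beta_rel=cfg.beta_rel_change[cond_key],
        theta_rel=cfg.theta_rel_change[cond_key],
        coupling_m=coupling_m,
        beta_carrier=cfg.beta_freq[task])
    trials = trials - trials.mean(axis=1, keepdims=True)  # average reference
    times = cfg.times
    window = cfg.effect_windows[task]
    seg = extraction_segment(window, cfg.theta_freq, times)
    mis = []
    for t_i in range(n_trials):
        for c_i in range(n_electrodes):
            phase, amp = phase_amplitude_series(
                trials[t_i, c_i], cfg.sfreq, cfg.theta_freq,
                cfg.beta_freq[task],
                theta_bw_sd=theta_filter_sd, beta_bw_sd=beta_filter_sd)
            mi, _ = modulation_index(phase[seg], amp[seg], n_bins=n_bins)
            mis.append(mi)
    return float(np.mean(mis))


def calibrate_coupling(
    target_mi: float, cfg: SyntheticConfig, cond_key: str,
    rng=None, rel_tol: float | None = None, n_trials: int | None = None,
    max_iter: int = 20,
) -> tuple[float, float]:
    """Bisection on the coupling parameter until the Monte-Carlo MI estimate
    matches ``target_mi``; returns (coupling_m, achieved MI).

    Common random numbers are used across evaluations, making the
    coupling -> MI map deterministic and monotone for the bisection.
    """
    rel_tol = cfg.pac_calibration_tol if rel_tol is None else rel_tol
    n_trials = cfg.pac_calibration_trials if n_trials is None else n_trials
    task = cond_key.rsplit("_", 1)[0]
    seed = [cfg.rng_seed, 101] if rng is None else rng.integers(2 ** 31)

    def f(m):
        return _mi_estimate(cfg, cond_key, task, m, n_trials, seed)

    floor = f(0.0)
    hi_mi = f(0.95)
    if target_mi < floor * 0.9:
        raise SimulationError(
            f"target MI {target_mi:.4f} below the noise floor {floor:.4f}; "
            f"achievable range ~[{floor:.4f}, {hi_mi:.4f}]")
    if target_mi > hi_mi:
        raise SimulationError(
            f"target MI {target_mi:.4f} above the achievable maximum "
            f"{hi_mi:.4f} under the configured noise")
    if target_mi <= floor:
        return 0.0, floor
    lo_m, hi_m = 0.0, 0.95
    m = 0.5 * (lo_m + hi_m)
    achieved = floor
    for _ in range(max_iter):
        m = 0.5 * (lo_m + hi_m)
        achieved = f(m)
        if abs(achieved - target_mi) <= rel_tol * target_mi:
            break
        if achieved < target_mi:
            lo_m = m
        else:
            hi_m = m
    return float(m), float(achieved)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _draw_condition_behavior(cfg: SyntheticConfig, eff: SubjectEffects,
                             key: str, n_trials: int, rng):
    """Per-trial correctness (Bernoulli) and RT (normal truncated at the
    floor) for one subject-condition cell."""
    correct = rng.random(n_trials) < eff.accuracy[key]
    a = (cfg.rt_floor_ms - eff.rt_mean_ms[key]) / cfg.rt_trial_sd_ms
    rt = truncnorm.rvs(a, np.inf, loc=eff.rt_mean_ms[key],
                       scale=cfg.rt_trial_sd_ms, size=n_trials,
                       random_state=rng)
    return correct, rt


def generate_behavior_table(cfg: SyntheticConfig) -> pd.DataFrame:
    """Behavioral table for the whole cohort without synthesizing EEG.

    Uses the same per-subject effect draws and RNG streams as
    :func:`generate_subject`, so the table matches a full cohort run.
    """
    rows = []
    for subject in range(cfg.n_subjects):
        eff = draw_subject_effects(cfg, subject)
        rng_beh = np.random.default_rng([cfg.rng_seed, 12, subject])
        for task, cog in CONDITIONS:
            key = _condition_key(task, cog)
            correct, rt = _draw_condition_behavior(
                cfg, eff, key, cfg.trials_per_condition, rng_beh)
            for j in range(cfg.trials_per_condition):
                rows.append({"subject": f"S{subject:02d}", "task": task,
                             "cognate": cog, "trial": j,
                             "correct": bool(correct[j]),
                             "rt_ms": float(rt[j])})
    return pd.DataFrame(rows)


def generate_subject(
    cfg: SyntheticConfig, subject: int, montage: Montage,
    coupling: dict, effect_scales: dict | None = None,
) -> tuple[EpochedDataset, pd.DataFrame]:
    eff = draw_subject_effects(cfg, subject)
    rng = np.random.default_rng([cfg.rng_seed, 11, subject])
    rng_beh = np.random.default_rng([cfg.rng_seed, 12, subject])
    n_ch = len(montage.names)
    n_tpc = cfg.trials_per_condition

    blocks, tasks, cogs, corrects, rts = [], [], [], [], []
    rows = []
    for task, cog in CONDITIONS:
        key = _condition_key(task, cog)
        roi_idx = montage.index(cfg.effect_rois[task])
        roi_mask = np.zeros(n_ch, dtype=bool)
        roi_mask[roi_idx] = True
        weights = roi_mask.astype(float)
        nbr = montage.neighbors[:, roi_mask].any(axis=1) & ~roi_mask
        weights[nbr] = 0.5
        data = synthesize_condition_trials(
            cfg, rng, n_tpc, n_ch, task, key,
            beta_rel=eff.beta_rel[key], theta_rel=eff.theta_rel[key],
            coupling_m=min(coupling[key] * eff.coupling_scale, 0.99),
            beta_carrier=eff.beta_carrier[task],
            effect_weights=weights,
            effect_scales=(effect_scales or {}).get(key, (1.0, 1.0)))
        blocks.append(data)
        correct, rt = _draw_condition_behavior(cfg, eff, key, n_tpc, rng_beh)
        tasks += [task] * n_tpc
        cogs += [cog] * n_tpc
        corrects.append(correct)
        rts.append(rt)
        for j in range(n_tpc):
            rows.append({"subject": f"S{subject:02d}", "task": task,
                         "cognate": cog, "trial": j,
                         "correct": bool(correct[j]),
                         "rt_ms": float(rt[j])})
    ds = EpochedDataset(
        data=np.concatenate(blocks, axis=0).astype(np.float32),
        sfreq=cfg.sfreq, times=cfg.times, channels=list(montage.names),
        task=np.array(tasks), cognate=np.array(cogs),
        correct=np.concatenate(corrects), subject_id=f"S{subject:02d}")
    return ds, pd.DataFrame(rows)


def generate_cohort(
    cfg: SyntheticConfig, montage: Montage | None = None,
    calibrate: bool = True,
    coupling: dict | None = None,
    effect_scales: dict | None = None,
):
    """Generate the full cohort.

    Returns (datasets, behavior table, meta) where ``meta`` records the
    calibrated coupling and effect scales per condition.  Precomputed
    ``coupling`` / ``effect_scales`` (e.g. from a previous cohort with the
    same configuration) can be passed to skip recalibration.
    """
    if montage is None:
        montage = load_montage("study38")
    achieved = {}
    if coupling is None:
        if calibrate:
            coupling = {}
            for key in CONDITION_KEYS:
                m, got = calibrate_coupling(cfg.pac_target_mi[key], cfg, key)
                coupling[key], achieved[key] = m, got
                logger.info("calibrated coupling %s: m=%.3f (MI %.4f -> %.4f)",
                            key, m, cfg.pac_target_mi[key], got)
        else:
            coupling = {key: 0.0 for key in CONDITION_KEYS}
            achieved = dict(coupling)
    if effect_scales is None:
        effect_scales = calibrate_band_effects(cfg, coupling, montage)
    datasets, tables = [], []
    for s in range(cfg.n_subjects):
        ds, table = generate_subject(cfg, s, montage, coupling, effect_scales)
        datasets.append(ds)
        tables.append(table)
    behavior = pd.concat(tables, ignore_index=True)
    meta = {"coupling": coupling, "calibrated_mi": achieved,
            "effect_scales": {k: list(v) for k, v in effect_scales.items()},
            "rng_seed": cfg.rng_seed}
    return datasets, behavior, meta
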