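"""Theta-phase / beta-amplitude coupling via the modulation index.

Per subject and task: (1) the most prominent theta (3-7 Hz) and beta
(13-30 Hz) peaks are located in the ROI-mean corrected power spectrum;
(2) trial counts are balanced across the four conditions by repeatedly
drawing 80% of the smallest correct-trial count; (3) each trial-electrode
series is duplicated and filtered with frequency-domain Gaussian kernels
centered on the peaks (spectral SD 0.5 Hz for theta, 5 Hz for beta), the
analytic signal giving theta phase and beta amplitude; (4) beta amplitude
is binned into 12 equidistant 30-degree theta-phase bins and the modulation
index is the normalized Kullback-Leibler distance of the bin profile from
uniform: MI = (log N - H(p)) / log N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import AnalysisConfig
from .containers import CONDITIONS, EpochedDataset, TFR

__all__ = [
    "BandPeak", "PACResult", "find_band_peak", "subsample_trials",
    "phase_amplitude_series", "modulation_index", "pac_condition_mean",
    "extraction_segment",
]


class PACError(ValueError):
    pass


@dataclass
class BandPeak:
    frequency: float
    prominence: float
    band: tuple[float, float]
    at_edge: bool = False


@dataclass
class PACResult:
    theta_peak: dict            # task -> BandPeak
    beta_peak: dict             # task -> BandPeak
    mi_per_condition: dict      # condition key -> mean MI
    bin_profile: dict           # condition key -> mean amplitude per phase bin
    mi_per_trial: dict = field(default_factory=dict)
    n_trials_used: int = 0
    n_iterations: int = 0
    seed: int | None = None


def find_band_peak(freqs: np.ndarray, spectrum: np.ndarray,
                   band: tuple[float, float]) -> BandPeak:
    """Most prominent local maximum of ``spectrum`` inside ``band``.

    Prominence is measured as height above the higher of the two flanking
    minima.  Without an interior local maximum, the band's maximum point is
    returned with a warning.
    """
    freqs = np.asarray(freqs, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    sel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    if sel.sum() == 0:
        raise PACError(f"band {band} not covered by the spectrum")
    if sel.sum() < 3:
        raise PACError(f"band {band} has fewer than 3 spectral points")
    f, s = freqs[sel], spectrum[sel]
    best = None
    for i in range(1, len(s) - 1):
        if s[i] >= s[i - 1] and s[i] >= s[i + 1] and \
                (s[i] > s[i - 1] or s[i] > s[i + 1]):
            left_min = s[:i].min()
            right_min = s[i + 1:].min()
            prom = s[i] - max(left_min, right_min)
            if best is None or prom > best[1]:
                best = (f[i], prom)
    if best is not None:
        return BandPeak(frequency=float(best[0]), prominence=float(best[1]),
                        band=band)
    warnings.warn(f"no interior spectral peak in band {band}; "
                  "using the band maximum", RuntimeWarning)
    i = int(np.argmax(s))
    return BandPeak(frequency=float(f[i]), prominence=0.0, band=band,
                    at_edge=True)


def subsample_trials(counts_or_indices, fraction: float = 0.8,
                     n_iterations: int = 100, rng=None) -> list[dict]:
    """Balanced trial subsampling across the four conditions.

    ``counts_or_indices`` maps condition key -> available trial indices (or
    an integer count).  ``m = floor(fraction * min count)`` trials are drawn
    without replacement per condition, per iteration.
    """
    rng = np.random.default_rng(rng)
    indices = {}
    for key, val in counts_or_indices.items():
        idx = np.arange(val) if np.isscalar(val) else np.asarray(val)
        if len(idx) < 2:
            raise PACError(f"condition {key} has fewer than 2 correct trials")
        indices[key] = idx
    m = int(np.floor(fraction * min(len(v) for v in indices.values())))
    if m < 1:
        raise PACError("subsampled trial count is below 1")
    draws = []
    for _ in range(n_iterations):
        draws.append({key: rng.choice(idx, size=m, replace=False)
                      for key, idx in indices.items()})
    return draws


def _gaussian_analytic(signal: np.ndarray, sfreq: float, f0: float,
                       bw_sd: float) -> np.ndarray:
    """Analytic signal after a frequency-domain Gaussian band-pass centered
    at ``f0`` with spectral SD ``bw_sd`` (zero-phase by construction)."""
    n = signal.shape[-1]
    freqs = np.fft.fftfreq(n, d=1.0 / sfreq)
    gain = np.exp(-(freqs - f0) ** 2 / (2.0 * bw_sd ** 2))
    gain[freqs < 0] = 0.0  # one-sided: the IFFT is the analytic signal
    spec = np.fft.fft(signal, axis=-1)
    return np.fft.ifft(2.0 * spec * gain, axis=-1)


def phase_amplitude_series(
    signal: np.ndarray, sfreq: float,
    theta_peak: float, beta_peak: float,
    theta_bw_sd: float = 0.5, beta_bw_sd: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Theta phase and beta amplitude-envelope series of a 1-D signal."""
    nyq = sfreq / 2.0
    for f0, sd, name in ((theta_peak, theta_bw_sd, "theta"),
                         (beta_peak, beta_bw_sd, "beta")):
        if not (0 < f0 < nyq):
            raise PACError(f"{name} peak {f0} outside (0, Nyquist)")
        if f0 + 3 * sd >= nyq:
            raise PACError(f"{name} filter extends beyond the Nyquist margin")
    z_theta = _gaussian_analytic(signal, sfreq, theta_peak, theta_bw_sd)
    z_beta = _gaussian_analytic(signal, sfreq, beta_peak, beta_bw_sd)
    return np.angle(z_theta), np.abs(z_beta)


def modulation_index(phase: np.ndarray, amplitude: np.ndarray,
                     n_bins: int = 12) -> tuple[float, np.ndarray]:
    """Normalized KL distance of the phase-binned amplitude profile from
    uniform; 0 for a flat profile, 1 when all amplitude sits in one bin."""
    phase = np.asarray(phase, dtype=float).ravel()
    amplitude = np.asarray(amplitude, dtype=float).ravel()
    if phase.size != amplitude.size:
        raise PACError("phase and amplitude series differ in length")
    if phase.size < n_bins:
        raise PACError("series shorter than the number of phase bins")
    if np.all(amplitude == 0):
        raise PACError("all-zero amplitude series")
    # bins cover (-pi, pi]; bin 0 starts at -pi
    bins = np.floor((phase + np.pi) / (2 * np.pi / n_bins)).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    sums = np.bincount(bins, weights=amplitude, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    profile = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    p = profile / profile.sum()
    nz = p > 0
    entropy = -(p[nz] * np.log(p[nz])).sum()  # 0*log 0 = 0
    mi = (np.log(n_bins) - entropy) / np.log(n_bins)
    return float(max(mi, 0.0)), profile


def extraction_segment(window: tuple[float, float], theta_freq: float,
                       times: np.ndarray, min_cycles: float = 2.0) -> np.ndarray:
    """Boolean mask for the MI extraction segment: the analysis window,
    extended symmetrically to at least ``min_cycles`` theta cycles so the
    phase distribution covers the circle."""
    need = min_cycles / theta_freq
    width = window[1] - window[0]
    if width >= need:
        lo, hi = window
    else:
        c = 0.5 * (window[0] + window[1])
        lo, hi = c - need / 2, c + need / 2
        if lo < times[0]:
            lo, hi = times[0], times[0] + need
        if hi > times[-1]:
            lo, hi = times[-1] - need, times[-1]
    return (times >= lo - 1e-9) & (times < hi - 1e-9 + 1e-12)


def _roi_spectrum(dataset: EpochedDataset, config: AnalysisConfig,
                  task: str) -> tuple[np.ndarray, np.ndarray]:
    """ROI/window-mean corrected power spectrum for peak finding."""
    from .spectral import condition_average, fit_fractal, morlet_tfr, subtract_fractal

    roi = [c for c in config.roi_for_task(task) if c in dataset.channels]
    window = config.window_for_task(task)
    mask = ((dataset.task == task) & dataset.correct)
    sub = dataset.select_trials(mask)
    min_span = config.n_cycles / config.tfr_fmin
    if sub.times[-1] - sub.times[0] < min_span:
        from .preprocess import zero_pad_epochs

        sub = zero_pad_epochs(sub, pad_to=min_span / 2.0 + 0.1)
    tfr = morlet_tfr(sub, freqs=np.arange(config.tfr_fmin, config.tfr_fmax + 0.5,
                                          config.tfr_fstep),
                     n_cycles=config.n_cycles, t_step=config.tfr_tstep,
                     tmin=window[0], tmax=window[1], picks=roi)
    fit = fit_fractal(tfr, share_trials=True, share_exclusion=True,
                      share_times=True)
    corr = subtract_fractal(tfr, fit)
    spec = np.nanmean(corr.power, axis=(0, 1, 3))
    return tfr.freqs, spec


def pac_condition_mean(
    dataset: EpochedDataset,
    config: AnalysisConfig,
    rng=None,
    mi_window: str = "task",
) -> PACResult:
    """Subject-level PAC pipeline: peaks, balanced subsampling, per-trial
    per-ROI-electrode MI, averaged to one value per condition.

    ``mi_window='task'`` (primary) computes MI on the task's analysis window
    extended to two theta cycles; ``'epoch'`` uses the full epoch.
    """
    rng = np.random.default_rng(rng)
    theta_band = config.bands["theta"]
    beta_band = config.bands["beta_pac"]

    theta_peaks, beta_peaks = {}, {}
    for task in ("naming", "size"):
        freqs, spec = _roi_spectrum(dataset, config, task)
        theta_peaks[task] = find_band_peak(freqs, spec, theta_band)
        beta_peaks[task] = find_band_peak(freqs, spec, beta_band)

    # balanced trial counts across the four conditions
    cond_keys, cond_idx = [], {}
    for task, cog in CONDITIONS:
        key = f"{task}_{'nc' if cog == 'noncognate' else 'c'}"
        cond_keys.append(key)
        cond_idx[key] = np.flatnonzero(dataset.condition_mask(task, cog))
    draws = subsample_trials(cond_idx, fraction=config.subsample_fraction,
                             n_iterations=config.n_subsample_iterations,
                             rng=rng)
    m = len(next(iter(draws[0].values())))

    # per-trial, per-electrode MI (independent of the resampling iteration)
    valid = dataset.time_mask(-1.0, 1.0)
    times_valid = dataset.times[valid]
    mi_trial, bin_profile = {}, {}
    for key in cond_keys:
        task = key.rsplit("_", 1)[0]
        roi = [c for c in config.roi_for_task(task) if c in dataset.channels]
        ch_idx = [dataset.channels.index(c) for c in roi]
        window = config.window_for_task(task)
        if mi_window == "task":
            seg = extraction_segment(window, theta_peaks[task].frequency,
                                     times_valid)
        else:
            seg = np.ones(times_valid.size, dtype=bool)
        per_trial, profiles = {}, []
        for t_i in cond_idx[key]:
            mis = []
            for c_i in ch_idx:
                sig = dataset.data[t_i, c_i, valid]
                phase, amp = phase_amplitude_series(
                    sig, dataset.sfreq,
                    theta_peaks[task].frequency, beta_peaks[task].frequency,
                    theta_bw_sd=config.theta_filter_sd,
                    beta_bw_sd=config.beta_filter_sd)
                mi, prof = modulation_index(phase[seg], amp[seg],
                                            n_bins=config.n_phase_bins)
                mis.append(mi)
                profiles.append(prof / prof.mean())
            per_trial[t_i] = float(np.mean(mis))
        mi_trial[key] = per_trial
        bin_profile[key] = np.mean(profiles, axis=0)

    # average over resampling iterations (equal trial counts per condition)
    mi_cond = {}
    for key in cond_keys:
        vals = [np.mean([mi_trial[key][t] for t in draw[key]])
                for draw in draws]
        mi_cond[key] = float(np.mean(vals))

    return PACResult(
        theta_peak=theta_peaks, beta_peak=beta_peaks,
        mi_per_condition=mi_cond, bin_profile=bin_profile,
        mi_per_trial=mi_trial, n_trials_used=m,
        n_iterations=config.n_subsample_iterations)
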