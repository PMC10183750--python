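"""Morlet time-frequency decomposition, iterative 1/f (aperiodic) removal,
baseline normalization, and band-power extraction.

The aperiodic background of the EEG spectrum is approximately linear in
log-log coordinates.  For every electrode-time pair the log power spectrum
is regressed on log frequency by least squares; frequencies whose residual
exceeds ``k`` residual SDs (oscillatory peaks) are excluded and the line is
refit until the excluded set stabilizes.  The fitted line is subtracted from
log power, which, exponentiated, leaves the oscillatory power as a ratio to
the aperiodic background.  Baseline normalization then expresses power as a
relative change, (P(t) - mean(P_baseline)) / mean(P_baseline), computed on
linear power.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import CONDITIONS, EpochedDataset, TFR

__all__ = [
    "morlet_tfr", "FractalFit", "fit_fractal", "subtract_fractal",
    "condition_average", "baseline_normalize", "band_power",
]

logger = logging.getLogger(__name__)


class SpectralError(ValueError):
    pass


def morlet_wavelet(freq: float, sfreq: float, n_cycles: float = 5.0,
                   support_sigmas: float = 4.0) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized, truncated at ``support_sigmas``
    temporal SDs.  sigma_t = n_cycles / (2 pi f)."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(support_sigmas * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def _default_times(times: np.ndarray, t_step: float, tmin, tmax) -> np.ndarray:
    lo = times[0] if tmin is None else tmin
    hi = times[-1] if tmax is None else tmax
    k0 = int(np.ceil(lo / t_step - 1e-9))
    k1 = int(np.floor(hi / t_step + 1e-9))
    return np.arange(k0, k1 + 1) * t_step


def morlet_tfr(
    dataset: EpochedDataset,
    freqs=None,
    n_cycles: float = 5.0,
    t_step: float = 0.020,
    tmin: float | None = None,
    tmax: float | None = None,
    picks=None,
    out_times=None,
) -> TFR:
    """Per-trial Morlet wavelet power on a regular output-time grid.

    The transform is evaluated only at the requested output times (20 ms
    steps by default, or an explicit ``out_times`` vector, which may be
    sparse) by direct windowed products with the wavelet, which makes
    cohort-scale decompositions tractable; signal outside the epoch is
    treated as zero, matching explicit zero-padding.
    """
    if freqs is None:
        freqs = np.arange(1.0, 41.0)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= dataset.sfreq / 2):
        raise SpectralError("frequencies must be below Nyquist")
    if np.any(freqs <= 0):
        raise SpectralError("frequencies must be positive")
    min_len = n_cycles / freqs.min()
    span = dataset.times[-1] - dataset.times[0]
    if span < min_len:
        raise SpectralError(
            f"epoch ({span:.2f} s) shorter than the {n_cycles}-cycle wavelet "
            f"at {freqs.min()} Hz ({min_len:.2f} s); zero-pad the epochs first")

    if picks is None:
        ch_idx = np.arange(len(dataset.channels))
        channels = list(dataset.channels)
    else:
        lookup = {c: i for i, c in enumerate(dataset.channels)}
        missing = [c for c in picks if c not in lookup]
        if missing:
            raise SpectralError(f"unknown channel(s): {', '.join(missing)}")
        ch_idx = np.array([lookup[c] for c in picks])
        channels = list(picks)

    if out_times is None:
        out_times = _default_times(dataset.times, t_step, tmin, tmax)
    else:
        out_times = np.asarray(out_times, dtype=float)
        if out_times.min() < dataset.times[0] - 1e-9 or \
                out_times.max() > dataset.times[-1] + 1e-9:
            raise SpectralError("requested output times outside the epoch")
    n_trials, _, n_samp = dataset.data.shape
    n_ch = len(ch_idx)
    x = np.ascontiguousarray(
        dataset.data[:, ch_idx, :].reshape(n_trials * n_ch, n_samp), dtype=np.float32)
    centers = np.round((out_times - dataset.times[0]) * dataset.sfreq).astype(int)

    power = np.empty((n_trials * n_ch, len(freqs), len(out_times)), dtype=np.float32)
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(f, dataset.sfreq, n_cycles)
        half = (len(w) - 1) // 2
        wri = np.empty((len(w), 2), dtype=np.float32)
        wri[:, 0], wri[:, 1] = w.real, w.imag
        for ti, c in enumerate(centers):
            a, b = c - half, c + half + 1
            wa, wb = max(0, -a), len(w) - max(0, b - n_samp)
            a, b = max(a, 0), min(b, n_samp)
            if b <= a:
                power[:, fi, ti] = 0.0
                continue
            coef = x[:, a:b] @ wri[wa:wb]
            power[:, fi, ti] = coef[:, 0] ** 2 + coef[:, 1] ** 2
    power = power.reshape(n_trials, n_ch, len(freqs), len(out_times))
    return TFR(power=power, freqs=freqs, times=out_times, channels=channels,
               stage="raw", trial_axis="trial")


@dataclass
class FractalFit:
    """Per (unit, channel, time) log-log line of the aperiodic component.

    ``slope``/``intercept`` have shape (units, channels, times); ``included``
    (units, channels, freqs, times) flags the frequencies used in the final
    fit — excluded frequencies are the detected oscillatory peaks.
    """

    slope: np.ndarray
    intercept: np.ndarray
    included: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: list


def _wls_line(y, mask, xf):
    """Vectorized per-row weighted least squares of y on xf."""
    n = mask.sum(axis=1)
    n_safe = np.maximum(n, 1)
    sx = mask @ xf
    sxx = mask @ (xf * xf)
    sy = (mask * y).sum(axis=1)
    sxy = (mask * y) @ xf
    denom = sxx - sx * sx / n_safe
    denom = np.where(denom <= 0, np.nan, denom)
    slope = (sxy - sx * sy / n_safe) / denom
    intercept = (sy - slope * sx) / n_safe
    return slope, intercept


def _iterative_peak_mask(y, valid, xf, k_sd, max_iter):
    """Exclusion set of the iterative aperiodic fit, per row of ``y``.

    The starting line is made robust to broad oscillatory plateaus by
    refitting once on the lower-residual half of the bins; then frequencies
    whose residual exceeds ``k_sd`` residual SDs are excluded and the line
    refit until the set stabilizes or ``max_iter`` is reached.  Only
    positive residuals are excluded: oscillatory peaks are positive
    excursions above the aperiodic line.
    """
    def resid_of(slope, intercept):
        return y - (intercept[:, None] + slope[:, None] * xf[None, :])

    slope, intercept = _wls_line(y, valid, xf)
    r0 = np.where(valid, resid_of(slope, intercept), np.nan)
    med = np.nanmedian(r0, axis=1)
    mask = valid & (r0 <= med[:, None])
    too_few = mask.sum(axis=1) < 3
    if too_few.any():
        mask[too_few] = valid[too_few]
    slope, intercept = _wls_line(y, mask, xf)
    for _ in range(max_iter):
        resid = resid_of(slope, intercept)
        sd = np.sqrt((mask * resid ** 2).sum(axis=1) /
                     np.maximum(mask.sum(axis=1), 1))
        new_mask = valid & ~(resid > k_sd * sd[:, None])
        too_few = new_mask.sum(axis=1) < 3
        if too_few.any():
            new_mask[too_few] = valid[too_few]
        if (new_mask == mask).all():
            break
        mask = new_mask
        slope, intercept = _wls_line(y, mask, xf)
    return mask


def fit_fractal(tfr: TFR, k_sd: float = 2.0, max_iter: int = 10,
                share_trials: bool = False,
                share_exclusion: bool = False,
                share_times: bool = False) -> FractalFit:
    """Iterative least-squares fit of log power on log frequency.

    Cells with non-positive power (zero-padding artifacts) are masked from
    the start.  Frequencies whose residual exceeds ``k_sd`` residual SDs
    (oscillatory peaks) are excluded iteratively and the line refit until
    the excluded set stabilizes or ``max_iter`` is reached; see
    :func:`_iterative_peak_mask` for the robust-start details.  Columns left
    with fewer than 3 usable frequencies fall back to the plain fit with a
    warning.

    ``share_trials`` pools all trials for each electrode-sample pair
    (equivalently: least squares on the trial-mean log spectrum), shrinking
    residual noise by ~sqrt(n_trials).  ``share_exclusion`` determines the
    excluded-peak set once per channel from the time-averaged spectrum and
    applies it to every sample's fit: oscillatory peaks are slowly varying
    properties of the spectrum, and a per-channel set prevents marginal
    per-sample exclusion flips from jittering the extrapolated background
    under the peaks.  ``share_times`` additionally estimates one aperiodic
    line per channel from the time-averaged spectrum (the aperiodic
    background is stationary over an epoch; a time-constant line cannot leak
    event-related oscillatory power changes into the baseline-normalized
    values through the fit).
    """
    if tfr.stage != "raw":
        raise SpectralError("fit_fractal expects raw power")
    u, c, F, T = tfr.power.shape
    n_fit_units = 1 if share_trials else u
    # columns = (unit, channel, time); rows = frequency
    p = np.ascontiguousarray(np.moveaxis(tfr.power, 2, 3), dtype=np.float64)
    if share_trials:
        vald = p > 0
        with np.errstate(divide="ignore"):
            logp = np.where(vald, np.log(np.where(vald, p, 1.0)), np.nan)
        ym = np.nanmean(logp, axis=0)            # (c, T, F)
        y = ym.reshape(-1, F)
        valid = np.isfinite(y)
        y = np.where(valid, y, 0.0)
    else:
        p = p.reshape(-1, F)
        valid = p > 0
        y = np.where(valid, np.log(np.where(valid, p, 1.0)), 0.0)
    xf = np.log(tfr.freqs)

    if share_exclusion:
        y3 = np.where(valid, y, np.nan).reshape(n_fit_units, c, T, F)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            y_ch = np.nanmean(y3, axis=(0, 2))   # (c, F)
        valid_ch = np.isfinite(y_ch)
        mask_ch = _iterative_peak_mask(np.where(valid_ch, y_ch, 0.0),
                                       valid_ch, xf, k_sd, max_iter)
        mask = np.broadcast_to(mask_ch[None, :, None, :],
                               (n_fit_units, c, T, F)).reshape(-1, F) & valid
    else:
        mask = _iterative_peak_mask(y, valid, xf, k_sd, max_iter)
    if share_times:
        y3 = np.where(valid, y, np.nan).reshape(n_fit_units, c, T, F)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            y_ct = np.nanmean(y3, axis=2)        # (units', c, F)
        yt = np.broadcast_to(y_ct[:, :, None, :], (n_fit_units, c, T, F))
        y = np.where(np.isfinite(yt), yt, 0.0).reshape(-1, F)
        valid = np.isfinite(yt).reshape(-1, F)
        mask = mask & valid
    slope, intercept = _wls_line(y, mask, xf)
    if (mask.sum(axis=1) < 3).any():
        warnings.warn("fewer than 3 usable frequencies in some cells; "
                      "non-iterative fallback fit used", RuntimeWarning)
    with np.errstate(invalid="ignore"):
        if np.nanmax(slope) > 0.5:
            warnings.warn("positive 1/f slope fitted in some cells (expected "
                          "<= 0 on physiological input)", RuntimeWarning)
    shape_ut = (n_fit_units, c, T)
    slope = slope.reshape(shape_ut)
    intercept = intercept.reshape(shape_ut)
    included = np.moveaxis(mask.reshape(n_fit_units, c, T, F), 3, 2)
    if share_trials and u > 1:
        slope = np.broadcast_to(slope, (u, c, T))
        intercept = np.broadcast_to(intercept, (u, c, T))
        included = np.broadcast_to(included, (u, c, F, T))
    return FractalFit(
        slope=slope, intercept=intercept, included=included,
        freqs=tfr.freqs, times=tfr.times, channels=list(tfr.channels))


def subtract_fractal(tfr: TFR, fit: FractalFit) -> TFR:
    """Subtract the fitted aperiodic line from log power.

    Returns a ``fractal_corrected`` TFR holding the log-ratio
    log(P) - (intercept + slope * log f); exactly fitted power-law input
    yields zeros.  Non-positive cells become NaN.
    """
    if tfr.power.shape[1:] != (len(fit.channels), len(fit.freqs), len(fit.times)):
        raise SpectralError("fractal fit grid does not match the TFR grid")
    if not (np.array_equal(tfr.freqs, fit.freqs) and
            np.allclose(tfr.times, fit.times)):
        raise SpectralError("fractal fit computed on a different freq/time grid")
    logf = np.log(tfr.freqs)
    line = (fit.intercept[:, :, None, :] +
            fit.slope[:, :, None, :] * logf[None, None, :, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(tfr.power > 0, np.log(tfr.power), np.nan) - line
    return TFR(power=corrected.astype(np.float32), freqs=tfr.freqs,
               times=tfr.times, channels=list(tfr.channels),
               stage="fractal_corrected", trial_axis=tfr.trial_axis)


def condition_average(tfr: TFR, dataset: EpochedDataset,
                      correct_only: bool = True) -> TFR:
    """Average a per-trial TFR within each (task, cognate) condition cell."""
    if tfr.trial_axis != "trial":
        raise SpectralError("TFR is already condition-averaged")
    if tfr.power.shape[0] != dataset.n_trials:
        raise SpectralError("TFR trials do not match the dataset")
    cells = []
    for task, cog in CONDITIONS:
        m = dataset.condition_mask(task, cog, correct_only=correct_only)
        if not m.any():
            raise SpectralError(f"no usable trials in condition {task}/{cog}")
        cells.append(np.nanmean(tfr.power[m], axis=0))
    return TFR(power=np.stack(cells), freqs=tfr.freqs, times=tfr.times,
               channels=list(tfr.channels), stage=tfr.stage,
               trial_axis="condition")


def baseline_normalize(tfr: TFR, baseline=(-0.700, -0.200)) -> TFR:
    """Relative power change against the pre-stimulus baseline mean.

    ``fractal_corrected`` input (log-ratio) is exponentiated back to linear
    power first so the relative-change formula is well defined.
    """
    if tfr.stage == "baseline_normalized":
        raise SpectralError("TFR is already baseline-normalized")
    lin = np.exp(tfr.power) if tfr.stage == "fractal_corrected" else tfr.power
    bmask = tfr.time_mask(*baseline)
    if not bmask.any():
        raise SpectralError(f"baseline {baseline} outside the TFR time grid")
    base = lin[..., bmask].mean(axis=-1, keepdims=True)
    if np.nanmin(base) <= 0:
        raise SpectralError("baseline mean power is non-positive")
    out = (lin - base) / base
    return TFR(power=out.astype(np.float32), freqs=tfr.freqs, times=tfr.times,
               channels=list(tfr.channels), stage="baseline_normalized",
               trial_axis=tfr.trial_axis)


def band_power(tfr: TFR, band, window, channels=None,
               per_channel: bool = False) -> np.ndarray:
    """Mean power over a channel set, frequency band, and time window.

    Returns one value per leading-axis unit (trial or condition cell), or
    per unit and channel when ``per_channel``.
    """
    if tfr.stage != "baseline_normalized":
        raise SpectralError("band_power expects baseline-normalized input")
    fmask = tfr.freq_mask(*band)
    tmask = tfr.time_mask(*window)
    if channels is None:
        ch_sel = np.arange(len(tfr.channels))
    else:
        lookup = {c: i for i, c in enumerate(tfr.channels)}
        missing = [c for c in channels if c not in lookup]
        if missing:
            raise SpectralError(f"unknown channel(s): {', '.join(missing)}")
        ch_sel = np.array([lookup[c] for c in channels])
    if not fmask.any() or not tmask.any() or len(ch_sel) == 0:
        raise SpectralError("empty band/window/channel selection")
    sub = tfr.power[:, ch_sel][:, :, fmask][:, :, :, tmask]
    if per_channel:
        return sub.mean(axis=(2, 3))
    return sub.mean(axis=(1, 2, 3))
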