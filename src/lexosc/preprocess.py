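"""Continuous-signal filtering, epoching with zero-padding, trial rejection,
channel interpolation, and average re-referencing.

The stage order is fixed: filter -> epoch -> reject -> interpolate ->
re-reference (-> zero-pad before time-frequency analysis).  ``run_preprocess``
enforces and records that order.  Ocular-artifact correction is out of scope;
a peak-to-peak amplitude threshold stands in for operator-driven trial
rejection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .containers import EpochedDataset
from .montage import Montage

__all__ = [
    "PreprocessReport", "butter_filter", "epoch_and_pad", "zero_pad_epochs",
    "reject_trials", "interpolate_channels", "rereference_average",
    "run_preprocess",
]

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessReport:
    n_trials_total: int = 0
    n_trials_rejected: int = 0
    channels_interpolated: list = field(default_factory=list)
    filters_applied: list = field(default_factory=list)
    dropped_events: list = field(default_factory=list)

    @property
    def fraction_rejected(self) -> float:
        if self.n_trials_total == 0:
            return 0.0
        return self.n_trials_rejected / self.n_trials_total

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["fraction_rejected"] = self.fraction_rejected
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def butter_filter(data: np.ndarray, sfreq: float, kind: str, edges_hz,
                  order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass or band-stop.

    ``order`` is the per-pass order; the two passes double the effective
    attenuation and cancel the phase response.  Length is preserved.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise PreprocessError("signal contains non-finite values")
    lo, hi = edges_hz
    nyq = sfreq / 2.0
    if not (0 < lo < hi < nyq):
        raise PreprocessError(
            f"filter edges {edges_hz} must satisfy 0 < lo < hi < Nyquist ({nyq})")
    btype = {"bandpass": "bandpass", "bandstop": "bandstop"}.get(kind)
    if btype is None:
        raise PreprocessError(f"unknown filter kind {kind!r}")
    sos = sps.butter(order, [lo, hi], btype=btype, fs=sfreq, output="sos")
    # second-order sections are numerically stable at any sensible order
    if not np.all(np.isfinite(sos)):
        raise PreprocessError(
            "unstable filter design; reduce the order (SOS form is used already)")
    return sps.sosfiltfilt(sos, data, axis=-1)


def epoch_and_pad(
    data: np.ndarray,
    sfreq: float,
    event_samples,
    channels,
    window: tuple[float, float] = (-1.0, 1.0),
    pad_to: float = 5.0,
    task=None, cognate=None, correct=None,
    subject_id: str = "S00",
) -> tuple[EpochedDataset, list[int]]:
    """Cut epochs around events and zero-pad them to ``+-pad_to`` seconds.

    Events whose full (unpadded) window falls outside the recording are
    dropped and reported in the returned list.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    pre = int(round(-window[0] * sfreq))
    post = int(round(window[1] * sfreq))
    pad = int(round(pad_to * sfreq))
    kept, kept_idx, dropped = [], [], []
    for j, ev in enumerate(event_samples):
        if ev - pre < 0 or ev + post > n_samp:
            dropped.append(int(ev))
            logger.warning("event at sample %d too close to recording edge; dropped", ev)
            continue
        kept.append(int(ev))
        kept_idx.append(j)
    epochs = np.zeros((len(kept), n_ch, 2 * pad), dtype=float)
    for i, ev in enumerate(kept):
        epochs[i, :, pad - pre:pad + post] = data[:, ev - pre:ev + post]
    times = (np.arange(2 * pad) - pad) / sfreq
    n = len(kept)

    def _labels(arr, default):
        if arr is None:
            return np.array([default] * n)
        return np.asarray(arr)[kept_idx]

    ds = EpochedDataset(
        data=epochs, sfreq=sfreq, times=times, channels=list(channels),
        task=_labels(task, "naming"), cognate=_labels(cognate, "noncognate"),
        correct=(_labels(correct, True).astype(bool) if correct is not None
                 else np.ones(n, dtype=bool)),
        subject_id=subject_id)
    return ds, dropped


def zero_pad_epochs(dataset: EpochedDataset, pad_to: float = 5.0) -> EpochedDataset:
    """Zero-pad already-epoched data symmetrically out to ``+-pad_to`` s."""
    pad = int(round(pad_to * dataset.sfreq))
    n_trials, n_ch, n_samp = dataset.data.shape
    t0 = int(round(dataset.times[0] * dataset.sfreq))
    out = np.zeros((n_trials, n_ch, 2 * pad), dtype=dataset.data.dtype)
    start = pad + t0
    if start < 0 or start + n_samp > 2 * pad:
        raise PreprocessError("epoch window does not fit inside the padded span")
    out[:, :, start:start + n_samp] = dataset.data
    times = (np.arange(2 * pad) - pad) / dataset.sfreq
    ds = dataset.copy()
    ds.data, ds.times = out, times
    return ds


def reject_trials(
    dataset: EpochedDataset,
    peak_to_peak_uv: float = 150.0,
    window: tuple[float, float] = (-1.0, 1.0),
    exclude_channels=(),
) -> tuple[EpochedDataset, PreprocessReport]:
    """Drop trials whose peak-to-peak amplitude exceeds the threshold on any
    non-excluded channel within ``window``."""
    if peak_to_peak_uv <= 0:
        raise PreprocessError("threshold must be positive")
    tmask = dataset.time_mask(*window)
    ch_idx = [i for i, c in enumerate(dataset.channels) if c not in exclude_channels]
    seg = dataset.data[:, ch_idx][:, :, tmask]
    ptp = seg.max(axis=-1) - seg.min(axis=-1)
    bad = (ptp > peak_to_peak_uv).any(axis=1)
    if bad.all() and dataset.n_trials > 0:
        raise PreprocessError(
            f"all {dataset.n_trials} trials exceed {peak_to_peak_uv} uV "
            "peak-to-peak; threshold is likely mis-set")
    report = PreprocessReport(
        n_trials_total=dataset.n_trials,
        n_trials_rejected=int(bad.sum()),
    )
    return dataset.select_trials(~bad), report


def interpolate_channels(
    dataset: EpochedDataset, bad_channels, montage: Montage,
) -> EpochedDataset:
    """Replace each bad channel by the inverse-planar-distance weighted mean
    of its good Delaunay neighbors (triangulation-of-nearest interpolation)."""
    ds = dataset.copy()
    bad_set = set(bad_channels)
    ch_idx = montage.index(dataset.channels)
    pos2d = montage.pos2d[ch_idx]
    adj_full = montage.neighbors[np.ix_(ch_idx, ch_idx)]
    name_to_local = {c: i for i, c in enumerate(dataset.channels)}
    for bad in bad_channels:
        i = name_to_local[bad]
        nbrs = [j for j in np.flatnonzero(adj_full[i])
                if dataset.channels[j] not in bad_set]
        if len(nbrs) < 2:
            raise PreprocessError(
                f"channel {bad} has fewer than 2 good neighbors; cannot interpolate")
        dist = np.linalg.norm(pos2d[nbrs] - pos2d[i], axis=1)
        w = 1.0 / np.maximum(dist, 1e-12)
        w /= w.sum()
        ds.data[:, i, :] = np.tensordot(w, dataset.data[:, nbrs, :], axes=(0, 1))
    return ds


def rereference_average(dataset: EpochedDataset) -> EpochedDataset:
    """Subtract the instantaneous mean across channels (average reference)."""
    if len(dataset.channels) < 2:
        raise PreprocessError("average reference needs at least 2 channels")
    ds = dataset.copy()
    ds.data = ds.data - ds.data.mean(axis=1, keepdims=True)
    return ds


def run_preprocess(
    dataset: EpochedDataset,
    montage: Montage,
    reject_ptp_uv: float = 150.0,
    bad_channels=(),
    pad_to: float | None = 5.0,
) -> tuple[EpochedDataset, PreprocessReport]:
    """Epoch-level preprocessing in the contract order:
    reject -> interpolate -> re-reference (-> zero-pad)."""
    ds, report = reject_trials(dataset, reject_ptp_uv)
    if bad_channels:
        ds = interpolate_channels(ds, bad_channels, montage)
        report.channels_interpolated = list(bad_channels)
    ds = rereference_average(ds)
    if pad_to is not None:
        ds = zero_pad_epochs(ds, pad_to)
    return ds, report
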