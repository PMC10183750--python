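"""In-memory containers (epoched EEG, time-frequency power) and their
on-disk form: a flat binary array plus a JSON metadata sidecar."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["EpochedDataset", "TFR", "write_epochs", "read_epochs"]

CONTAINER_SCHEMA_VERSION = 1

TASKS = ("naming", "size")
COGNATE_LEVELS = ("noncognate", "cognate")
#: (task, cognate) pairs in the canonical reporting order
CONDITIONS = (
    ("naming", "noncognate"),
    ("naming", "cognate"),
    ("size", "noncognate"),
    ("size", "cognate"),
)


class ContainerError(ValueError):
    pass


@dataclass
class EpochedDataset:
    """Epoched multichannel EEG with per-trial condition labels.

    ``data`` is trials x channels x samples in microvolts; ``times`` is the
    shared latency axis in seconds relative to stimulus onset.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    channels: list[str]
    task: np.ndarray          # per-trial, values in TASKS
    cognate: np.ndarray       # per-trial, values in COGNATE_LEVELS
    correct: np.ndarray       # per-trial bool
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        self.task = np.asarray(self.task)
        self.cognate = np.asarray(self.cognate)
        self.correct = np.asarray(self.correct, dtype=bool)
        n_trials, n_ch, n_samp = self.data.shape
        if len(self.channels) != n_ch:
            raise ContainerError("channel list does not match data shape")
        if self.times.shape != (n_samp,):
            raise ContainerError("times axis does not match data shape")
        dt = np.diff(self.times)
        if n_samp > 1 and not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6, atol=1e-9):
            raise ContainerError("times must increase uniformly at 1/sfreq")
        for arr, name in ((self.task, "task"), (self.cognate, "cognate"),
                          (self.correct, "correct")):
            if arr.shape != (n_trials,):
                raise ContainerError(f"{name} labels must have length n_trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def condition_mask(self, task: str, cognate: str, correct_only: bool = True) -> np.ndarray:
        mask = (self.task == task) & (self.cognate == cognate)
        if correct_only:
            mask &= self.correct
        return mask

    def select_trials(self, mask: np.ndarray) -> "EpochedDataset":
        return replace(
            self, data=self.data[mask], task=self.task[mask],
            cognate=self.cognate[mask], correct=self.correct[mask],
        )

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        return (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)

    def copy(self) -> "EpochedDataset":
        return replace(self, data=self.data.copy())


# Valid provenance stages, in pipeline order.
TFR_STAGES = ("raw", "fractal_corrected", "baseline_normalized")


@dataclass
class TFR:
    """Time-frequency power, per trial or per condition.

    ``power`` has shape (units, channels, freqs, times) where the leading
    axis is trials (``trial_axis='trial'``) or condition cells
    (``trial_axis='condition'``, ordered like :data:`CONDITIONS`).
    ``stage`` records provenance: raw linear power, 1/f-corrected log-ratio
    power, or baseline-normalized relative change.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: list[str]
    stage: str = "raw"
    trial_axis: str = "trial"
    conditions: tuple = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.stage not in TFR_STAGES:
            raise ContainerError(f"unknown TFR stage {self.stage!r}")
        expect = (self.power.shape[1], self.power.shape[2], self.power.shape[3])
        if expect != (len(self.channels), len(self.freqs), len(self.times)):
            raise ContainerError("TFR power shape does not match axes")
        if self.stage == "raw" and self.power.size and float(np.nanmin(self.power)) < 0:
            raise ContainerError("raw power must be non-negative")

    def freq_mask(self, fmin: float, fmax: float) -> np.ndarray:
        return (self.freqs >= fmin - 1e-9) & (self.freqs <= fmax + 1e-9)

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        return (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)


def write_epochs(dataset: EpochedDataset, path) -> None:
    """Write ``<path>.bin`` (little-endian float32, C order) and ``<path>.json``."""
    path = Path(path)
    data = np.ascontiguousarray(dataset.data, dtype="<f4")
    meta = {
        "schema_version": CONTAINER_SCHEMA_VERSION,
        "shape": list(data.shape),
        "dtype": "<f4",
        "sfreq": dataset.sfreq,
        "tmin": float(dataset.times[0]),
        "channels": list(dataset.channels),
        "task": dataset.task.tolist(),
        "cognate": dataset.cognate.tolist(),
        "correct": dataset.correct.astype(int).tolist(),
        "subject_id": dataset.subject_id,
    }
    path.with_suffix(".bin").write_bytes(data.tobytes())
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_epochs(path) -> EpochedDataset:
    path = Path(path)
    meta_path, bin_path = path.with_suffix(".json"), path.with_suffix(".bin")
    if not meta_path.exists() or not bin_path.exists():
        raise ContainerError(f"missing container file(s) for {path}")
    meta = json.loads(meta_path.read_text())
    version = meta.get("schema_version")
    if version != CONTAINER_SCHEMA_VERSION:
        raise ContainerError(
            f"container schema version {version!r} unsupported "
            f"(expected {CONTAINER_SCHEMA_VERSION})")
    shape = tuple(meta["shape"])
    raw = bin_path.read_bytes()
    expected = int(np.prod(shape)) * 4
    if len(raw) != expected:
        raise ContainerError(
            f"truncated container: {len(raw)} bytes, expected {expected}")
    data = np.frombuffer(raw, dtype=meta["dtype"]).reshape(shape).copy()
    n_samp = shape[2]
    times = meta["tmin"] + np.arange(n_samp) / meta["sfreq"]
    return EpochedDataset(
        data=data, sfreq=meta["sfreq"], times=times,
        channels=meta["channels"],
        task=np.array(meta["task"]), cognate=np.array(meta["cognate"]),
        correct=np.array(meta["correct"], dtype=bool),
        subject_id=meta["subject_id"],
    )
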