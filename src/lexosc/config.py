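"""Analysis and simulation configuration.

Defaults mirror the study conditions: 38-channel 10-20 EEG at 500 Hz,
18 subjects, 2 tasks x 2 cognate conditions x 32 trials, theta 3-7 Hz /
beta 25-35 Hz band power in task-specific centro-parietal ROIs and windows,
2000-iteration cluster permutation tests, and theta-beta coupling targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "SyntheticConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


NAMING_ROI = ("T3", "C3", "CP3", "CP4", "P3", "P4", "Pz", "POz", "PO2", "Oz", "O2")
SIZE_ROI = ("T5", "Cz", "C3", "C4", "CP3", "CP4", "P3", "P4")
COMMON_ROI = ("C3", "CP3", "P3", "C4", "CP4", "P4", "Cz", "CPz", "Pz")


@dataclass
class AnalysisConfig:
    """Parameters of the statistical analysis chain."""

    bands: dict = field(default_factory=lambda: {
        "theta": (3.0, 7.0),
        "alpha": (8.0, 12.0),
        "beta_power": (25.0, 35.0),
        "beta_pac": (13.0, 30.0),
    })
    windows: dict = field(default_factory=lambda: {
        "naming_roi": (0.160, 0.260),
        "size_roi": (0.260, 0.380),
        "baseline": (-0.700, -0.200),
    })
    rois: dict = field(default_factory=lambda: {
        "naming": NAMING_ROI,
        "size": SIZE_ROI,
        "common": COMMON_ROI,
    })
    n_permutations: int = 2000
    min_neighbor_channels: int = 3
    cluster_alpha: float = 0.05
    subsample_fraction: float = 0.8
    n_subsample_iterations: int = 100
    n_phase_bins: int = 12
    bonferroni_alpha: float = 0.0125
    theta_filter_sd: float = 0.5   # Hz, spectral SD of the PAC theta filter
    beta_filter_sd: float = 5.0    # Hz, spectral SD of the PAC beta filter
    tfr_fmin: float = 1.0
    tfr_fmax: float = 40.0
    tfr_fstep: float = 1.0
    tfr_tstep: float = 0.020       # s
    n_cycles: float = 5.0
    reject_ptp_uv: float = 150.0   # peak-to-peak artifact threshold stand-in
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction <= 1):
            raise ConfigError("subsample_fraction must be in (0, 1]")
        if 360 % self.n_phase_bins != 0:
            raise ConfigError("n_phase_bins must divide 360 evenly")
        for name, (lo, hi) in self.windows.items():
            if hi <= lo:
                raise ConfigError(f"window {name} is empty")

    def validate_rois(self, montage) -> None:
        for name, chans in self.rois.items():
            montage.index(chans)  # raises listing unknown channels

    def window_for_task(self, task: str) -> tuple[float, float]:
        return self.windows[f"{task}_roi"]

    def roi_for_task(self, task: str):
        return tuple(self.rois[task])


# Condition keys in canonical order, matching containers.CONDITIONS.
CONDITION_KEYS = ("naming_nc", "naming_c", "size_nc", "size_c")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic EEG + behavior generator.

    The per-condition defaults are the group means the analysis is expected
    to recover: relative beta decreases / theta increases, modulation-index
    targets, and RT/accuracy means.  Between-subject SDs are half the
    reported across-subject SDs, the remainder being contributed at trial
    level by the generator's noise.
    """

    n_subjects: int = 18
    trials_per_condition: int = 32
    sfreq: float = 500.0
    epoch_tmin: float = -1.0
    epoch_tmax: float = 1.0
    aperiodic_exponent: float = 1.0
    aperiodic_amplitude: float = 1.0    # sqrt(uV^2 Hz^(chi-1)): PSD(f) = amp^2 / f^chi
    sensor_noise_sd: float = 0.3        # uV, white
    # oscillation-to-background power ratio at the carrier's TFR bin
    osc_background_ratio: dict = field(default_factory=lambda: {
        "theta": 50.0, "beta": 40.0})
    # frequency bands over which the analysis averages normalized power
    measure_bands: dict = field(default_factory=lambda: {
        "theta": (3.0, 7.0), "beta": (25.0, 35.0)})
    theta_freq: float = 5.0
    theta_spectral_sd: float = 0.5      # Hz, width of the theta component
    beta_freq: dict = field(default_factory=lambda: {"naming": 29.8, "size": 29.6})
    beta_freq_subject_sd: float = 0.3   # Hz, clipped to [28.5, 29.9]
    # relative band-power changes per condition (naming_nc, naming_c, size_nc, size_c)
    beta_rel_change: dict = field(default_factory=lambda: {
        "naming_nc": -0.13, "naming_c": -0.21, "size_nc": -0.15, "size_c": -0.22})
    theta_rel_change: dict = field(default_factory=lambda: {
        "naming_nc": 0.47, "naming_c": 0.55, "size_nc": 0.46, "size_c": 0.36})
    # reported across-subject SDs; drawn per subject after scaling
    beta_rel_sd: dict = field(default_factory=lambda: {
        "naming_nc": 0.13, "naming_c": 0.10, "size_nc": 0.16, "size_c": 0.13})
    theta_rel_sd: dict = field(default_factory=lambda: {
        "naming_nc": 0.23, "naming_c": 0.34, "size_nc": 0.27, "size_c": 0.22})
    between_subject_scale: float = 0.5
    # correlation of a subject's condition effects within a band (shared
    # oscillatory-reactivity component)
    effect_correlation: float = 0.7
    effect_windows: dict = field(default_factory=lambda: {
        "naming": (0.160, 0.260), "size": (0.260, 0.380)})
    effect_rois: dict = field(default_factory=lambda: {
        "naming": NAMING_ROI, "size": SIZE_ROI})
    # trial-to-trial band-power jitter (SD of a unit-mean multiplier)
    trial_power_jitter_sd: float = 0.25
    pac_target_mi: dict = field(default_factory=lambda: {
        "naming_nc": 0.028, "naming_c": 0.029, "size_nc": 0.032, "size_c": 0.031})
    pac_calibration_tol: float = 0.02
    pac_calibration_trials: int = 96
    rt_mean_ms: dict = field(default_factory=lambda: {
        "naming_nc": 848.0, "naming_c": 799.0, "size_nc": 805.0, "size_c": 795.0})
    rt_between_sd_ms: dict = field(default_factory=lambda: {
        "naming_nc": 115.0, "naming_c": 120.0, "size_nc": 147.0, "size_c": 142.0})
    rt_subject_sd_ms: float = 110.0     # shared subject intercept
    rt_condition_sd_ms: float = 20.0    # condition-specific subject deviation
    rt_trial_sd_ms: float = 150.0
    rt_floor_ms: float = 150.0
    accuracy_mean: dict = field(default_factory=lambda: {
        "naming_nc": 0.72, "naming_c": 0.84, "size_nc": 0.79, "size_c": 0.85})
    accuracy_subject_sd: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for key, r in self.beta_rel_change.items():
            if r <= -1:
                raise ConfigError(f"beta_rel_change[{key}] must be > -1")
        for key, r in self.theta_rel_change.items():
            if r <= -1:
                raise ConfigError(f"theta_rel_change[{key}] must be > -1")
        for key, mi in self.pac_target_mi.items():
            if not (0 <= mi < 1):
                raise ConfigError(f"pac_target_mi[{key}] must be in [0, 1)")
        for key, acc in self.accuracy_mean.items():
            if not (0 < acc <= 1):
                raise ConfigError(f"accuracy_mean[{key}] must be in (0, 1]")
        if self.epoch_tmax <= self.epoch_tmin:
            raise ConfigError("empty epoch window")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_tmax - self.epoch_tmin) * self.sfreq))

    @property
    def times(self):
        import numpy as np
        return self.epoch_tmin + np.arange(self.n_samples) / self.sfreq


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config, path) -> None:
    kind = "analysis" if isinstance(config, AnalysisConfig) else "synthetic"
    payload = {"kind": kind, "params": _to_plain(asdict(config))}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path):
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "kind" not in payload:
        raise ConfigError(f"not a lexosc config file: {path}")
    cls = {"analysis": AnalysisConfig, "synthetic": SyntheticConfig}[payload["kind"]]
    params = payload.get("params", {})
    cfg = cls(**params)
    # YAML round-trips tuples as lists; normalize windows back to tuples
    for attr in ("windows", "effect_windows"):
        if hasattr(cfg, attr):
            d = getattr(cfg, attr)
            setattr(cfg, attr, {k: tuple(v) for k, v in d.items()})
    return cfg
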