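"""Orchestration of the full analysis: simulate -> preprocess -> spectral ->
cluster/searchlight -> PAC -> behavioral statistics.

Stages exchange data through tidy tables and the package's containers; a
``RunManifest`` records the configuration hash, the seed fan-out and the
outputs, so a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (one_sample_t_bonferroni, paired_t_cohen_bf,
                       rm_anova_2x2, trim_and_aggregate)
from .cluster import cluster_permutation_test
from .config import AnalysisConfig, CONDITION_KEYS, SyntheticConfig
from .containers import CONDITIONS, EpochedDataset, read_epochs, write_epochs
from .montage import Montage, load_montage
from .pac import pac_condition_mean
from .preprocess import run_preprocess
from .searchlight import scalp_effect_distribution, searchlight_pvalue
from .simulate import generate_cohort
from .spectral import (band_power, baseline_normalize, condition_average,
                       fit_fractal, morlet_tfr, subtract_fractal)

__all__ = ["RunManifest", "run", "analysis_times", "normalized_condition_tfr",
           "band_power_table", "per_channel_band_power"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


# fixed per-stage seed offsets fanned out from the global seed
STAGE_SEEDS = {"simulate": 1, "cluster": 2, "searchlight": 3, "pac": 4}


def stage_seed(seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([seed, STAGE_SEEDS[stage]])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stage_seconds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def _hash_config(*configs) -> str:
    from dataclasses import asdict

    text = yaml.safe_dump([asdict(c) for c in configs], sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def analysis_times(config: AnalysisConfig) -> np.ndarray:
    """Output-time grid covering the baseline and both analysis windows
    (20 ms steps), the minimum the band-power statistics need."""
    step = config.tfr_tstep
    spans = [config.windows["baseline"],
             (config.windows["naming_roi"][0] - 2 * step,
              config.windows["size_roi"][1] + 2 * step)]
    pts = []
    for lo, hi in spans:
        k0, k1 = int(np.ceil(lo / step - 1e-9)), int(np.floor(hi / step + 1e-9))
        pts.extend(np.arange(k0, k1 + 1) * step)
    return np.unique(np.round(np.asarray(pts), 6))


def normalized_condition_tfr(dataset: EpochedDataset, config: AnalysisConfig,
                             picks=None, out_times=None):
    """Full spectral chain for one subject: Morlet TFR (per trial) ->
    iterative 1/f fit and subtraction -> condition averaging (correct trials)
    -> baseline normalization.  Returns a condition-level TFR."""
    freqs = np.arange(config.tfr_fmin, config.tfr_fmax + config.tfr_fstep / 2,
                      config.tfr_fstep)
    if out_times is None:
        out_times = analysis_times(config)
    tfr = morlet_tfr(dataset, freqs=freqs, n_cycles=config.n_cycles,
                     t_step=config.tfr_tstep, picks=picks, out_times=out_times)
    fit = fit_fractal(tfr, share_trials=True, share_exclusion=True,
                      share_times=True)
    corrected = subtract_fractal(tfr, fit)
    cond = condition_average(corrected, dataset, correct_only=True)
    return baseline_normalize(cond, baseline=config.windows["baseline"])


def band_power_table(datasets, config: AnalysisConfig,
                     bands=("beta_power", "theta"), picks=None) -> pd.DataFrame:
    """Subject x condition x band ROI band power (tidy long table).

    Each band is averaged over the task-specific ROI and window.
    """
    rows = []
    for ds in datasets:
        union = picks
        if union is None:
            union = sorted({c for task in ("naming", "size")
                            for c in config.roi_for_task(task)
                            if c in ds.channels})
        ntfr = normalized_condition_tfr(ds, config, picks=union)
        for ci, (task, cog) in enumerate(CONDITIONS):
            roi = [c for c in config.roi_for_task(task) if c in ntfr.channels]
            window = config.window_for_task(task)
            for band in bands:
                val = band_power(ntfr, config.bands[band], window,
                                 channels=roi)[ci]
                rows.append({"subject": ds.subject_id, "task": task,
                             "cognate": cog, "band": band,
                             "value": float(val)})
    return pd.DataFrame(rows)


def per_channel_band_power(datasets, config: AnalysisConfig,
                           band: str = "beta_power") -> tuple[np.ndarray, list]:
    """(subjects, conditions, channels) window-mean normalized band power
    for channel-space cluster and searchlight statistics."""
    channels = list(datasets[0].channels)
    out = np.empty((len(datasets), len(CONDITIONS), len(channels)))
    for si, ds in enumerate(datasets):
        ntfr = normalized_condition_tfr(ds, config, picks=channels)
        for ci, (task, cog) in enumerate(CONDITIONS):
            window = config.window_for_task(task)
            out[si, ci] = band_power(ntfr, config.bands[band], window,
                                     channels=channels, per_channel=True)[ci]
    return out, channels


def roi_band_timecourse(datasets, config: AnalysisConfig, task: str,
                        band: str = "beta_power", tmin: float = 0.0,
                        tmax: float = 0.6, t_step: float | None = None):
    """ROI-mean normalized band-power timecourses for one task's two
    conditions.

    Returns (values_nc, values_c, times) with values subjects x times,
    suitable for :func:`lexosc.cluster.timecourse_cluster_test`.
    """
    step = t_step or config.tfr_tstep
    base = config.windows["baseline"]
    pts = []
    for lo, hi in (base, (tmin, tmax)):
        k0, k1 = int(np.ceil(lo / step - 1e-9)), int(np.floor(hi / step + 1e-9))
        pts.extend(np.arange(k0, k1 + 1) * step)
    out_times = np.unique(np.round(pts, 6))
    roi = [c for c in config.roi_for_task(task) if c in datasets[0].channels]
    ci_nc = CONDITIONS.index((task, "noncognate"))
    ci_c = CONDITIONS.index((task, "cognate"))
    rows_nc, rows_c = [], []
    for ds in datasets:
        ntfr = normalized_condition_tfr(ds, config, picks=roi,
                                        out_times=out_times)
        fmask = ntfr.freq_mask(*config.bands[band])
        tmask = ntfr.time_mask(tmin, tmax)
        tc = ntfr.power[:, :, fmask][:, :, :, tmask].mean(axis=(1, 2))
        rows_nc.append(tc[ci_nc])
        rows_c.append(tc[ci_c])
    times = out_times[(out_times >= tmin - 1e-9) & (out_times <= tmax + 1e-9)]
    return np.array(rows_nc), np.array(rows_c), times


def behavioral_stats(behavior: pd.DataFrame) -> dict:
    """Accuracy/RT aggregation, 2x2 rm-ANOVAs, and planned comparisons."""
    agg = trim_and_aggregate(behavior)
    out = {"aggregate": agg}
    for dv in ("accuracy", "mean_rt_ms"):
        wide = agg.pivot_table(index="subject", columns=["task", "cognate"],
                               values=dv)
        cells = np.stack([
            np.stack([wide[("naming", "noncognate")], wide[("naming", "cognate")]],
                     axis=1),
            np.stack([wide[("size", "noncognate")], wide[("size", "cognate")]],
                     axis=1)], axis=1)
        out[f"anova_{dv}"] = rm_anova_2x2(cells)
        out[f"planned_{dv}"] = {
            task: paired_t_cohen_bf(wide[(task, "cognate")],
                                    wide[(task, "noncognate")])
            for task in ("naming", "size")}
    return out


def run(
    synth_config: SyntheticConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    stages=("simulate", "preprocess", "tfr", "cluster", "searchlight",
            "pac", "stats"),
    out_dir="lexosc_out",
    seed: int | None = None,
    montage: Montage | None = None,
) -> RunManifest:
    """Execute the requested stages in dependency order under ``out_dir``."""
    synth_config = synth_config or SyntheticConfig()
    analysis_config = analysis_config or AnalysisConfig()
    if seed is not None:
        synth_config = replace(synth_config, rng_seed=seed)
    montage = montage or load_montage("study38")
    analysis_config.validate_rois(montage)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_hash_config(synth_config, analysis_config),
        seed=synth_config.rng_seed)
    state: dict = {}

    def _record(name, t0):
        manifest.stage_seconds[name] = round(time.time() - t0, 3)

    def _need(key, stage, hint):
        if key not in state:
            raise PipelineError(
                f"stage '{stage}' needs outputs of '{hint}'; run it first")

    for stage in stages:
        t0 = time.time()
        logger.info("stage %s ...", stage)
        if stage == "simulate":
            datasets, behavior, meta = generate_cohort(synth_config, montage)
            state["raw"] = datasets
            state["behavior"] = behavior
            behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
            (out / "simulate_meta.json").write_text(json.dumps(meta, indent=1))
            manifest.outputs.append("behavior.tsv")
        elif stage == "preprocess":
            _need("raw", stage, "simulate")
            processed = []
            reports = []
            for ds in state["raw"]:
                p, rep = run_preprocess(
                    ds, montage, reject_ptp_uv=analysis_config.reject_ptp_uv,
                    pad_to=5.0)
                processed.append(p)
                reports.append({"subject": ds.subject_id,
                                "n_rejected": rep.n_trials_rejected,
                                "fraction": rep.fraction_rejected})
            state["epochs"] = processed
            (out / "preprocess_report.json").write_text(
                json.dumps(reports, indent=1))
            manifest.outputs.append("preprocess_report.json")
        elif stage == "tfr":
            _need("epochs", stage, "preprocess")
            table = band_power_table(state["epochs"], analysis_config)
            state["band_power"] = table
            table.to_csv(out / "band_power.tsv", sep="\t", index=False)
            manifest.outputs.append("band_power.tsv")
        elif stage == "cluster":
            _need("epochs", stage, "preprocess")
            power, channels = per_channel_band_power(
                state["epochs"], analysis_config)
            state["channel_power"] = (power, channels)
            adjacency = montage.neighbors
            rng_seed = stage_seed(synth_config.rng_seed, "cluster")
            results = {}
            for ti, task in enumerate(("naming", "size")):
                nc, c = 2 * ti, 2 * ti + 1
                res = cluster_permutation_test(
                    power[:, nc], power[:, c], adjacency,
                    n_permutations=analysis_config.n_permutations,
                    alpha=analysis_config.cluster_alpha,
                    min_nbchan=analysis_config.min_neighbor_channels,
                    rng=rng_seed + ti, elements=channels)
                res.to_json(out / f"cluster_{task}.json")
                results[task] = res
                manifest.outputs.append(f"cluster_{task}.json")
            state["cluster"] = results
        elif stage == "searchlight":
            _need("channel_power", stage, "cluster")
            power, channels = state["channel_power"]
            rng_seed = stage_seed(synth_config.rng_seed, "searchlight")
            results = {}
            for ti, task in enumerate(("naming", "size")):
                roi = [c for c in analysis_config.roi_for_task(task)
                       if c in channels]
                nc, c = 2 * ti, 2 * ti + 1
                dist = scalp_effect_distribution(
                    power[:, nc], power[:, c], channels, montage, roi,
                    k=len(roi))
                searchlight_pvalue(dist,
                                   n_permutations=analysis_config.n_permutations,
                                   rng=rng_seed + ti)
                dist.to_json(out / f"searchlight_{task}.json")
                results[task] = dist
                manifest.outputs.append(f"searchlight_{task}.json")
            state["searchlight"] = results
        elif stage == "pac":
            _need("raw", stage, "simulate")
            rng_seed = stage_seed(synth_config.rng_seed, "pac")
            rows = []
            for si, ds in enumerate(state["raw"]):
                res = pac_condition_mean(ds, analysis_config,
                                         rng=rng_seed + si)
                for key, mi in res.mi_per_condition.items():
                    task, cc = key.rsplit("_", 1)
                    rows.append({
                        "subject": ds.subject_id, "task": task,
                        "cognate": "noncognate" if cc == "nc" else "cognate",
                        "mi": mi,
                        "theta_peak": res.theta_peak[task].frequency,
                        "beta_peak": res.beta_peak[task].frequency})
            pac_table = pd.DataFrame(rows)
            state["pac"] = pac_table
            pac_table.to_csv(out / "pac.tsv", sep="\t", index=False)
            manifest.outputs.append("pac.tsv")
        elif stage == "stats":
            _need("behavior", stage, "simulate")
            stats_out = behavioral_stats(state["behavior"])
            payload = {}
            for key, val in stats_out.items():
                if key == "aggregate":
                    val.to_csv(out / "behavior_aggregate.tsv", sep="\t",
                               index=False)
                    manifest.outputs.append("behavior_aggregate.tsv")
                elif hasattr(val, "effects"):
                    payload[key] = val.effects
                else:
                    payload[key] = val
            if "band_power" in state:
                payload["band_power_one_sample"] = {}
                for (task, cog), grp in state["band_power"][
                        state["band_power"].band == "beta_power"].groupby(
                            ["task", "cognate"]):
                    payload["band_power_one_sample"][f"{task}_{cog}"] = \
                        one_sample_t_bonferroni(grp["value"].to_numpy())
            (out / "stats.json").write_text(json.dumps(payload, indent=1,
                                                       default=float))
            manifest.outputs.append("stats.json")
        else:
            raise PipelineError(f"unknown stage {stage!r}")
        _record(stage, t0)

    manifest.to_json(out / "manifest.json")
    return manifest
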