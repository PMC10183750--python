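# lexosc

Oscillatory EEG analysis of lexical access in bilingual picture-object
processing: Morlet time–frequency decomposition with iterative 1/f
(aperiodic) subtraction, channel-space cluster-based permutation statistics,
a searchlight mini-cluster test of scalp specificity, theta–beta
phase–amplitude coupling via the modulation index, behavioral statistics
with Bayes factors — and a synthetic EEG + behavior generator that realizes
the cohort structure these analyses assume, so the whole chain is testable
end to end.

## The scientific problem

When bilinguals name a picture, words whose translations share form across
the two languages (*cognates*, e.g. tomate/tomàquet) are retrieved more
easily than non-cognates.  The analyses here quantify the
electrophysiological signature of that advantage in a 2 (task: picture
naming vs. size judgment) × 2 (cognate status) within-subject design with
38-channel, 500 Hz EEG:

- **Beta desynchronization.**  Post-stimulus power in the 25–35 Hz band,
  expressed as relative change against a −700…−200 ms baseline,
  (P − P̄_base)/P̄_base, decreases over centro-parietal electrodes, more for
  cognates than non-cognates, in task-specific windows (160–260 ms for
  naming, 260–380 ms for size judgment).
- **Theta synchronization.**  3–7 Hz power increases in the same windows.
- **Theta–beta coupling.**  Beta amplitude is modulated by theta phase; the
  modulation index MI = (log N − H(p))/log N (N = 12 phase bins, H the
  Shannon entropy of the normalized bin-amplitude profile) quantifies the
  coupling, computed per trial and electrode on participant-specific
  spectral peaks with balanced (80% of the smallest correct-trial count)
  subsampling across conditions.
- **Inference.**  Monte-Carlo cluster-based permutation tests (2000
  sign-flip iterations, cluster-forming α = 0.05, ≥ 3 supra-threshold
  neighbors, maximum cluster size), a searchlight comparison of the ROI
  effect against equally sized electrode neighborhoods tiled over the rest
  of the scalp, 2×2 repeated-measures ANOVAs, and planned t tests with
  Cohen's d = t/√n and JZS Bayes factors.

Because oscillatory power rides on a 1/f aperiodic background, log power is
regressed on log frequency per electrode–sample pair (iteratively excluding
oscillatory peaks) and the fitted line subtracted before baseline
normalization.

## Worked example

```python
from lexosc.config import AnalysisConfig, SyntheticConfig
from lexosc.montage import load_montage
from lexosc.pipeline import band_power_table
from lexosc.preprocess import run_preprocess
from lexosc.simulate import generate_cohort

montage = load_montage("study38")
cfg = SyntheticConfig(rng_seed=11)          # 18 subjects, 32 trials/condition
analysis = AnalysisConfig()

datasets, behavior, meta = generate_cohort(cfg, montage)
processed = [run_preprocess(d, montage, pad_to=5.0)[0] for d in datasets]
table = band_power_table(processed, analysis)

summary = (table.groupby(["band", "task", "cognate"]).value.mean()
           .round(3).unstack("cognate"))
print(summary)
```

```
cognate            cognate  noncognate
band       task
beta_power naming   -0.214      -0.112
           size     -0.204      -0.139
theta      naming    0.588       0.517
           size      0.355       0.476
```

Reading the numbers: beta power drops ~11–21% below baseline in the
analysis windows, more for cognates than non-cognates in both tasks
(−0.214 vs −0.112 in naming), while theta rises ~36–59% — the configured
condition means of the generator (beta −0.13/−0.21/−0.15/−0.22, theta
+0.47/+0.55/+0.46/+0.36), recovered by the full preprocessing + Morlet +
1/f-subtraction + baseline-normalization chain up to this cohort's
between-subject draws.

The same objects feed the inferential stages: `cluster_permutation_test`
on per-channel band power, `scalp_effect_distribution` /
`searchlight_pvalue` for the searchlight, `pac_condition_mean` for MI, and
`behavioral_stats` for accuracy/RT ANOVAs.  A thin CLI wraps the pipeline:

```bash
lexosc all --seed 11 --out run_out      # simulate ... stats, writes TSV/JSON
```

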