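# eggsense

Noise-robust nausea detection from the electrogastrogram (EGG).

The cutaneous EGG records gastric myoelectrical activity: µV-scale slow
waves at roughly 3 cycles per minute (cpm). Nausea — for example
simulator sickness during a driving simulation — shifts the slow wave
towards higher frequencies, raises its amplitude and makes the rhythm
more irregular. Because the EGG is small and slow it is exceptionally
sensitive to motion artifacts and wideband noise, so any feature used
for automated nausea detection must be vetted for noise robustness.

`eggsense` provides that vetting pipeline end to end, for signal-processing
researchers and driving-simulator/VR teams:

- **Synthetic EGG cohorts** — a generator that emulates baseline and
  nausea-state slow waves (AR(1) frequency jitter, sub-1-cpm drift,
  wideband noise, spike artifacts), so the whole pipeline runs without
  any recordings.
- **Semi-synthetic noise injection** — seeded white noise scaled to
  exact target SNRs (−20 … 20 dB) against the raw signal, then coloured
  by the standard 1–10 cpm bandpass; achieved in-band SNRs are measured
  and reported.
- **Preprocessing** — 6th-order zero-phase Butterworth bandpass
  (0.0167–0.167 Hz), robust spike detection, fewest-artifact channel
  selection, half-open segment labelling from button-press events.
- **A 17-feature battery** (per segment): RMS; median frequency; dominant
  frequency DF and its PSD magnitude MagDF; crest factor CS of the PSD;
  spectral variation distribution SDV; sample entropy of the time series
  (SampEntT) and of the PSD sequence (SampEntP) at embedding dimensions
  m = 2, 3, 4 with tolerance r = 0.15·SD of the noiseless reference;
  spectral entropy; autocorrelation zero-crossing; and the Poincaré
  descriptors SD1, SD2, SDEGG of the lag-1 sample scatter, where
  SampEn(m, r) = −ln(A/B) with B and A the counts of m- and
  (m+1)-length template pairs within Chebyshev distance r, SD1² =
  Var(xₙ₊₁−xₙ)/2, SD2² = 2·Var(x) − SD1², SDEGG² = (SD1²+SD2²)/2.
- **Robustness statistics** — per feature and SNR level, Shapiro–Wilk
  gated paired t / Wilcoxon signed-rank tests with Cohen's d / Cliff's
  delta; unpaired Welch t / Mann–Whitney U for the nausea effect;
  Pearson chi-square with Monte-Carlo p for the categorical entropy
  split at 10.
- **Random-forest protocol** — stratified 75/25 split, leave-one-out
  tuning of mtry over {2, 9, 17}, seeded 500-tree forest, confusion
  metrics with exact binomial CI, train/test AUCs, selection-count
  feature importance, and two noisy-evaluation variants (trained on
  noisy data, or trained on the original and tested on noisy twins).

The core estimators are sklearn-compatible (`BandpassFilter`,
`SnrNoiseInjector`, `EggFeatureExtractor`, `NauseaForest`) and compose
with sklearn pipelines and model selection.

## Worked example

```python
from eggsense import PipelineConfig, run_all
from eggsense.classify import RfConfig

cfg = PipelineConfig(seed=1234, snr_targets_db=(20.0, -20.0),
                     rf=RfConfig(n_trees=128))
bundle = run_all(cfg)

table = bundle["original_table"]
print(len(table), int(table["nausea"].sum()))           # 68 12
print(bundle["achieved_snr"]["-20dB"]["per_record_mean_db"])

clf = bundle["classifier"]["noisy_train"]
for tag in ("original", "20dB", "-20dB"):
    r = clf[tag]
    print(tag, round(r.accuracy, 3), round(r.kappa, 3))
```

prints

```
68 12
-18.52
original 1.0 1.0
20dB 1.0 1.0
-20dB 0.824 0.0
```

Reading: the 17-subject synthetic cohort yields 68 labelled segments, 12
of them nausea-positive (prevalence 0.176). The achieved in-band SNR at
the −20 dB target is about −18.5 dB: the bandpass removes most of the
wideband noise but only part of the signal lies in band. The planted
nausea effect (higher frequency, higher amplitude, more jitter) is fully
separable on clean and mildly noisy data; at −20 dB the forest collapses
to majority-class behaviour (kappa 0) — degradation is worst at the most
negative SNRs.

The same experiment runs from the shell:

```bash
eggsense run-all --out results/ --seed 1234
eggsense synth-cohort --out rec/ --seed 3 --n-subjects 17
eggsense inject-noise --in rec/ --out noisy/ --snr -20 --snr 20 --seed 1
```

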