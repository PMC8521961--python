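# cardiosleep

Single-epoch sleep-wake classification from cardiorespiratory signals, with
total-sleep-time (TST) estimation and uncertainty-based screening for
obstructive sleep apnea (OSA).

Clinical sleep staging needs EEG and a sleep laboratory. Unobtrusive sensors
(ECG electrodes, a respiratory-effort belt) can be worn at home, but most
staging algorithms built on them need long stretches of clean signal —
exactly what movement-prone home recordings cannot guarantee. `cardiosleep`
implements a pipeline that classifies every 30 s epoch **independently** from
two channels only:

* **ECG** → per-epoch instantaneous-heart-rate (IHR) tachogram: R-peak
  detection per 30 s segment, 60/IBI in beats/min, PCHIP interpolation to a
  4 Hz / 120-sample grid, outlier rejection (40–180 bpm, median ± 20 bpm,
  median ± 3·SD), mirror-filling of gaps ≤ 10 samples, and subtraction of
  the subject's overall median;
* **RIP** (thoracic respiratory effort) → zero-phase Butterworth band-pass
  [0.04, 2] Hz, cubic-spline resampling to the same 120-sample grid, and a
  recording-level robust normalization;
* a **1D CNN** per modality ((f,k,s)-Conv/ReLU stacks into a dense head with
  50% dropout and a 2-class softmax, class 0 = Sleep, class 1 = Wake),
  trained with Adam on class-balanced batches of 16 non-sequential epochs;
  the trained convolutional branches are then **frozen** and fused into a
  multimodal network whose dense head is retrained.

On top of the per-epoch wake posterior p(Wake) the package derives:

* **TST** — 0.5 min per valid epoch predicted Sleep;
* **confidence thresholds** T_s / T_w — the median confidence of the
  sleep-/wake-predicted pool minus its SD — splitting predictions into
  *confident* and *uncertain*;
* **%USE / %UWE** — the share of valid epochs predicted sleep/wake with
  sub-threshold confidence — and **%SWT**, the share of valid epochs at
  which the predicted label flips;
* an **OSA screening rule**: a patient is flagged when %USE or %SWT strictly
  exceeds its threshold (thresholds selectable by ROC analysis at a
  specificity floor). The logic: a network trained only on low-AHI patients
  becomes *uncertain* on apneic sleep, because the sympathetic response to
  apneas resembles wakefulness, so prediction uncertainty itself indicates
  OSA severity.

Since clinical PSG recordings cannot be redistributed, the package ships a
first-class synthetic cohort generator (`cardiosleep.simulate`): Markov
hypnograms, an integrate-and-fire beat process with respiratory sinus
arrhythmia, stage-dependent breathing, apnea events with the wake-like
sympathetic response, and movement artifacts — everything needed to exercise
and test the full pipeline end to end.

## Worked example

Simulate a small cohort, train, and score a severe-OSA night:

```bash
cardiosleep simulate --out cohort --n-per-class 1 --epochs-per-night 120 --seed 3
cardiosleep train --manifest cohort/manifest.csv --seed 0 --out model.npz
cardiosleep predict --model model.npz --edf cohort/severe-00.edf \
    --hypnogram cohort/severe-00_hypnogram.csv --out post.csv
cardiosleep metrics --posteriors post.csv --t-s 0.81 --t-w 0.63 \
    --patient-id severe-00 --out summary.json
cardiosleep detect --summary summary.json
```

The train step prints the fit summary (the two unimodal networks are
trained first, then the frozen-branch fusion):

```
Sleep-wake classifier (multimodal CNN, frozen conv branches)
==============================================================
selected seed        : 0
parameters           : 58,018 total, 53,442 trainable (fused head)
candidates trained   : 1
```

and `predict`/`metrics` report, for this one (tiny, one-hour) night:

```
epoch kappa vs reference: 0.375
{
 "patient_id": "severe-00",
 "tst_min": 50.5,
 "pct_use": 9.166666666666666,
 "pct_uwe": 1.6666666666666667,
 "pct_swt": 19.166666666666668,
 "n_valid_epochs": 120, ...
}
OSA risk: negative
```

`kappa` is chance-corrected epoch agreement with the reference hypnogram;
`tst_min` the predicted total sleep time; `pct_use`/`pct_swt` the two
screening metrics compared against the thresholds (defaults 64% and 24%) by
`detect`. At this toy scale the classifier is weak; the library API
(`SleepWakeClassifier(...).fit(...)`, returning a `SleepWakeResults` with
`predict`, `kappa` and `summary`) is what the full-scale runs use.

## Layout

| module | contents |
| --- | --- |
| `cardiosleep.io` | EDF read (mne) / minimal EDF write, hypnogram & event tables, epoch grid, stage collapse |
| `cardiosleep.ecg` | R-peak detector, IHR epochs, outlier repair, subject centering |
| `cardiosleep.rip` | band-pass + resampling, recording normalization, discard propagation |
| `cardiosleep.dataset` | epoch datasets, AHI-based patient splits, balanced batches |
| `cardiosleep.nn` | numpy conv/dense/dropout layers, softmax cross-entropy, Adam |
| `cardiosleep.model` | network construction, training, frozen-branch fusion, selection; `SleepWakeClassifier`/`SleepWakeResults` |
| `cardiosleep.metrics` | TST, confidence thresholds, %USE/%UWE/%SWT, kappa, ROC, screening rule |
| `cardiosleep.simulate` | synthetic PSG cohort generator |
| `cardiosleep.cli` | `cardiosleep` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
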