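# Methods

This note documents the models, numerical choices and limitations behind
`cardiosleep`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## Problem setting

Sleep is scored clinically in 30 s epochs over five stages
(W, N1, N2, N3, REM). The package collapses these to a binary target
(class 0 = Sleep, class 1 = Wake) and classifies **each epoch on its own**
from two unobtrusive-capable channels: the ECG-derived instantaneous heart
rate (IHR) and thoracic respiratory effort (RIP). Single-epoch operation is
a deliberate constraint: home recordings from movement-sensitive sensors
rarely provide long clean stretches, so no temporal context beyond the
epoch is used, and every epoch can be dropped independently when its signal
quality is insufficient.

## Preprocessing

**Epoch grid.** Epoch *i* covers `[30·i, 30·(i+1))` seconds from recording
start (0-based, half-open); a trailing partial window is dropped. Both
channels must start at the same instant.

**ECG → IHR epochs.** R-peaks are detected per 30 s segment with a
Pan–Tompkins-style detector (5–15 Hz zero-phase band-pass, derivative,
squaring, 150 ms moving-window integration, adaptive floor at 0.2× the 98th
percentile, 250 ms refractory, refinement to the band-passed extremum
within ±100 ms). The detector sits behind `detect_r_peaks` so alternatives
can be swapped in. Segments with fewer than 15 beats are discarded. IHR at
beat *i* (i ≥ 1) is 60/IBI\_{i-1} in beats/min; the first beat repeats the
second's value. To avoid border artifacts, the first beat time is moved to
(t₂ − mean(IBI₂, IBI₃)) and the last symmetrically, then the series is
interpolated by a shape-preserving piecewise cubic (PCHIP) onto the 4 Hz
grid (120 samples); outside the shifted outermost beats the boundary value
is held constant, since cubic extrapolation could leave the observed rate
range. Outliers — outside 40–180 bpm, or beyond ±20 bpm or ±3·SD of the
epoch median — are flagged jointly in a single pass against the pre-flag
median/SD (population formula), so the rules are order-free and
reproducible bit for bit. Flagged runs of ≤ 10 samples (2.5 s) are repaired
by mirroring the preceding samples; longer runs, or runs without enough
preceding history (e.g. at the epoch start), invalidate the epoch. Finally
the subject's overall median (over all samples of all valid epochs) is
subtracted, removing between-subject level differences while keeping
between-stage structure.

**RIP epochs.** Each segment is band-pass filtered at [0.04, 2] Hz with a
4th-order Butterworth applied forward-backward (zero phase, preserving
breath timing relative to the tachogram) and resampled to 4 Hz by
cubic-spline evaluation. *Filter realization:* the 0.04 Hz edge settles
with a ~10 s time constant, and reflection padding of any length injects a
border kink whose spectrum reaches into the passband (a unit 3 Hz stopband
tone leaks at ≈0.5 amplitude under reflected pads). Each segment is
therefore extended per border by 60 s of autoregressive extrapolation
(Yule–Walker, order 24, with a constant-extension fallback for degenerate
fits) — a standard edge-effect mitigation — bringing the measured stopband
leak to ≈0.03 and the passband amplitude error below 1%. Normalization per
recording: subtract the median of per-epoch medians, divide by the median
of per-epoch SDs (statistics over **all** candidate epochs, robust to which
modality failed), then subtract each epoch's own median. Epochs whose
paired IHR epoch was discarded are discarded too, so the network always
sees pairs.

## Network and training

Per modality: `(8,7,2)-Conv → (16,5,2)-Conv → (32,3,2)-Conv` (ReLU
throughout) → flatten → `(64)-Dense` → 50% dropout → `Softmax(1,2)`;
~29k parameters per branch, all sizes config-exposed. The multimodal
network copies both trained convolutional stacks **with frozen weights**
and trains a fresh dense head on the concatenated features (58k total,
53k trainable). The engine is pure numpy (im2col convolutions, reverse-mode
gradients, inverted dropout, Adam with lr 1e-3, β₁ 0.9, β₂ 0.999); float64
throughout, and every random draw (init, dropout, batch sampling) descends
from one seed, so training is a pure function of (data, config, seed).

Batches hold 16 epochs, drawn class-balanced with replacement (each draw
picks a class with probability ½, then an epoch uniformly within it) and
independently of temporal order. One training pass covers the valid
training epochs once in expectation; after each pass the plain
cross-entropy on the validation patients is evaluated and the best-loss
weights are kept (defaults: at most 100 passes, patience 10; the end-to-end
tests and the acceptance script use 12 passes / patience 5, which the loss
curves show is past convergence at their cohort sizes). Cohorts are split
by patient: only low-AHI patients (AHI < 10) enter training, 70/30
train/validation per split seed; with several seeds, one fused network per
seed is trained and the one with the highest Cohen's kappa on a fixed test
set is selected (ties to the lowest seed). The selected kappa is a
model-selection score, not an unbiased generalization estimate — the
package logs a warning to that effect.

## Outcome metrics and screening

Wake iff p(Wake) ≥ 0.5 (equality to Wake). TST = 0.5 min × valid epochs
predicted Sleep; an extrapolated variant scaling by total/valid epochs is
reported alongside, clearly labelled, since discarded epochs have no
canonical TST attribution. Confidence thresholds are fitted on a reference
cohort, pooling epochs across subjects: T_w = median − SD of p(Wake) over
wake-predicted epochs, T_s likewise for p(Sleep) over sleep-predicted
epochs. %USE (%UWE) is the share of valid epochs predicted sleep (wake)
with confidence below T_s (T_w); %SWT counts label changes between
consecutive valid epochs (invalid epochs removed before pairing), divided
by the number of valid epochs. Screening: positive iff %USE or %SWT
**strictly** exceeds its threshold; thresholds are chosen by ROC analysis —
candidate thresholds are midpoints between sorted unique values, and among
those reaching the specificity floor (default 0.95) the most sensitive is
taken (ties to the most specific; if the floor is unreachable, the most
specific candidate is returned with a flag). Cohen's kappa and the
trapezoid AUROC are implemented in-package and verified against independent
reference implementations in the tests.

## Synthetic cohort generator

The generator produces what the pipeline assumes about real recordings,
with known ground truth:

* **Hypnogram**: first-order Markov chain over the five stages,
  `P = a·I + (1−a)·1πᵀ` with persistence a = 0.8 (mean dwell 2.5 min) and
  stationary π = (W 17, N1 4, N2 40, N3 22, REM 17)%, typical overnight
  proportions in a sleep-clinic population.
* **Beats**: integrate-and-fire on a stage-dependent rate — levels
  W 76 / REM 71 / N1 70 / N2 66 / N3 63 bpm with per-epoch wander
  (SD 8/6/5/4/3 bpm) deliberately comparable to the level gaps, per-beat
  jitter, and respiratory sinus arrhythmia whose depth grows with sleep
  depth (1.5→4 bpm) and follows the *actual* respiratory excursion. The
  ECG waveform is a QRS-like pulse train (Gaussian R wave, small side
  troughs, T wave) plus noise at 256 Hz.
* **Effort**: a non-sinusoidal oscillation at stage-dependent rate
  (13.3–15.0 breaths/min with per-epoch wander of 1 breath/min, so rate
  alone does not separate stages) and stage-dependent amplitude
  irregularity (wake and REM most irregular), at 32 Hz.
* **Apneas** (placed only during sleep, durations 15–40 s, non-overlapping,
  count Poisson with the configured events/hour): during the event,
  thoracic effort is irregular and reduced (×0.7 mean, +0.45 modulation —
  obstructive, paradoxical effort rather than a central flat-line), the
  rhythm slows ×0.85, RSA is suppressed proportionally; the event ends with
  large fast recovery breaths (×1.5, rate ×1.2, 10 s) and a sustained
  heart-rate surge (+14 bpm decaying over 20 s) after mild in-event
  bradycardia (−3 bpm). This implements the sympathetic wake-resemblance
  mechanism: apneic epochs move part-way toward the wake feature cluster,
  so a low-AHI-trained network predicts them with reduced confidence.
* **Artifacts**: Poisson-placed bursts (5–40 s) of either saturating noise
  or flat signal on both channels.
* **Severity classes**: none/mild/moderate/severe at 2/10/20/60 events/h.

Everything is deterministic under the seed; regeneration is bit-identical.

What the generator does **not** emulate: realistic ECG morphology (no
ectopy, no waveform pathology), SpO₂/airflow, stage-transition physiology
(arousals around events are not explicitly staged), inter-patient
heterogeneity of the apnea response, or scorer disagreement. Passing tests
therefore demonstrate that the pipeline's machinery — preprocessing rules,
training dynamics, uncertainty metrics, screening logic — behaves as
designed under its stated assumptions, not that clinical performance levels
would be reproduced on real patients.

## Problem sizes and calibration of the end-to-end checks

The end-to-end tests and the acceptance script train on ~20,160 epochs
(28 synthetic low-AHI patients × 6 h nights), select/evaluate on 6 held-out
low-AHI patients, and score a 40-patient severity cohort (10 per class,
4 h nights). At these sizes a full acceptance run takes a few minutes on
one CPU. The generator's stage overlap was calibrated so that the fused
classifier lands in a realistic accuracy regime (epoch kappa ≈ 0.6–0.8
rather than a near-perfect separation no cardiorespiratory classifier
attains in practice), which is what makes the confidence-based metrics
informative: with saturated posteriors, %USE and %SWT are degenerate.

## Numerical conventions

* Median over an even count = mean of the two central order statistics;
  SD uses the population formula (n divisor) everywhere.
* "Median zero" after centering/normalization holds to floating-point
  rounding (|median| < 1e-12), not bit-exactly.
* p(Wake) = 0.5 classifies as Wake; screening threshold equality is
  negative ("exceeds" is strict).
* The EDF writer quantizes to 16-bit over each channel's observed range;
  round-trips are exact to one quantization step.
* Degenerate inputs raise typed errors (`cardiosleep.errors`): empty
  recordings, all-constant effort, single-class batching pools, empty
  predicted classes when fitting confidence thresholds, constant vectors
  for Pearson correlation.

## Known limitations

* The R-peak detector is tuned for adult surface ECG at ≥100 Hz; very low
  SNR segments yield spurious beats that the outlier rules must catch.
* Confidence thresholds are fitted by pooling epochs across subjects; a
  per-subject-then-aggregate variant would weight patients equally and can
  differ when night lengths vary.
* TST ignores discarded epochs by default; the extrapolated variant assumes
  missingness is independent of sleep state.
* Model selection reuses the fixed test set for selection and reporting;
  an untouched holdout would be needed for unbiased accuracy claims.
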