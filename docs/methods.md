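# Methods

This note documents the models, parameters and numerical choices
implemented in `biofusion`, what the synthetic data generator does and does
not emulate, and the package's known limitations.  Any number quoted here
is either a fixed design parameter or is computed by the test suite /
acceptance script at runtime.

## 1. Problem setting

The package decodes the external load held during elbow
flexion–extension — three classes: 0, 3 or 5 lbs — from five channels
recorded at 4000 Hz:

- EEG: C3, C4, Cz (motor cortex; microvolt scale, stored in mV),
- EMG: biceps brachii, triceps brachii (millivolt scale).

Movements are performed at two speeds (long "slow" repetitions and short
"fast" ones), each speed × weight condition repeated three times.  Models
are subject-specific: trained, tuned and tested within one subject's
session.

## 2. Synthetic data generator

Real sessions are not shipped; `biofusion.synth.generate_recording`
produces surrogate recordings with the statistical structure the pipeline
needs.  Per repetition:

- **EMG** — band-limited (20–500 Hz) Gaussian noise, normalized to unit
  RMS, amplitude-modulated by raised-cosine activation envelopes: biceps
  active during the flexion half, triceps during the extension half, with
  a small rest floor (0.05).  Active amplitude scales as
  `1 + emg_gain_per_lb × weight` (default 0.15/lb) and a `speed_gain`
  factor (default 1.3) for fast repetitions.  Base scale 1 mV.
- **EEG** — a 1/f ("pink") background plus mu (8–12 Hz) and beta
  (13–30 Hz) oscillations with relative amplitudes 0.6/0.3/0.2.  During
  movement the oscillation amplitude drops as
  `sqrt(1 − eeg_erd_depth_per_lb × weight)`, a simple model of
  event-related desynchronization (default depth 0.05/lb).  Base scale
  0.01 mV, i.e. EMG is ~100× larger, as in practice.
- **Artifacts** — Poisson-distributed motion transients (default
  0.1/s): 0.4 s raised-cosine bumps of 5–10× channel amplitude.
- **Timing** — 0.5 s rest margins around the movement; start/end markers
  bracket the movement exactly.

Randomness is reproducible per `(seed, subject_id)`: each recording uses
`SeedSequence([seed, crc32(subject_id)])`, so subjects are independent
streams and any subject can be regenerated in isolation.

The generator aims only at plausible *relative* structure (amplitude
ratios, band powers, class separations); it does not emulate volume
conduction, electrode impedance drift, cross-talk between channels,
inter-subject anatomy, eye blinks, or realistic EEG topography.
Absolute accuracies obtained on it are properties of the generator, not
of any real population.

## 3. Preprocessing

- **Filtering** (`preprocess.filter_recording`) — zero-phase Butterworth
  filtering via `scipy.signal.sosfiltfilt`: EEG band-pass 0.5–40 Hz,
  order 3; EMG DC removal plus band-pass 20–500 Hz, order 4.  Because the
  filter is applied forward and backward, the realized magnitude response
  is |H(f)|²; the tests verify the realized 60 Hz attenuation on EEG
  against the analytic response (≈92% amplitude attenuation) rather than
  assuming the single-pass figure.
- **Segmentation** (`segment_movement`) — keep `[start, end)` samples at
  the markers.
- **Windowing** (`make_windows`) — 250 ms windows (1000 samples) with 50%
  overlap (step 500); a repetition of `n` samples yields
  `(n − 1000)//500 + 1` windows.  A 30 s repetition gives 239 windows, a
  2 s repetition 15.

## 4. Spectrogram images and fusion layouts

Each window/channel pair becomes a short-time Fourier magnitude image
(`imaging.spectrogram`):

- 56-sample periodic Hann window, 75% overlap (hop 14) → 68 time frames
  from 1000 samples;
- zero-padded DFT lengths 3200 (EEG, Δf = 1.25 Hz) and 256 (EMG,
  Δf = 15.625 Hz);
- frequency crop keeps bins 1..32 (DC dropped): 1.25–40 Hz for EEG and
  15.6–500 Hz for EMG — 32 bins for both modalities, so all channel
  images are 32 × 68;
- linear magnitude; the implementation multiplies tapered frames by an
  explicit DFT matrix restricted to the kept bins, which is
  mathematically identical to the zero-padded FFT (verified in tests)
  but avoids forming 3200-point transforms.

Note the 56-sample Hann window has a main-lobe width of roughly 143 Hz
at 4000 Hz sampling, so EEG-band features are *not* resolved as distinct
peaks; the EEG image encodes broadband low-frequency energy over time.
This is a property of the short-window design itself.

Images are min–max normalized to [0, 1] per subject and per modality
(EEG channels share one min/max, EMG channels another), so the 100×
EMG/EEG amplitude difference does not dominate the fused image.  By
default statistics are fitted over all of a subject's windows;
`fit_indices` restricts fitting to the training split.

Fusion layouts (`imaging.LAYOUTS`):

| layout | shape | arrangement |
|---|---|---|
| `grouped` | 160 × 68 | rows C3, C4, Cz, biceps, triceps (modalities grouped) |
| `mixed` | 160 × 68 | rows C3, biceps, C4, triceps, Cz (modalities interleaved) |
| `stacked` | 32 × 68 × 5 | channels along image depth |
| `eeg_stack` / `emg_stack` | 96 × 68 / 64 × 68 | single-modality vertical stacks |
| `eeg_multi` / `emg_multi` | 32 × 68 × 3 / × 2 | single-modality depth stacks |
| `signal_full` / `signal_eeg` / `signal_emg` | 5/3/2 × 1000 | normalized raw-signal images |

All spectrogram layouts contain the same pixels; only the arrangement —
and therefore what a convolution kernel can see jointly — differs.

## 5. Models and training engine

Three CNN families (`models.FAMILIES`), built on the package's own
NumPy training engine (`biofusion.nn`: im2col convolution, max pooling,
inverted dropout, dense layers, softmax cross-entropy, Adam):

- `spectro2d` — 3 × [k×k conv (valid, stride 1) → 2×2 max pool →
  dropout] → 2 × [dense → dropout] → dense softmax(3).  For
  single-channel layouts the kernel size is tuned in {3, 5} (third layer
  also 7); depth-stacked layouts fix 3×3 kernels.
- `split_conv` — for signal images: a 1×k temporal convolution followed
  by an H×1 spatial convolution across channels, 1×2 pooling, dropout,
  dense head.
- `conv1d` — three 1×k convolution + 1×2 pooling + dropout stages over
  the time axis (channels as depth), dense head.

Training protocol (fixed): Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7), batch
size 32, at most 50 epochs, early stopping on validation loss with
patience 5 and best-epoch weight restoration; float32 throughout.

Hyperparameter search (`models.tune`): random search, by default 50
configurations × 2 fits each, scored by the minimum validation loss over
the fits.  The search space (`SearchSpace`) covers kernel sizes as above,
1-D kernel widths 3..55 (odd), filter counts 8..1024 in powers of two
(≤512 for `split_conv`), dropout 0..0.5 in steps of 0.05, dense widths
20..500 in steps of 20 and a log-uniform Adam learning rate on
[1e-5, 1e-2].  Configurations whose shape arithmetic
(`propagate_shapes`) is infeasible for the input are resampled.
`SearchSpace.quick()`/`TrainSpec.quick()` provide a reduced budget
(5 trials × 1 fit, ≤15 epochs) for smoke-scale experiments.

## 6. Evaluation protocol and statistics

Per subject and model (`evaluation`):

- repetitions 0–1 of every trial are training data; repetition 2 is
  shuffled (seeded) and split 50/50 into validation and test, stratified
  by weight class (per-class counts differ by at most one);
- reported: overall and per-speed accuracy, the 3×3 confusion matrix
  (rows true, columns predicted), class-wise precision/recall/F (0/0
  defined as 0 and flagged), macro F.

Across subjects (`aggregate`): unweighted mean ± sample SD (ddof = 1) of
subject accuracies, plus metrics of the pooled (summed) confusion
matrix — pooling weights subjects by test-set size and is therefore not
identical to averaging per-subject scores.

Across models (`compare_models`): one-way repeated-measures ANOVA on the
subjects × models accuracy table, computed from textbook sums of squares
(F = MS_models/MS_error with df (k−1) and (k−1)(n−1); validated against
`pingouin` in the tests), followed by Bonferroni-adjusted pairwise paired
t-tests (raw p × number of comparisons, capped at 1).  Degenerate inputs
(zero error variance) are flagged rather than silently returning NaN.

## 7. Numerical choices

- Explicit cropped-DFT matrix instead of full zero-padded FFTs (identical
  output, far smaller intermediates).
- Convolution forward/backward via offset-sliced im2col and a single
  GEMM; pooling via a streaming maximum over pool offsets with uint8
  argmax storage (first occurrence wins ties).
- float32 end to end in the network; float64 in filters, statistics and
  the ANOVA.
- All stochastic stages (generation, shuffling, weight init, dropout,
  search) consume explicit seeds derived via `numpy.random.SeedSequence`,
  so every result in the test suite and acceptance script is exactly
  reproducible.

## 8. Limitations

- The training engine is CPU-only NumPy: correct and adequately fast for
  the image sizes used here, but not a replacement for a deep-learning
  framework at full search budgets (50 trials × 2 fits on 160×68 images
  is hours of CPU time).
- Synthetic data places an unknown ceiling/floor on attainable
  accuracies; results quantify the pipeline, not human neurophysiology.
- Normalization defaults to whole-session statistics (fit before the
  split); use `fit_indices` for strictly train-only normalization.
- The evaluation protocol holds out one repetition, so test windows come
  from the same session as training windows; no cross-session or
  cross-subject transfer is claimed.
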