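# Methods

## The screening problem and the calibration-interval design

The pipeline treats hypertension screening as a binary image-classification
problem. A subject's systolic blood pressure (SBP) is defined as the mean of
the systolic peaks of an invasive arterial blood pressure (ABP) recording;
SBP > 130 mmHg defines the hypertensive (HTS) class, SBP ≤ 130 mmHg the
normotensive (NTS) class (the boundary value itself is assigned to NTS; the
threshold is a parameter of `assign_label`). The classifier, however, never
sees the ABP channel: it sees time–frequency images of the
photoplethysmogram (PPG), so whatever it learns must come from pulse
morphology.

The design question is not only *whether* PPG morphology carries class
information but *for how long* a labeled measurement stays informative.
Each interval bin (<1 h, 1–6 h, 6–24 h, >24 h) selects, per subject, a
chronological chain of recordings whose consecutive gaps fall in the bin;
odd chain positions act as calibration (training) measurements and even
positions are validated, so each validated recording is bracketed by
calibration measurements roughly one bin-width away. Images of subjects
with no qualifying chain augment the training set only — they can teach
the network about morphology in general but cannot leak validation
subjects' held-out data.

## Synthetic cohort model

Real ICU waveform collections cannot be redistributed, so the package
ships a generator whose defaults emulate the cohort structure the analysis
assumes: 69 subjects (45 NTS, 24 HTS) contributing 974 recordings of 120 s
at 125 Hz on a multi-day schedule (`study_cohort_config`).

Each beat is a sum of positive Gaussian lobes: a systolic peak (width
`w_sys`), a reflected wave (fraction `r_refl`, delay `d_refl`) and a
dicrotic component (amplitude `a_dicr`). Shape parameters vary linearly in
a dimensionless coordinate m that maps SBP from mid-normotensive
(112.5 mmHg → m = 0) to mid-hypertensive (150 mmHg → m = 1): hypertensive
morphology has a larger reflected-wave fraction (+0.45·m), a broader
systolic peak (+0.04 s·m) and a damped dicrotic wave (−0.18·m), the
standard qualitative picture of arterial stiffening. `morphology_effect`
scales these class-dependent terms; 0 makes the classes
morphologically identical. Realism terms: per-subject parameter jitter,
beat-to-beat heart-rate jitter N(0, (2 bpm)²) and multiplicative amplitude
jitter N(1, 0.02²), and additive waveform noise (`noise_sd`, default 0.02,
as a fraction of pulse amplitude for PPG and of pulse pressure for ABP).

ABP carries the labels, so each beat is rescaled so its *sampled* maximum
equals the beat's target SBP exactly — peak placement between grid points
can therefore never bias the label. PPG is zero-mean in arbitrary units;
amplitude information is additionally destroyed downstream by per-image
normalization, so classification rests on shape alone.

Two drift mechanisms, both off by default, model non-stationary subjects:
a linear SBP drift (`drift_mmHg_per_hour`, sign drawn per subject) which
moves morphology through the m-mapping, and a Brownian drift of m itself
(`shape_drift_per_sqrt_hour`) which changes morphology without moving the
label. The packaged drifting cohort (`drifting_cohort_config`) uses
0.25 mmHg/h and 0.2/√h over a 90-hour, 9-recording schedule whose gaps
populate all four bins, with SBP ranges pulled 10 mmHg back from the
threshold so drift rarely flips labels (subjects whose labels do flip are
removed by the exclusion rule, as designed).

What the generator does **not** model: validated hemodynamics, arrhythmia,
motion artifacts, sensor-contact variation, demographic covariates, or
inter-device differences. Passing tests on this cohort show the pipeline's
machinery is correct and that the design detects morphology drift; they do
not certify clinical performance on real PPG.

## Preprocessing

SBP peak detection uses local maxima with a 0.33 s refractory distance
(≤180 bpm) and ≥10 mmHg prominence. "Significant fluctuation" is
operationalized as *any* mixed NTS/HTS labels across a subject's
recordings; such subjects are excluded entirely.

The PPG filter is a Chebyshev type-II band-pass designed with order 4 and
stopband edges 0.5 and 10 Hz (40 dB attenuation), realized as second-order
sections and applied zero-phase (`sosfiltfilt`), so waveform features are
not phase-distorted before imaging. Note that with stopband edges at
0.5/10 Hz the transition band shades the upper passband (≈0.84 power gain
at 5 Hz after the forward–backward pass); tests pin the realized response,
not an idealized flat passband. Filtering happens at 125 Hz before
decimation; downsampling to 25 Hz is then plain 5:1 sample selection,
alias-free because the signal is already band-limited below the 12.5 Hz
Nyquist. Recordings are segmented into 10-s windows (12 per 120-s
recording); a sub-multiple remainder is dropped with a warning.

## Scalograms

The analytic generalized Morse wavelet is implemented in the frequency
domain, ψ̂(ω) = 2·(ω/ω_p)^β·exp((β/γ)(1 − (ω/ω_p)^γ)) for ω > 0, with
γ = 3 and β = P²/γ = 20 (time–bandwidth P² = 60), peak-normalized so a
unit-amplitude sinusoid yields magnitude ≈1 at the matching scale. Scales
are geometric at 12 voices per octave from f_min = 2/T (0.2 Hz for a 10-s
window — below this, fewer than two cycles fit) to the Nyquist 12.5 Hz.
The signal is symmetrically extended by half its length per side before
the FFT-domain transform.

The cone of influence is the region within C/f seconds of either edge at
frequency f, where C is the one-sided e-folding time of the mother
wavelet's envelope measured numerically (in periods of the peak
frequency). Rendering: magnitudes are min–max normalized per image
(rendering is therefore amplitude-invariant — asserted by test), mapped
through viridis (configurable; log scaling off by default), bilinearly
resized to 224 × 224 RGB with high frequencies at the top, and the COI is
overdrawn afterwards as a one-pixel pure-white trace per column so it
survives resizing exactly. Outside-COI regions are marked, not masked.
No axes or margins are ever rendered.

## Classifier

Training follows the fine-tuning recipe: a 2-class fully-connected +
softmax head, Adam with initial learning rate 1e-4, batch size 128, at
most 20 epochs, validation once per epoch (= every ⌊n_train/batch⌋
iterations), early stopping on validation loss with patience 3 and
best-weights restoration. Prediction ties break toward NTS. No data
augmentation is applied.

Two backbones implement this contract. The torchvision backbones
(GoogLeNet, ResNet-18/50, optional `cnn` extra) fine-tune all layers by
default with a `freeze_features` flag. The `tiny-test-cnn` is a scratch
numpy network sized for CPU desk scale: inputs are average-pooled 8× to
28 × 28 × 3 and per-batch standardized, then one 3 × 3 convolution with 8
filters → ReLU → 2 × 2 max-pool → 32-unit hidden layer → softmax.
`desk_scale_config` pairs it with batch 32 and learning rate 1e-3, the
conventional scratch-training rate (1e-4 suits fine-tuning of pretrained
weights). All arithmetic is plain numpy, so fixed seeds give bit-identical
runs on any machine.

## Evaluation

Metrics are computed per image (10-s sub-segment) with HTS positive. F1 is
the count form 2TP/(2TP+FP+FN) — the harmonic mean of precision and
recall; the "harmonic mean of Se and Acc" variant seen in some clinical
reports is internally inconsistent with the count form and is reported
only as the auxiliary field `f1_se_acc_harmonic`. Zero-denominator metrics
are reported as NaN with a warning. Bins with no qualifying subject are
reported as skipped, not errors.

## Problem sizes

Integration tests and the analysis drivers run deliberately small
configurations chosen to exercise every code path while keeping a laptop
CPU run comfortable: 20-subject drift-free cohorts (4 recordings each,
30 min apart) for parameter recovery, 12-subject drifting cohorts
(9 recordings over 90 h, ≤ ~290 validation images per bin) for the
interval trend, and three seeds per stochastic claim. The study-shaped
69-subject/974-recording cohort is used where only generation and
preprocessing are involved (counts and labeling), since no training is
needed to check exact accounting.

## Known limitations

- The tiny CNN's per-batch input standardization means single-image and
  batched predictions can differ minutely; evaluation always batches.
- The chain-selection rule (longest chain, skipping allowed, earliest
  start on ties) is one defensible reading of "segments spaced at each
  interval"; alternatives (greedy first-fit, no skipping) would change
  split accounting at the margin.
- With an even-length chain the final validation recording has only one
  flanking calibration measurement; accepted, since train/val counts are
  not forced equal.
- The generator's class separation is by construction recoverable from
  beat morphology (a nearest-centroid oracle on beat-averaged pulses
  exceeds 0.9 accuracy); real-cohort difficulty — prehypertensive
  borderline subjects, artifacts, device variation — is out of scope.
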