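# Methods

This note records the models, parameter choices and numerical conventions
behind `fnirsflow`, and what the synthetic validation does and does not
establish.

## Paradigm model

A session is an ordered list of sections; a section is an initial rest
followed by trials of `notification → video → rating → rest`. Defaults are
2 s / {15, 30, 60} s / 5 s / 30 s, an initial rest of 120 s, and two
sections of six videos (two passes over the 15/30/60 s sequence), giving 12
trials and 1,104 s in total; one three-trial duration block spans 216 s
(52 + 67 + 97 s). Sample indexing is 0-based with half-open windows and
onset sample `floor(onset_s × fs)` — unambiguous and round-trip safe.

Two epoch-length conventions are supported. The natural one is
`floor(duration × fs)` samples (234 at 15.625 Hz for a 15 s video). The
`table3` preset instead fixes 208 / 416 / 832 samples for 15 / 30 / 60 s
epochs by truncation from video onset; it exists to reproduce a published
layer-size table whose 15 s input length (208) is shorter than the full
phase. Both are configuration, not inference.

Preference labels are supplied per trial in the input metadata (they
originate from a rating phase the toolkit does not model); a tertile
threshold helper converts continuous ratings when needed. The synthetic
default assigns balanced labels rotated across three-trial blocks so that no
class coincides with a single video duration — otherwise the decoder's task
would confound preference with stimulus length.

## Hemodynamic conversion and preprocessing

MBLL is applied per channel and sample by exactly solving the 2×2 system
over the two wavelengths. The four extinction coefficients (690 nm: 0.95,
4.93; 830 nm: 2.135, 1.791 μM⁻¹cm⁻¹) are assigned to chromophores by the
hemoglobin spectra: deoxy-hemoglobin dominates at 690 nm, oxy- at 830 nm.
The differential path factor defaults to 6.0 at both wavelengths — a common
adult-forehead value — and is configurable per wavelength, since it scales
concentrations linearly. The optical-density baseline defaults to the
whole-recording mean intensity and should be pointed at a rest window in
practice; the choice shifts each channel by a constant, which the detrending
stage removes anyway.

Filtering is a 4th-order Butterworth low-pass at 0.15 Hz applied
forward–backward (zero phase). Offline analysis does not need causality,
and zero-phase application avoids lagging trial onsets; the effective
magnitude response is the square of the single-pass design, which is what
the tests characterize (half-power at the cutoff; ≈ −58 dB at the 0.8 Hz
cardiac line). Filtering acts on concentration series by default; filtering
OD before conversion is equivalent up to the linear MBLL and available in
the pipeline configuration.

Detrending is per-channel linear least squares (idempotent projection;
leaves zero mean and zero best-fit slope). A discrete-cosine drift basis
(components below 1/128 Hz by default) is available as an alternative for
slow non-linear drifts.

## Synthetic generator

Each video trial contributes `amplitude(label) × (boxcar ⊗ HRF)` to the
active channels, with the per-trial regressor rescaled to unit peak so the
class amplitude *is* the peak ΔHbO in μM. The HRF is the SPM-style
double-gamma (peak delay 6 s, undershoot delay 16 s, dispersions 1 s, peak:
undershoot 6:1), sampled on the acquisition grid and normalized to unit
peak. Class amplitudes default to 1.0 / 0.5 / 0.1 μM for like / so-so /
dislike — a deliberately well-separated "high/mid/low activation" regime —
on channels 1–6. Noise is the sum of fixed-frequency sinusoids with uniform
random phases (0.03, 0.2, 0.8 Hz; 0.05 μM amplitude each), white noise
(sd 0.05 μM) and a linear drift (2×10⁻⁴ μM/s). ΔHbR mirrors the activation
with negative proportionality r = 1/3 and carries its own r-scaled noise.
All randomness flows from the single config seed.

What this emulates: the additive boxcar⊗HRF activation structure, the named
physiological noise lines, drift, and HbO/HbR anticorrelation. What it does
not: motion artifacts, non-stationary noise, inter-subject anatomical and
SNR variability, serial dependence beyond the low-pass band, and any
realistic effect size — the class amplitudes are not estimates of a real
study's SNR. Passing the validation therefore demonstrates that the
pipeline recovers structure it is designed for when that structure is
present; it says nothing about accuracy attainable on recorded data.

## Decoder

Samples are M×24 matrices (12 ΔHbO columns then 12 ΔHbR). Convolution is
1-D along time, kernel height 3, zero same-padding (so the time length is
preserved), followed by ReLU, non-overlapping max-pooling of 2 (odd
trailing sample dropped) and dropout 0.5; after the final block the
features are flattened into fully connected layers of 52 and 26 units and a
softmax output. Weights are He-initialized (normal, sd √(2/fan-in)) from an
explicit seed.

Column accounting has two modes. In `standard` mode a conv layer with f
filters outputs f columns — the conventional reading. `compat_table3` mode
reproduces a published shape table in which every conv layer outputs 12
columns regardless of its stated 8 filters: the first layer becomes a
grouped convolution over each channel's (ΔHbO, ΔHbR) pair (12 groups, one
output each) and later layers map 12 → 12. Both modes are first-class; the
printed-arithmetic checks use compat mode, everything else defaults to
standard.

Training minimizes categorical cross-entropy with Adam (β₁ = 0.9,
β₂ = 0.999, ε = 10⁻⁸; β₂ = 0.1 is selectable for faithfulness to a source
that prints it, though it cripples second-moment smoothing and is not the
default). Batches are reshuffled every epoch from the training seed;
dropout is active only during training; argmax ties at prediction resolve
to the lowest class index in the canonical order (dislike, so-so, like).
Given a seed and single-threaded BLAS, training is bit-reproducible; with
threading only statistical equivalence is guaranteed. The implementation is
pure numpy (im2col convolution with explicit backprop); the networks are
small enough that this is fast, and it keeps every operator identical to
the brute-force oracles the tests compare against.

Because 12 trials are far too few samples to train on directly, sliding
sub-windows of the video phase are used as samples (`augment_windows`),
each inheriting its trial's label and trial index. Windows never cross
trial boundaries, and the trial index is the cross-validation grouping key,
so augmentation cannot leak between folds. The per-trial cap balances
classes when durations differ.

## Evaluation

Accuracy is the fraction of correctly identified samples over all classes,
×100. Folds partition *trials* (grouped), stratified by label, shuffled by
seed and dealt round-robin, so fold sizes differ by at most one trial and
every window of a trial shares its fold. With 12 trials and k = 8, four
folds necessarily hold a single trial, and some test folds contain one
class only; these folds are scored (with a warning) rather than silently
dropped. Per-fold training re-seeds as `seed + fold`. Normalization
(per-column z-score) is fit on training folds only. Pairwise classification
filters to the two classes and rebuilds the output layer with two nodes.

## Activation maps and feature projection

The design regressor is the video boxcar convolved with the canonical HRF,
unit peak. Per channel, ΔHbO is robustly regressed on it (IRLS, Tukey
bisquare, tuning constant 4.685, intercept, tolerance 10⁻⁸, 50 iterations —
the conventional robust-fit defaults, via statsmodels RLM) and
t = β/se(β); a channel is active when t exceeds the one-tailed Student
quantile at α = 0.05 (configurable) with df = N−1. Zero-residual fits are
reported as t = ±∞ with an `exact_fit` flag instead of a spurious finite
value. Note the per-channel test is uncorrected: with 12 channels, about
one false positive per two maps is expected at α = 0.05 even under perfect
calibration, and low-pass-filtered physiological noise is autocorrelated,
which inflates the per-channel rate further. The calibration benchmark
therefore checks the null rate on white noise (where the nominal level
applies) and checks *detection* of injected channels on the full noise
model.

Features for visualization are the flattened post-pooling activations
(dropout off) — the last stage that is still "convolutional features" —
projected by PCA onto two components (scikit-learn, full SVD).

## Validation problem sizes

The benchmark module fixes the sizes used by the test suite and the
acceptance script: decoding recovery uses the 12-trial session, 128-sample
windows (≈ 8.2 s), 20 windows per trial (80 per class), the one-conv-layer
variant and 50 epochs, 3 seeded replicates; the chance control permutes
labels across windows (under the null, labels are exchangeable across
windows, so per-window fold groups are valid — trial-level permutation with
only 12 trials would leave the control dominated by permutation-overlap
variance) with 6 windows per trial, 15 epochs and 10 runs; t-map
calibration uses 500 white-noise replicates of 200 samples, and detection
uses 50 one-section sessions with channels 1–3 driven at 1.0 μM. These
sizes keep a full validation pass within a few minutes on one CPU while
leaving all statistical margins wide.

## Known limitations

- The CNN is CPU-only numpy; it is meant for 10²–10³ small samples, not
  large-scale training.
- SNIRF support covers the format's required fields and this toolkit's two
  payload types (CW intensity, processed Hb); it is not a general SNIRF
  implementation.
- The t-map is uncorrected for multiple comparisons across channels by
  design (the per-channel rule is the contract); users who need family-wise
  control should lower α or correct externally.
- Input lengths for 30/60 s epochs under the printed-shape preset follow
  the 208-sample convention proportionally (416/832); the source table
  covers only the 15 s case.
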