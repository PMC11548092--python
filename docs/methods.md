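# Methods

This note records the models implemented in `semgrec`, the assumptions behind
the synthetic benchmark, and the numerical and design choices that were
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The recognition problem

Four cyclic lower-limb movements — walking, stair ascent, stair descent,
squatting (class codes 0–3) — are to be recognised from 7-channel surface EMG
(rectus femoris, vastus lateralis, vastus medialis, semitendinosus, tibialis
anterior, lateral and medial gastrocnemius) sampled at 1 kHz. The unit of
classification is a 7 × 1024 window cut from an annotated action cycle (2 s,
or 3 s for squats) by a 1024 ms sliding window with 512 ms step.

## Synthetic signal model

No public dataset exists for this recording setup, so the generator *is* the
data contract. Per channel

```
x(t) = e_c(t) · n_B(t) + a_p sin(2π·50·t + φ) + g(t) + ε(t)
```

* `n_B` — zero-mean Gaussian noise, zero-phase band-passed to 20–450 Hz (the
  conventional sEMG bandwidth) and normalised to unit RMS. Surface EMG is
  well described as amplitude-modulated filtered noise; this is the standard
  phenomenological model, not a motor-unit simulation.
* `e_c` — per class and muscle, a raised-cosine burst parameterised by
  (onset fraction, duration fraction, scale) plus a resting tone of
  0.1 × scale. The default table gives each movement a loosely gait-like and,
  more importantly, pairwise-distinct activation pattern. A single knob,
  `envelope_contrast ∈ [0, 1]`, interpolates every class's table toward the
  cross-class mean: at 0 the classes coincide in expectation (no class
  information), at 1 (default) they are well separated.
* powerline: amplitude 0.1 at 50 Hz, random phase per channel.
* `g` — ECG-like artifact: a 1.2 Hz train of Gaussian pulses (σ = 15 ms,
  amplitude 0.15), common to all channels. It exists to exercise the 30 Hz
  high-pass edge, with no morphological realism.
* `ε` — white noise, σ = 0.05.

Defaults were chosen once as plausible contamination levels relative to a
unit-RMS carrier and are not tuned to any test outcome. Cycle onsets are
emitted as metadata (real onset detection is out of scope). Per-class
sub-seeds derive from the spec seed via `SeedSequence(seed, spawn_key)`, so a
dataset is reproducible as a whole and bit-identical under a fixed seed.

What a green end-to-end test establishes: that the pipeline and optimisers
recover class structure that is present by construction. It does *not*
establish real-world accuracy — there is no inter-subject variability,
electrode-shift effect, fatigue drift, or class overlap unless dialled in.

## Denoising chain

Per channel, in fixed order: 4th-order Butterworth bandpass 30–300 Hz →
50 Hz IIR notch → db2 wavelet threshold denoising.

* Both IIR stages run forward–backward (zero phase) to preserve burst timing;
  the effective magnitude response is the squared single-pass response. The
  test oracles evaluate |H(f)|² directly from the filter coefficients.
* Notch Q = 30 (≈1.7 Hz −3 dB width): narrow enough to spare the 30–300 Hz
  band; the value is a package choice.
* Wavelet stage: 4-level decomposition with the orthonormal 4-tap db2 filter
  pair (implemented in `semgrec.wavelet`; no wavelet library is required),
  soft thresholding of all detail levels with the universal threshold
  σ√(2 ln N), σ = median|d₁|/0.6745 from the finest details.
* Boundary handling is **periodized**, not symmetric extension: periodization
  keeps the transform exactly orthonormal (verified to machine precision),
  which is what makes "soft thresholding never increases energy" a theorem
  rather than an approximation. Odd-length levels are padded by repeating the
  last sample and trimmed on reconstruction.
* A deliberate consequence of universal thresholding: a *pure-noise* input
  loses nearly all detail-band energy while the level-4 approximation band
  (≲31 Hz) passes untouched, so out-of-band suppression ratios are only
  meaningful for the linear stages — the suite tests them there.
* The literature places useful sEMG content at 5–200 Hz, yet the stated
  chain filters 30–300 Hz; the stated chain is implemented as written.

## Features

Per window and channel: MAV, RMS, and MPF/MF from a Welch PSD (256-sample
Hamming segments, 50 % overlap — the field-standard estimator for 1024-sample
EMG windows). MF uses the left-continuous discrete rule: the smallest grid
frequency whose cumulative trapezoidal power reaches half the total.
Normalization is a per-column z-score fitted on training rows only (avoiding
test leakage); whether the original normalization was min–max or z-score is
unknowable from the published description, so the conservative choice is
documented here. Column order is fixed channel-major
(`ch1_mav, ch1_rms, ch1_mpf, ch1_mf, ch2_mav, …`) so serialized matrices are
portable.

## Classifiers

All deep models are numpy implementations with manual backpropagation
(`semgrec.nn`), gradient-checked against central differences to <1e-5
relative error in the test suite.

**CNN.** Three blocks of [conv k=3, stride 1, no padding → batch norm → ReLU
→ max-pool 2 (floor)] with 64/32/10 channels: per-channel lengths
1024 → 1022 → 511 → 509 → 254 → 252 → 126, flattened size 10 × 126 = 1260.
The published parameter table prints 1020/510/508 for the early conv outputs,
which is inconsistent with kernel 3 on 1024; kernel 3 / no padding is kept
because every printed shape from the second pooling onward (254, 252, 126,
1260) is then reproduced exactly. Fully connected layers 1260 → 600 → 100 → 4
("three FC layers"), ReLU after the first two, dropout 0.5 (unstated; the
conventional default) after each of the first two.

**Batch norm semantics.** Training uses batch statistics and updates running
averages (momentum 0.1); inference applies the running averages — a
deterministic affine map. Whether the original work froze batch statistics
differently at test time is unstated.

**LSTM.** Three layers, 100 hidden units, standard forget/input/output gate
equations. Two deviations from the nominal design, both measured during
development and ledgered:

* *Forget-gate bias init = 1* on top of fan-in uniform init. Without it the
  stacked LSTM sits in the majority class for tens of epochs under Adadelta;
  with it the hybrid models converge within the 30-epoch benchmark. This is
  the standard LSTM initialisation trick.
* *Input framing.* Reading the 7 × 1024 window as a 1024-step sequence of
  7-dim raw samples (the nominal convention, available via
  `LSTMSpec(frame_len=1)`) is both ~16× slower and unlearnable at desk
  scale: each step's input is zero-mean carrier noise, so the envelope —
  the only class signal — is invisible to the gates, and training never
  left chance in 15 epochs. The default frames the window into 64 steps of
  7 × 16 = 112 raw samples (`frame_len=16`), retaining all data and no
  hand-crafted features.

**Transformer encoder.** Sinusoidal positional encoding
(PE[pos, 2i] = sin(pos/10000^{2i/d}), odd columns cos), multi-head scaled
dot-product self-attention, post-norm residual blocks with a ReLU
feed-forward layer. Hyperparameters are unstated in the source design;
defaults are n_layers = 2, n_heads = 2, d_model = 10, ff_dim = 64, all
configurable.

**Hybrids.** CNN conv stack → FC(1260→600) → FC(600→100) → reshape of the
100-dim representation into a 10 × 10 sequence → Transformer and/or LSTM →
FC head to 4 classes. The 10 × 10 factorisation is a documented choice (the
original reshape is unspecified); `FusionSpec` enforces
seq_len × d_model = 100. CNN-Transformer flattens the encoded sequence into
the head; CNN-LSTM and CNN-TL use the LSTM's final hidden state.

**SVM baseline.** Four one-vs-all binary RBF SVMs (C = 1, γ = 0.1) on the
normalized 28-dim features; labels by maximal decision value;
probability-like scores for ROC by a softmax over the four decision values.

**Optimisation.** Cross-entropy loss; Adadelta with ρ = 0.9, ε = 1e-6 and
step scale `lr`. The nominal configuration lists both "Adadelta" and
"learning rate 0.001", which are mutually inconsistent: with a 1e-3 step
scale Adadelta's updates are ~10⁻³ × √ε-scale and no model trains within
hundreds of epochs. The default is the canonical lr = 1.0 (as in
`torch.optim.Adadelta`); 0.001 remains settable. Batch size 40; the full
published schedule is 300 epochs, the desk-scale benchmark uses 30.

## Evaluation

Confusion matrix with rows = true class; accuracy = trace/total; per class
one-vs-rest TP/TN/FP/FN with precision, recall and F1, macro-averaged
(the reduction used for the single headline numbers is unstated in the
source; macro is the documented choice and per-class values are always
emitted). A class with no predicted positives gets precision 0 with a
warning. ROC: per-class one-vs-rest staircases over all unique score
thresholds (ties grouped), AUC by trapezoid, mean curve by vertical averaging
on a 101-point FPR grid, mean AUC as the unweighted mean of per-class AUCs.
One caveat verified numerically: macro *recall* is invariant to duplicating a
class's samples, but macro *precision* is not (extra false positives land in
other columns), so only the recall invariance is asserted.

## Benchmark and scaling

`default_benchmark_config` is the stated desk-scale world: high envelope
contrast, 60 two-second cycles per class and **30** squat cycles — squat's
3 s cycles yield 4 windows each versus 2, so halving its cycle count keeps
the window counts balanced (mirroring the near-equal screened class counts of
the motivating experiment and making 4-class chance 0.25) — 80/20 stratified
window-level split, 30 epochs. Window-level splitting places overlapping
windows of one cycle on both sides of the split and can flatter accuracy;
with no subject structure in synthetic data, subject-wise splitting is not
implementable, and the caveat stands.

The acceptance tests run this world at reduced scale to fit a single-CPU
time budget (40 cycles / 3 seeds for the CNN-TL median; each remaining model
once at the scale where its convergence was measured; thresholds unchanged).
End-to-end determinism — identical seeds reproduce metric files bit for bit —
is asserted on a small configuration.

## Known limitations

* The synthetic world has no subject variability; accuracies near 100 % on
  it say nothing about inter-subject generalisation.
* The published headline accuracies (e.g. 96.13 % for CNN-TL on 20-subject
  data) are context, not reproduction targets: the underlying recordings are
  not deposited.
* The screening rule behind the published per-class sample counts is
  unstated; the package's RMS-floor + finite-value screen is an invention
  and is off by default.
* Pure-LSTM training on raw sample-rate sequences (frame_len = 1) is
  supported but impractically slow and data-hungry; see above.
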