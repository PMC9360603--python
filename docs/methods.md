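# Methods

This note documents the models, numerical choices and study conditions
implemented in `cossvep`, in the spirit of a methods appendix: what is
computed, under which assumptions, and what the synthetic experiments
do and do not demonstrate.

## Signal model (synthetic SSVEP generator)

A trial of class *i* (stimulation frequency `f_i`, phase `φ_i`) on
channel *c* is

    x_c(t) = g_c · Σ_{h=1..H} (a/h) · sin(2π h f_i (t − τ) + h φ_i) + n_c(t)

with `H = 3` harmonics, amplitude decay `1/h` and phase progression
`h·φ` (the standard quasi-sinusoidal SSVEP approximation), channel gains
`g = (0.9, 1.0, 0.9)` for (O1, Oz, O2) — Oz dominant, a documented
default rather than an empirical claim — and per-subject amplitude
scale `a` and response latency `τ`.

The paradigm constants are fixed: four targets at 8.6/10/12/15 Hz with
phases 1.35π/0.35π/0.9π/0.35π, 256 Hz sampling, 4 s stimulation.

**Noise.** `n_c` mixes pink (1/f, spectrally shaped white noise, DC
removed) and white Gaussian components; `pink_fraction = 0.7` of the
noise power is pink, reflecting the predominantly 1/f EEG background.
Noise is drawn independently per channel and scaled so that evoked
power / noise power equals the configured SNR exactly per channel.
`estimate_snr_db` measures SNR by least-squares projection onto the
harmonic sine/cosine subspace (6 regressors out of ~1000 samples, so
the noise absorbed into the fit is negligible).

**SNR defaults.** The generator default is −6 dB broadband — a
realistic single-trial figure at which the band-limited spectrum still
shows a clear peak. Two named study conditions are used by the canned
experiments: *high SNR* (+15…+20 dB), where classification saturates
and structural/protocol properties are tested, and *moderate SNR*
(−18 dB, `experiments.MODERATE_SNR_DB`), chosen so that single-person
accuracy spans the mid-range (~60–90 %) across the window sweep — the
regime in which multi-subject collaboration has measurable headroom.

**Inter-subject variability** is limited to amplitude scale
(log-normal, σ = 0.2), SNR offset (normal, σ = 2 dB) and latency jitter
(uniform 0–30 ms) — the minimal model producing distinct individual
differences. No forward-model head geometry, no ocular/muscular
artifacts, no within-session nonstationarity: trials are exchangeable
given the subject.

**Group simulation** enforces the collaborative-gaze assumption: all
subjects share one shuffled, class-balanced stimulus schedule, so trial
k carries the same label for everyone. All randomness flows through
`numpy` seed sequences keyed by (seed, subject, trial); identical
inputs are bit-identical.

## Feature extraction

Filter → window → FFT → band → normalize, per trial:

* zero-phase (forward–backward) 4th-order Butterworth band-pass,
  5–40 Hz, second-order sections. Zero-phase application squares the
  magnitude response and avoids latency distortion; causality is an
  offline-analysis choice.
* onset-anchored analysis window of `round(w · fs)` samples,
  `w ∈ {3.0, 2.8, …, 1.6}` s in the standard sweep.
* per-channel `|rfft|` with no taper and no zero padding, so the bin
  spacing is exactly `1/w` Hz.
* band selection `6 ≤ f < 32` Hz, half-open by convention: with a 3 s
  window (Δf = 1/3 Hz) this retains exactly 78 bins; a closed interval
  would retain 79. (Including 32 Hz while excluding 6 Hz would also give
  78; the half-open-low convention is the documented choice.) Shorter
  windows give whatever the selection yields (2 s → 52, 1.6 s → 42);
  networks are parameterized by the bin count B rather than fixed at 78.
* per-channel, per-epoch min–max normalization to [0, 1]; a constant
  channel maps to zeros to keep outputs bounded.

## Feature fusion

Fusion consumes *normalized* features of subjects who shared the
stimulus (alignment is checked label-by-label and errors name the
offending trial index). Member order is the caller's subject order and
is recorded. Parallel stacking (3K × B) and serial concatenation
(3 × KB) only relocate values; averaging (3 × B) is the only operator
creating new ones, and is consumable by the unmodified single-person
network. Averaging magnitude spectra does not lower the mean background
level — it shrinks background *fluctuations* — so its benefit is
measured as peak prominence (z-score against background bins), the
standard SSVEP spectral-SNR measure.

## Network family

All convolutions are followed by batch normalization then ReLU (the
conventional conv→BN→ReLU order; the placement is otherwise a free
choice), use bias terms, and pad with zeros symmetrically when a layer
"preserves" its axis (for even kernels the extra zero goes after). The
shared head is flatten → dense 8 (linear) → dropout 0.5 → dense 4 →
softmax.

* **single** (3 × B): conv 16×(3,1) preserve → 32×(3,1) valid →
  32×(1,3) preserve → 64×(1,3) valid. Trace for B = 78:
  (3,78)→(3,78)→(1,78)→(1,78)→(1,76); flatten length 4864.
* **parallel, K = 2** (6 × B): 16×(6,1) preserve → 32×(3,1) valid →
  64×(3,1) valid → 64×(2,1) valid → 128×(1,3) preserve → 256×(1,3)
  valid; channel trace 6→6→4→2→1. For K > 2 the recipe generalizes: a
  full-height (3K,1) preserve conv, (3,1) valid convs doubling filters
  until ≤ 2 channel rows remain, a final (remaining,1) valid collapse
  at the same width, then the two (1,3) spectral convs doubling filters
  twice more — mirroring the K = 2 collapse pattern.
* **serial, K = 2** (3 × KB): the single stack with filters ×3
  (48/96/96/192). For general K the multiplier is (2K − 1), which
  reproduces ×3 at K = 2; only K = 2 has a printed reference, so the
  generalization is a package choice. The width-234 variant of the
  serial net is constructible directly (the builder accepts any input
  width) even though 2 × 78 = 156; the generic K·B rule is what the
  fusion operator produces.

Implementation is pure NumPy (float32): im2col convolutions, standard
batch-norm backward, inverted dropout driven by a per-network seeded
generator, softmax + cross-entropy fused gradient. Probabilities are
clipped at 1e-12 inside the loss, which is otherwise undefined at
P = 0. Weight init is He-normal for convs and Glorot-uniform for dense
layers, drawn from a generator seeded by the model seed — training is
bit-reproducible given (data, config, seed).

## Transfer-learning protocol

* **Pretrain**: all layers, Adam (β = 0.9/0.999, ε = 1e-8), lr 0.001,
  80 epochs, batch 16, shuffled each epoch by a seeded generator.
* **Freeze**: policy `first_half_convs` freezes the first ⌊n_conv/2⌋
  convolutions (2 of 4 for single/serial, 3 of 6 for the two-person
  parallel net) *including* their batch-norm layers — a frozen layer is
  a fixed feature extractor: no gradient updates and no running-stat
  drift, so its tensors are bit-identical before and after fine-tuning.
* **Fine-tune**: lr 1e-4 (0.1× the pretrain rate; only "small" is
  prescribed, the factor is a conventional default), 40 epochs, fresh
  optimizer state at the stage boundary.
* Source domains for fused networks are built from random combinations
  of source subjects (several combinations per trial), since which
  subjects are combined does not affect the resulting classifier.

Checkpoints (.npz) store the architecture JSON, its hash, all tensors,
the frozen set and a SHA-256 content checksum; loading verifies both
hashes and fails with an integrity error on corruption or architecture
mismatch.

## Evaluation protocol

Stratified, shuffled k-fold cross-validation (k = 10) with a recorded
seed; every fold fine-tunes from one shared pretrained checkpoint whose
source domain is simulated independently of the target group, so no
test trial influences pretraining. The partition property (every trial
in exactly one test fold, one trial per class per fold for balanced
sets) is asserted in tests. ITR uses the Wolpaw definition with the
analysis window alone as the selection time T (the 2 s inter-trial rest
is excluded by default; `include_rest_s` adds it for conservative
estimates). `compare_modes` aggregates reports into mode × window
accuracy and ITR tables plus the per-mode overall mean across windows.

## Canned experiments and problem sizes

The `experiments` module fixes desk-scale study conditions chosen so a
full run takes minutes on one CPU:

* **Simulator fidelity**: 100 epochs at +20 dB; spectral-peak hit rate
  and mean absolute SNR calibration error.
* **Single-person benchmark**: +15 dB, 8 subjects × 48 trials; 6
  subjects pretrain (full 80/40 protocol), 2 target subjects evaluated
  by 10-fold transfer CV.
* **Fusion-benefit sweep**: −18 dB, all eight windows, 10 replicate
  seeds; per window one pretrain per mode (24 epochs on a 4-subject
  source domain, 3 combinations per trial), per seed a fresh 2-subject
  group of 32 trials split half/half for fine-tuning (12 epochs) and
  testing. Shortened schedules keep the sweep tractable; the paper-scale
  80/40 protocol remains the library default.
* **Transfer-vs-scratch**: −18 dB, single-person net pretrained on 6
  subjects (40 epochs); 10 paired seeds, each a fresh subject with 24
  training and 24 test trials; fine-tuning (40 epochs, frozen shallow
  convs) vs the same architecture trained from scratch on the same 24
  trials for the same 40 epochs at lr 1e-3.

## What the synthetic results do and do not show

Passing synthetic suites demonstrates that the pipeline's machinery is
correct (geometry, freezing, determinism, protocol) and that its
qualitative claims — fusion helps, transfer helps, shorter windows
hurt — hold under the generator's assumptions: stationary sinusoidal
responses, independent pink+white noise, variability limited to gain,
SNR and latency. Real EEG adds alpha rhythms overlapping the stimulus
band, artifacts, nonstationarity and electrode-level correlations,
none of which are modelled; absolute synthetic accuracies are therefore
not calibrated to any recorded dataset, and the generator's SNR knob is
not a claim about human signal quality.

## Known limitations

* The serial-fusion filter multiplier for K > 2 and the K > 2 parallel
  collapse are principled extrapolations from the K = 2 designs.
* The distributed (per-subject voting) collaborative variant is out of
  scope; only centralized feature fusion is implemented.
* The public 40-target benchmark loader is a documented stub; no
  external corpus is bundled or required.
* No significance testing across modes; reported comparisons are means
  over seeds.
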