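# Methods

`lstmecoc` classifies 63-channel resting-state EEG into three groups —
healthy, mild traumatic brain injury (TBI), moderate TBI — with a fixed
four-stage architecture: a deterministic pre-processing chain, a
single-cell LSTM trained by backpropagation-through-time (BPTT) whose
final hidden state is the feature vector, a one-vs-one error-correcting
output codes (ECOC) support-vector classifier decoded by Hamming
distance, and a bootstrap + 3-fold cross-validation evaluation protocol.
This note records the model, its assumptions, the tunable parameters, and
the design decisions taken where the architecture left choices open.

## Signal model and pre-processing

The input is a sampled multichannel potential `d_i[n] = a_i(n / Fs)` in
microvolts, 63 functional channels in the 10-10 montage (CPz is the EOG
channel and is excluded), `Fs = 1000` Hz. The chain is, in order:

1. **50 Hz notch** — zero-phase second-order IIR, quality factor 30.
2. **0.1–100 Hz bandpass** — zero-phase 4th-order Butterworth.
   Zero-phase (forward–backward) filtering preserves temporal alignment
   across channels; order and realization are standard EEG practice.
3. **Decimation by D = 10** — literally `x[n] = d[10 n]`, taking the rate
   to 100 Hz. No anti-alias filter is applied by default, so 50–100 Hz
   content folds across the new 50 Hz Nyquist; this mirrors the plain
   keep-every-Dth-sample definition of the stage. An optional 45 Hz
   low-pass (`anti_alias=True`) is available.
4. **Artifact excision** — masked intervals are cut out and the clean
   segments concatenated. Masks come either from the caller or from an
   automatic amplitude detector (below).
5. **Windowing** — the first 60 s of the cleaned signal are skipped
   (startup artifacts, subject settling), the next 60 s are kept and
   reshaped to 60 one-second steps × 63 channels × 100 samples — the
   63×6000 matrix the LSTM consumes.

### Automatic artifact detector

Visual artifact inspection is replaced by a reproducible two-stage rule.
Stage one flags any sample whose deviation from the channel median
exceeds `threshold_sd` robust standard deviations (1.4826 × the channel
MAD) on any channel, excluding an `edge_guard_s` margin at the recording
boundaries. Stage two refines boundaries on a `grid_s` cell grid using
normalized cell energy (mean over channels of the cell mean square, in
units of each channel's robust variance): a flagged cell is kept only if
its energy exceeds `energy_ratio` × the recording's median cell energy,
and is then extended across contiguous high-energy neighbours. Defaults:
`threshold_sd = 7`, `edge_guard_s = 2`, `grid_s = 0.5`,
`energy_ratio = 2`.

Three numerical points motivated the defaults. A 5-SD rule on a
two-minute, 63-channel recording of near-Gaussian EEG flags ≈ 0.5
samples per recording *by chance* (≈ 9·10⁵ samples × P(|z| > 5)); each
false flag excises a segment and silently shifts the analysis window, so
the threshold sits at 7 SD — still a factor ≈ 3 below the amplitude of
genuine high-voltage bursts. The edge guard excludes zero-phase-filter
startup transients. And boundary refinement by cell energy — a statistic
with far higher signal-to-noise than a single sample crossing — makes
the excised interval depend on where the artifact is rather than on
which sample happened to cross the threshold first, so identical
artifacts yield identical excisions in every recording.

## LSTM feature extractor

One LSTM cell with `H` hidden units (256 in the full architecture)
followed by a 3-neuron fully-connected softmax head. The cell is the
standard Graves formulation: logistic forget/input/output gates, tanh
cell candidate and output nonlinearity,

    f_t = σ(W_f x_t + R_f h_{t−1} + b_f)
    i_t = σ(W_i x_t + R_i h_{t−1} + b_i)
    s_t = tanh(W_s x_t + R_s h_{t−1} + b_s)
    o_t = σ(W_o x_t + R_o h_{t−1} + b_o)
    c_t = f_t ⊙ c_{t−1} + i_t ⊙ s_t,   h_t = o_t ⊙ tanh(c_t)

with the flattened 63×100 block (6300 values) as the per-step input and
`h_0 = c_0 = 0`. Training minimizes softmax cross-entropy plus an L2
penalty `λ · ½‖W‖²` over all weight matrices (biases excluded), by BPTT
over all 60 steps. Fixed hyperparameters: learning rate 0.001,
mini-batch 4, λ = 0.0005, ADAM (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸; SGD with
momentum 0.9 as the alternative), 30 epochs.

Choices the architecture left open, resolved here:

* **Initialization** — Glorot-uniform input weights, orthogonal recurrent
  weights per gate, zero biases except the forget-gate bias at 1 (the
  cell starts by retaining state).
* **"30 training repetitions"** — read as 30 full epochs over the
  dataset (at n = 36 and batch 4, nine parameter updates per epoch).
* **Feature vector** — the final hidden state h₆₀ (one vector of length
  H per recording); mean-over-steps pooling is available behind a flag.
* **Gradient clipping** — global-norm clip at 1.0 by default (60-step
  BPTT stability); disable with `grad_clip=None`.
* **Input standardization** — per-channel z-scoring with statistics from
  the training fold only, applied before the LSTM.
* **Numerics** — training runs in float32 (the batched input projection
  is the dominant cost and halves in time); the analytic-vs-numeric
  gradient check is done in float64, where BPTT matches central
  differences to ≈ 10⁻⁶ relative error.

## ECOC-SVM classifier

Multiclass decisions come from three binary SVMs arranged by the
one-vs-one (exhaustive) coding matrix

|          | SVM 1 | SVM 2 | SVM 3 |
|----------|-------|-------|-------|
| healthy  |  1    |  1    |  0    |
| mild     | −1    |  0    |  1    |
| moderate |  0    | −1    | −1    |

Each column trains one learner on the +1 class versus the −1 class,
ignoring the 0-coded class. At prediction time each learner's decision
sign forms a ±1 vector, and the predicted class minimizes the Hamming
distance to its codeword counting only nonzero positions; ties break by
fixed class order (healthy < mild < moderate), making decoding total and
deterministic — all eight sign vectors decode, each class is reachable.

Base learners are linear-kernel SVMs with C = 1 (both configurable):
256-dimensional features from at most 36 examples are a regime where
linear margins are appropriate. Features are z-standardized with
training-set statistics before fitting; margin classifiers are
scale-sensitive. The LSTM's own softmax head is retained behind a
configuration switch (`classifier="softmax"`) as the ablation arm.

## Evaluation protocol

For each of `n_bootstrap` replicates (250 for design comparisons, 2000
for a final assessment; the bundled scaled-down runs use 25):

1. draw a bootstrap sample of the cohort — with replacement, original
   size, stratified per class (12 draws within each 12-member class) so
   every subsequent fold split can contain all classes;
2. run stratified 3-fold cross-validation of the *entire* pipeline
   (z-scoring, LSTM training, feature extraction, ECOC-SVM fitting are
   all redone inside each training fold);
3. pool the fold predictions into one confusion matrix and record
   accuracy and macro-averaged one-vs-rest sensitivity, specificity and
   precision, in percent.

Replicates are summarized by mean, standard deviation (0 by convention
for a single replicate), and the percentile 95% CI (2.5th/97.5th
percentiles). The macro average is the conventional multiclass
reduction; with balanced classes it nearly coincides with the micro
average. A class with zero predicted positives contributes zero
precision and logs a warning.

**Duplicates never cross the train/test boundary.** Fold assignment
groups the sample by original recording: all bootstrap copies of one
original land in the same fold (largest-multiplicity-first onto the
lightest fold, per class, which gives exactly 12-item folds in the
duplicate-free case and approximately balanced folds otherwise). The
alternative — treating copies as independent items that may land in
different folds — lets a model that merely memorizes training items
score far above chance on data whose labels carry no information; the
chance-level calibration below is the regression test for this choice.

On data whose labels carry no information, pooled cross-validated
accuracy sits systematically slightly *below* 1/3 rather than at it:
with a model expressive enough to fit its training fold exactly, a test
item's features land away from the training items of its own (here
meaningless) label, a mild anti-learning bias well known for
cross-validation on null data. The chance-level calibration band used
in the tests (33.3 ± 10) absorbs this.

The hill-climbing hyperparameter sweep evaluates one axis at a time in
the order learning rate → mini-batch size → hidden units → optimizer
(grids 0.1/0.01/0.001/0.0001; 1–64; 8–256; SGD-momentum/ADAM), freezing
each axis at its best-mean-accuracy value before moving on.

## Synthetic cohort generator

No clinical recordings ship with the package; the generator produces
cohorts with the statistical structure the pipeline assumes, so every
stage is testable. Each recording is a sum of:

* **Band oscillations** — narrowband-filtered Gaussian noise (not pure
  tones) for delta (1–4 Hz, 12 µV), theta (4–8, 10), alpha (8–13, 20),
  beta (13–30, 5) and gamma (30–45, 2), with a fixed scalp topography:
  alpha posterior-dominant, theta/delta frontal-dominant — the textbook
  eyes-closed resting pattern. Amplitudes are the RMS at the dominant
  region.
* **Class effects** — TBI classes attenuate alpha amplitude (mild ×0.7,
  moderate ×0.5) and amplify theta (×1.5, ×2.0), graded with severity,
  matching the reduced-alpha / elevated-theta qEEG biomarkers of TBI.
  These effect sizes are tool knobs chosen so the default pipeline
  separates the classes cleanly; they are not estimates of the clinical
  effect.
* **Shared class rhythm** — a fraction `class_coherence` (default 0.8)
  of each band's source variance comes from a class-level narrowband
  realization shared by every recording of that class; the rest is
  private to the recording. This is a deliberate idealization: real
  subjects do not share waveforms. It exists because the class signal in
  fully independent realizations is second-order only (band variances),
  and a 30-epoch LSTM trained on 24 examples learns waveform-matched
  filters rather than variance statistics — measured directly: with
  `class_coherence = 0`, held-out accuracy stays near chance while
  training accuracy is 100%, and time-rolling the *training* sequences
  collapses their accuracy too. The shared rhythm puts the class signal
  where this architecture can find it. Passing the recovery test
  therefore shows the pipeline is implemented correctly, not that it
  would reach the same numbers on clinical EEG.
* **Background** — 1/f^β noise (β = 1, 5 µV RMS) and a 50 Hz line-noise
  sinusoid (5 µV).
* **Artifact bursts** — Poisson-many (rate 3/recording, capped at 6)
  0.5–2 s windows of 5× RMS noise. Burst *times* follow a session-level
  stream shared by all recordings (environment/equipment interference
  hitting every recording at the same times) and are quantized to the
  detector's 0.5 s grid, so threshold-based excision removes the same
  segments everywhere and the shared rhythms stay aligned after
  excision; burst *content* is recording-specific. Ground-truth burst
  intervals are logged on the recording for detector validation.

Everything derives deterministically from `(class_label, config, seed)`;
the label only scales amplitudes and selects the shared-stream identity,
so matched seeds across classes share their private waveforms (halving
the alpha amplitude exactly quarters alpha power). `null_effects()`
disables all three class effects (attenuation, gain, shared rhythm) —
under it, recordings are identical across labels for matched seeds, so
labels carry no information by construction; the evaluation protocol
must then score at chance (33.3% for three balanced classes).

What the generator does **not** model: volume conduction from dipolar
sources (no forward model), non-stationary band power, alpha peak
frequency shifts, subject-specific spectra, ocular/muscle artifact
morphology, or inter-channel correlation beyond the shared sources.

## Problem sizes of the bundled runs

The scaled-down recovery runs used by the test suite and the acceptance
script simulate 36 recordings (12/class, 140 s, 1000 Hz), train at
H = 32 for the standard 30 epochs, and run 25 bootstrap replicates of
3-fold CV; the full-architecture shape contracts (H = 256 features,
63×6000 input) are checked structurally. The sweep grids are exposed in
`evaluation.DEFAULT_SWEEP_GRID` but the bundled runs do not sweep.

## Known limitations

* The generator's class separability is by construction (see above);
  results on it say nothing quantitative about clinical data.
* Literal decimation without anti-aliasing folds 50–100 Hz energy into
  the 0–50 Hz band; the optional `anti_alias` flag departs from the
  literal definition but is the signal-processing-correct choice.
* EDF export uses a built-in 16-bit encoder (one-second records,
  symmetric physical range); reading goes through MNE. Round-trip error
  is bounded by the 16-bit quantization step.
* With `k_folds` > the number of distinct originals of some class in a
  bootstrap sample, fold construction fails; at the default 12-per-class
  stratified resampling this is vanishingly rare (each replicate is
  retried once with a derived seed, then aborts).
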