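# Methods

`eegmse` implements an EEG emotion-recognition pipeline that turns
multi-channel recordings into three binary affect decisions (low/high
arousal, valence and dominance) via multiscale sample entropy (MSE)
features and a hybrid CNN–HMM classifier. This note records the model,
its assumptions, the defaults that matter, and the design decisions
taken where more than one reasonable choice existed.

## Signal model and feature extraction

**Band decomposition.** Each channel is split into theta (4–7 Hz),
alpha (8–13 Hz), beta (14–30 Hz) and gamma (31–45 Hz) signals with
digital Butterworth bandpass filters. The lowpass prototype magnitude
obeys |H(w)|² = 1/(1 + (w/w_c)^{2n}): unit gain at DC and half power at
the cutoff; the bandpass design follows by the standard lowpass-to-
bandpass transformation (`scipy.signal.butter`). The filter order is
not dictated by the method; the default is n = 5, a common EEG choice
steep enough to separate adjacent bands at 128 Hz, and it is
configurable (`filter.order`). Filtering is forward–backward
(zero-phase) by default so that windowed entropy values are not
shifted by group delay; a causal mode exists (`filter.zero_phase`).

**Segmentation and labels.** A 63-s trial is tiled into 63
non-overlapping 1-s windows: 3 pre-trial baseline windows and 60 trial
windows that inherit the trial's labels. Ratings in [1, 9] are
binarized at 5 per dimension (≤ 5 → low, > 5 → high). At the full DEAP
layout this yields 32 × 40 × 60 = 76,800 labeled trial segments.

**Multiscale sample entropy.** For a window y, sample entropy is
−ln(B^{m+1}/B^m), where B^m is the average per-template fraction of
other m-length templates within Chebyshev distance strictly less than
r. Defaults m = 2 and r = 0.2 × std, the standard EEG settings. The
counting conventions implemented (and mirrored exactly by the
brute-force oracle in the test suite) are: self-matches excluded;
per-template counts divided by N − m; the average taken over all
N − m + 1 templates (N − m − 1 and N − m respectively at dimension
m + 1). The multiscale variant first coarse-grains the series; the
default mode is a *sliding* (moving-average) window of length τ, which
keeps N − τ + 1 points, with the classical non-overlapping block
average available as `entropy.coarse_grain_mode = "nonoverlapping"`.
The tolerance r is computed from the original (pre-coarse-graining)
series with the sample standard deviation (N − 1 denominator), keeping
r fixed across scales. The pipeline default scale is τ = 2, the scale
at which the hybrid classifier performs best; τ ∈ {1..5} is the
supported sweep range.

Degenerate windows — zero match counts, e.g. a flat channel where
r = 0.2 × std = 0 — return NaN rather than raising; the tensor builder
imputes 0 after baseline correction and logs a warning.

**Baseline correction and spatial tensors.** The mean MSE vector of
the 3 baseline windows is subtracted elementwise from every trial
window's MSE vector. The corrected per-channel values are embedded
into an 8 × 8 inner grid by 10-20 electrode geometry (rows
front-to-back Fp…O, columns left-to-right by lateral position, with
the midline and "2" electrodes sharing a column index but never a
row), surrounded by a ring of always-zero border cells, giving one
10 × 10 plane per band and a 10 × 10 × 4 tensor per window. The exact
channel-to-cell table is a documented package constant
(`eegmse.montage.DEAP_GRID`) and can be overridden from a JSON file;
unmapped cells are zero-filled, never interpolated.

## CNN feature extractor

Four convolutional layers (64, 128, 256, 64 channels; kernels 4×4,
4×4, 4×4, 2×2; stride 1; SAME padding, so the 10 × 10 spatial size is
preserved) followed by fully connected layers of 1024 and 512 units,
all with ReLU activations. A softmax head is attached for training and
retained for diagnostics; the downstream observation vector is the
512-dimensional second fully-connected activation.

Training minimizes softmax cross-entropy plus an L2 penalty (default
1e-4) with Adam at initial learning rate 0.01, dropout 0.5 on both
fully connected layers, and a plateau schedule that divides the
learning rate by 10 whenever validation error stops improving
(patience 3 epochs). Batch size 128 and 50 epochs by default; all of
this sits under `cnn.*` in the config. The network is implemented
directly on numpy (float32 im2col + GEMM with manual backpropagation);
at 10 × 10 input size this trains at useful speed on a single CPU
core. One extractor is trained per emotional dimension per CV fold,
on that fold's training split only.

## HMM classifiers

One Gaussian hidden Markov model λ = (π, A, B) per class (high, low)
per dimension. The transition matrix has Bakis (left-right) support:
nonzero entries only on and above the diagonal (self-loop, advance,
skip), enforced exactly after every update. Emissions are
diagonal-covariance Gaussians, one component per state (mixtures with
M > 1 are deliberately not implemented: the single-component
configuration is the one under which this classifier performs best,
and the parameter is validated with a clear error). Defaults: Q = 3
states, variance floor 1e-6, at most 1000 EM iterations, stopping when
the total log-likelihood improves by less than 0.01.

Training is multi-sequence Baum-Welch: forward-backward posteriors are
accumulated over all of a class's training sequences (one sequence =
one trial's 60 consecutive segment feature vectors) before each
M-step, making the updates exact EM and the total log-likelihood
non-decreasing — asserted in the tests at every iteration.
Initialization is deterministic: π = (1, 0, …, 0), uniform transitions
over the allowed upper triangle, emission means from averaging each
sequence's Q contiguous blocks, pooled variances. The recursions run
in the log domain: with 512-dimensional ReLU features and floored
variances, per-frame emission log-densities can differ by thousands of
nats between states, which underflows the classical scaled (linear-
domain) recursion; log-sum-exp arithmetic is exact in this regime and
cheap at Q = 3. Equal-length sequences are batched through the E-step.

A held-out trial is classified by the larger forward log-likelihood;
exact ties (possible only for identical models) go to "low" with a
warning.

## Cross-validation protocol

10-fold CV with a seeded shuffle. The fold unit is the **trial**: all
60 segments of a trial stay on one side of the split. Splitting the
segment pool directly would place segments of the same trial in both
training and test — since every segment of a trial shares one label
and one generating stimulus, that protocol leaks; it is nevertheless
available (`cv.unit = "segment"`, with per-segment accuracy
accounting) for comparison with results reported under it. Accuracy is
scored at the sequence (trial) level by default. The split is neither
stratified nor subject-aware; it is a plain seeded shuffle at the
chosen unit. Fold-level seeds are derived from the master seed through
`numpy.random.SeedSequence`, so a run is reproducible end to end and
the absence of train/test trial overlap is asserted programmatically
inside every fold.

## Synthetic data generator

Real affect-rated EEG of this shape is access-restricted, so the
generator emulates the layout and plants a controllable class signal:

- Layout: subjects × trials × channels × samples, default 128 Hz,
  3 s baseline + 60 s trial (8064 samples), 32-channel 10-20 montage,
  integer ratings per dimension drawn uniformly from {1..5} (low class)
  or {6..9} (high class), so threshold-5 labeling recovers the
  generative class exactly.
- Per band, the *low* regime is a sinusoid at the band center plus
  Gaussian noise at 10% of its amplitude; the *high* regime is
  band-passed white noise of matched variance. Sample entropy provably
  separates these regimes, so the features the pipeline computes are
  exactly the ones that carry the class. A `contrast` knob in [0, 1]
  linearly mixes the regimes' variances (0 ⇒ no class signal at all).
- Each dimension owns one band (arousal → beta, valence → alpha,
  dominance → gamma by default), so the three decisions are
  independent. Baseline portions and untargeted bands always follow
  the class-independent low regime.
- Per-band amplitudes (θ/α/β/γ std ≈ 8/8/6/4 arbitrary units) mimic
  the decreasing band power of resting EEG.

What the generator does **not** emulate: ocular/muscle artifacts,
inter-channel spatial correlation, volume conduction, non-stationary
emotional dynamics within a trial, or rating noise (labels are exact).
Passing end-to-end tests therefore demonstrates that the pipeline
recovers a band-specific irregularity contrast planted in DEAP-shaped
data — not that it attains any particular accuracy on real recordings.

## Numerical choices and problem sizes

- Entropy matching is strict (< r) in float64; the short-segment path
  folds a full |y_i − y_j| matrix with shifted maxima, the long-series
  path chunks the same computation.
- Constant windows are detected by zero peak-to-peak range (a pure
  std > 0 test is defeated by float rounding).
- EM monotonicity is asserted with relative slack 1e-8; the variance
  floor (1e-6) in principle can break monotonicity but never binds in
  practice on these features.
- Test-suite end-to-end runs use reduced scales chosen for single-CPU
  turnaround: strong-contrast recovery at 4 subjects × 20 trials ×
  8 channels with 10 CNN epochs and a narrowed conv stack
  (8/16/32/8, fc 64/64); the chance-level null at 4 × 80 trials (320
  held-out decisions, binomial sd ≈ 2.8 points) with a tiny 2-epoch
  CNN, since the null does not depend on model capacity. The
  full-width architecture is exercised by the forward-pass and
  feature-dimension tests.

## Known limitations

- The CNN trains on CPU via numpy; it is adequate for the package's
  scales but not for GPU-sized sweeps.
- Only single-component Gaussian emissions (M = 1).
- EDF input is read-only and optional (requires `mne`); the native
  container is one `.npy` per subject plus a JSON sidecar.
- The channel-to-grid table fixes one canonical 8 × 8 embedding;
  montages outside the DEAP 32-channel set need a user-supplied
  mapping file.
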