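# Methods

## Problem and pipeline

`mitopo` decodes binary motor imagery (left fist vs right fist) from
64-channel EEG by classifying *spatial-spectral images* rather than raw
time series. The physiological signal is event-related
desynchronization (ERD): imagining a hand movement suppresses mu-rhythm
(~10-15 Hz) power over the contralateral sensorimotor cortex, so the
class information lives in *where on the scalp* band power drops.

Each 4-s, 160 Hz trial is processed as:

1. **Band-pass 5-35 Hz** — zero-phase Hamming-window FIR (designed and
   applied via MNE), covering mu and beta rhythms while suppressing
   drifts, line noise and most artifact energy (>=40 dB stopband by
   design; approximately -3 dB at the band edges).
2. **Welch PSD per channel** — the trial's 640 samples are cut into
   L = 2 contiguous non-overlapping blocks of M = 320, each tapered
   (Hamming), periodogram-normalized by the window power
   U = (1/M) Σ w², scaled to one-sided density units (µV²/Hz), and
   averaged. M = 320 gives a 0.5 Hz bin spacing — exactly one bin per
   sub-band below.
3. **Sub-band powers** — the 10-15 Hz mu band is split into ten 0.5 Hz
   sub-bands; the per-channel value of a sub-band is the *mean* of the
   PSD bins whose centers fall in its half-open interval (mean rather
   than sum, so values are insensitive to bin count).
4. **Topology matrix** — the 64 channel values are placed into an
   11 x 10 grid ordered anterior -> posterior (rows) and left -> right
   (columns, midline at column 5); non-electrode cells are structural
   zeros. The placement ships as data (`MontageLayout`, JSON-editable).
   The inferior temporal electrodes T9/T10 would make the central ring
   11 electrodes wide — one more than the grid has columns — so they
   occupy their own row just below the C ring; these two cells are the
   least certain part of the default layout.
5. **Interpolation** — each grid is upsampled to 110 x 100 by
   Clough-Tocher piecewise-cubic interpolation over a Delaunay
   triangulation of all 110 cell centers, evaluated on a uniform
   lattice spanning the grid extent. Zero-cells participate as genuine
   data points by default (`mask_zero_cells` interpolates from
   electrode cells only; this changes edge behavior, not the cap
   interior). The gradient-estimation tolerance is tightened to 1e-12
   so constant and planar fields reproduce to ~1e-9.
6. **Tensor** — the ten interpolated frames are stacked into a
   110 x 100 x 10 array: two spatial axes, one spectral axis.

## The network

A factorized ("pseudo-3D") CNN with two convolution blocks and a dense
head:

    block:  spatial conv 5x5x1 -> ReLU -> spectral conv 1x1x5
            -> square -> conv-pool 2x2x2 stride 2, no padding -> log
    head:   dropout 0.5 -> flatten -> FC 256 (ReLU) -> FC 2 -> softmax

* The 5x5x1 / 1x1x5 pair factorizes a 3D kernel into a spatial and a
  spectral convolution. These use same-padding; with valid padding the
  spectral axis (10 frames) would shrink below the 5-tap spectral
  kernel by the second block, so the factorized kernels could not be
  applied twice. Only the conv-pool layers — learnable strided
  convolutions, not max/average pooling — reduce resolution
  (d -> floor((d-2)/2) + 1 per axis).
* square -> pool -> log makes each block a log-power feature extractor:
  with uniform pool weights the chain computes the log of a local mean
  of squares. Conv-pool weights are initialized as positive
  near-uniform (jittered averaging) filters for exactly this reason:
  signed initial weights would feed the log negative values, clamp
  them at log(eps) (eps = 1e-6) and kill those units' gradients — a
  failure mode we observed empirically as training pinned at chance.
* Batch normalization follows conv layers 2 and 6 (convs are counted
  spatial/spectral/pool per block). At conv 2 it sits directly after
  the conv. At conv 6 — a conv-pool — it is placed after the log:
  normalizing the strictly positive pooled squares *before* the log
  would re-center them around zero and clamp half the units.
* The output layer is zero-initialized (hidden layers Glorot), so a
  balanced problem starts exactly at the chance loss ln 2 with no
  class preference.
* Loss is the mean negative log-likelihood of the softmax; training is
  shuffled minibatch SGD, deterministic given the seed.

Stock training configuration: 500 epochs, learning rate 0.001,
batch 64, 16/32 filters, plain SGD. These match the printed protocol
for full-scale experiments and are the defaults; they are not exercised
by the test suite.

**Reduced preset** (`reduced_configs`): 4/8 filters, FC 64, 10 epochs,
lr 0.01 stepped down 10x after epoch 6, momentum 0.9, batch 16, weight
decay 1e-3 on weights (not biases/BN), gradient-norm clip 5, a log10 +
per-pixel z-score input transform, and the weights of the final 3
epochs averaged (Polyak-style) to damp the late-phase SGD bounce. This
preset is used for simulation studies and the band scan, where the
stock network is needlessly large; its settings were chosen for stable
desk-scale convergence.

Two symmetry devices exploit the fact that left- and right-fist imagery
are mirror conditions on a (near) left-right-symmetric montage:

* **mirror augmentation** — the training set is doubled with trials
  mirrored about the scalp midline and given the opposite label;
* **symmetrized prediction** — class probabilities are averaged with
  those of the mirrored input (labels swapped), which cancels
  hemisphere-asymmetric overfitting noise at evaluation time.

The mirror operates on the interpolated pixel axis: electrode columns
1-9 of the grid are symmetric about the midline column 5, i.e. pixel
indices 0-88 of the 100-pixel axis; the off-cap right-edge band is
structurally near zero and kept as is. On real caps the symmetry is
approximate (and brain responses are not perfectly mirror-symmetric),
so both devices are preset flags, off in the stock configuration.

The network itself is implemented in NumPy (`mitopo.nn`) with explicit
backpropagation: convolutions are im2col + a single GEMM, and every
layer's gradient is verified against central finite differences in the
test suite. Forward/backward state is float32; memory per training step
is dominated by the im2col buffers of block 1 (~200 MB at batch 16).

## Band scan

Before committing to a band, the 5-35 Hz range is cut into six 5 Hz
bands; each is imaged into tensors and scored under the split protocol
with an injected classifier (mean +/- std over repeated splits; seeds
derived from the split seed). The default classifier is the reduced
CNN; `BandPowerLogistic` — logistic regression on the tensors
block-averaged back to the 11 x 10 grid — is the fast alternative used
where six CNN fits would be wasteful. Ties select the lower band.

## Evaluation protocol

Trials are shuffled with seed 42 and split 75/25 (non-stratified by
default, matching a plain shuffle of the whole set; stratified
available). Metrics: accuracy; Cohen's kappa (P_o - P_e)/(1 - P_e)
with P_e fixed at 0.5 for the binary task (hence kappa = 2 acc - 1);
recall, precision and F1 for a designated positive class (default:
left fist); and the actual x predicted confusion matrix. Subject-level
accuracy is the unweighted mean of per-subject rates R_i/S_i — each
subject counts equally — with the pooled-count variant available
separately, since the two differ whenever trial counts are unequal.

## Synthetic data

The generator (`mitopo.synthetic_data`) emulates the statistical
structure the method exploits, so the full pipeline is testable with no
recordings:

* **Background**: per-channel 1/f^alpha Gaussian noise (alpha = 1,
  spectrum flattened below 1 Hz), mixed across channels with
  distance-decaying weights on the electrode grid (correlation length
  1.2 cells) so adjacent channels co-vary; broadband RMS 10 µV.
* **Mu rhythm**: narrowband-filtered Gaussian noise (4th-order
  Butterworth, 10-15 Hz) — not a sinusoid, so spectral estimates carry
  realistic variance — carried by the C3 and C4 neighborhoods with
  Gaussian spatial falloff; 15 µV RMS at the focus, a realistic
  sensorimotor amplitude that puts in-band mu power well above the
  background's mu-band content.
* **ERD**: left-fist trials scale the *right*-hemisphere mu power by
  (1 - erd_effect), and symmetrically (contralateral physiology).
  At the stock erd_effect = 0.6 the measured C4-region band-power
  ratio between classes lands near 0.45: the nominal 0.4 diluted by
  background leakage into the band.
* **Trial variability**: log-normal per-trial, per-hemisphere amplitude
  jitter (sigma = 0.15).

What the simulation does *not* model: volume conduction through a head
model, eye/muscle artifacts, non-stationarity within trials, beta-band
ERS, inter-subject variability. Passing tests therefore demonstrate
that the pipeline recovers a lateralized band-power contrast of
realistic size from realistically noisy spectra — not performance on
any real recording.

With these conditions (100 trials/class) an oracle classifier reading
the true lateralization feature (log contralateral-region mu power,
left vs right) reaches about 95%; the reduced network operates close to
that ceiling, and at erd_effect = 0 decoding stays at chance.

## Numerical choices and edge cases

* Welch periodograms are scaled 1/(U M f_s) with the one-sided factor 2
  on interior bins, so Σ PSD × Δf equals the signal's mean square
  exactly for a rectangular window (Parseval); the estimator is
  cross-checked against an independent brute-force DFT oracle and
  against `scipy.signal.welch`.
* Sub-bands narrower than the frequency resolution raise an error
  directing the user to a larger M.
* `log` activations floor their input at eps = 1e-6; gradients are zero
  in the floored region.
* NLL of an exactly-zero true-class probability is clamped at 1e-12
  with a warning rather than returning infinity.
* All stochastic components (generator, weight init, shuffling,
  dropout) draw from explicit seeded `numpy` generators; identical
  seeds give bit-identical trials, parameters and predictions.

## Known limitations

* The NumPy network is CPU-bound: the stock 500-epoch configuration on
  a full dataset is impractical without a GPU framework; the package's
  own studies use the reduced preset.
* The Eq-style printed placement of the 64 electrodes on an 11 x 10
  grid cannot hold the 11-wide central electrode ring; the default
  layout resolves this by giving T9/T10 their own row (see above) and
  is deliberately editable data.
* The 75/25 protocol evaluates within-session generalization only;
  cross-subject transfer is out of scope.
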