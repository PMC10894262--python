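# Methods

## Problem and approach

A lateral-flow assay (LFA) is normally read 10–15 minutes after sample
loading, once the test line has fully developed. The readout implemented
here exploits the *kinetics* of color development instead: a short time
series of strip images (typically 12 frames over the first two minutes,
one frame every 10 s) is fed to a small convolutional encoder whose
per-frame features are consumed by an LSTM; the final hidden state passes
through a fully connected head that outputs a continuous score on the
manufacturer color-chart scale (levels 0–8). Rounding the score gives the
chart level, the level maps onto the five reporting classes (high: levels
8–7, middle: 6–5, mid-low: 4–3, low: 2–1, negative: 0), and a strict
threshold on the raw score gives the binary positive/negative call.

The pipeline has four stages, each usable on its own:

1. **Simulation** (`lfaseq.simulate`) — seeded synthetic strips with known
   ground truth, so the whole method is testable without image downloads.
2. **ROI localization** (`lfaseq.roi`) — a deterministic intensity-profile
   detector finds the test and control lines and crops the model input.
3. **Sequence model** (`lfaseq.model`, `lfaseq._nn`) — conv-LSTM regression
   trained with mean absolute error (MAE), plus a head-swap fine-tuning
   recipe for binary classification with cross-entropy (CE).
4. **Decision and evaluation** (`lfaseq.metrics`) — level/class/binary
   mapping, confusion tables, sensitivity/specificity/accuracy, rank-based
   ROC-AUC, RMSE and the frames-vs-RMSE trade-off curve.

## The strip simulator

The simulator emulates the phenomenology of a colloidal-gold LFA under a
fixed reader, not its chemistry.

**Wicking front.** Buffer advances along the membrane with a Washburn-like
square-root law. The front is parameterized so that it reaches the test
line exactly at `arrival_time_s` (default 30 s, the point at which sample
visibly reaches the test line in this class of kits):
`front(t) = test_line_center_px * sqrt(t / arrival_time_s)`, clipped to the
strip width. The control line, lying downstream, is reached at
`arrival * (control_center/test_center)^2`.

**Line development.** The test-line contrast (a scalar in [0, 1]) follows
first-order binding toward a concentration-dependent saturation:

    q(c, t) = A_max * c / (c + K) * (1 - exp(-k * (t - t_arrival)))    for t > t_arrival

with Michaelis–Menten saturation in concentration (`K` = half-saturation
concentration) and rate `k` in 1/s. This closed form is also the oracle the
tests compare rendered images against. It is an emulation chosen for
plausibility and testability — no claim is made about the true binding
kinetics of any particular kit. The control line develops with the same
rate law from its own arrival time, with fixed amplitude
`control_amplitude`, for every sample including blanks.

**Color model.** A contrast `q` removes `q*255` counts from the green and
blue channels and leaves red untouched, the appearance of a reddish-purple
gold-nanoparticle line on a white membrane. A wet-membrane wash term
`bg_wash_amplitude * exp(-t / bg_decay_tau_s)` is applied behind the front
the same way, reproducing the early diffuse background that makes short
assays hard to read by eye. Per-frame multiplicative illumination jitter
and per-pixel Gaussian noise (8-bit units) are added, then the frame is
rounded and clipped to uint8. Identical parameters and seed give
bit-identical stacks.

**Defaults** (chosen once for phenomenological realism): `arrival = 30 s`,
`k = 0.03 /s`, `A_max = 0.85`, `K = 5 ng/mL` (mid-ladder), control
amplitude 0.6, wash amplitude 0.15 with `tau = 90 s`, pixel sigma 2.0,
illumination sigma 0.01. Strips are 40×160 px with the test line at column
60, control at 100, lines 4 px wide. With the default 2-minute, 10-s-grid
acquisition this puts line appearance in the 1–2 minute range for low
concentrations and guarantees a well-developed control line by the final
frame.

**What the simulator does not model:** perspective and lighting variation
of hand-held photography, cassette housings, membrane lot-to-lot
variability, multi-line (e.g. influenza A+B) strips, hook effects at
extreme concentrations. Passing tests on synthetic panels therefore
demonstrate the pipeline's mechanics and learnability under controlled
kinetics, not clinical performance.

## Frame grids and panels

Acquisition timestamps live on the half-open grid `(0, duration]`:
`t = i * interval` for `i = 1..floor(duration/interval)`. This is the only
convention simultaneously consistent with 12 frames per 2-minute assay,
6 per minute at 10 s, 30 per minute at 2 s, and 12 frames in a `(36, 60]` s
window on a 2-s grid — all acquisition patterns the package supports.
Windowing with `select_window(start, end]` keeps the same convention.

Dilution ladders are geometric (`serial_dilution(50, 2, 8)` gives
50 … 0.390625 ng/mL). The highest ladder point maps to chart level 8, each
dilution to the next level down, blanks to level 0; off-ladder
concentrations are rejected rather than interpolated. The train/validation
split moves `floor(frac * n_train)` seeded-random train records to the
validation split (default 10%).

## ROI localization

Each column of a frame is scored by its row-mean gold-deficit
`(R - (G+B)/2)/255`; a rolling-median baseline (window 31 px) removes
slowly varying background so line peaks survive. Profiles are averaged over
the last quarter of frames, where lines are strongest. The two most
prominent peaks (minimum separation 10 px, prominence floor 0.02) become
test = upstream and control = downstream; boxes span three line-widths in
columns and the central 80% of rows. Peak prominence normalized by the
largest peak is reported as confidence.

On negative strips only the control line is visible: given the layout's
expected line spacing, the test box is then placed upstream of the single
detected peak at that spacing with confidence 0. The single detected peak
is assumed to be the control line, because only the control line is
guaranteed present on a valid strip; a strip with a developed test line but
a genuinely absent control line can therefore be mislocated — a known
limitation of the single-peak fallback. Zero peaks is an error (invalid
strip). Any callable with the same sequence-to-boxes contract can replace
this detector, e.g. a learned object detector.

Strip validity is the background-subtracted control-box contrast in the
final frame exceeding `min_contrast` (default 0.1). The contrast estimator
subtracts flanking membrane bands and is exact (to quantization) when its
neighborhood is uniformly wet or dry; while the wet front transits the
reference bands it is biased, which the tests account for by checking
oracle agreement only on fully wetted frames.

## Sequence model

The default network is deliberately small: conv3×3 → ReLU → 2×2 average
pool with channels (8, 16), global average pooling, a linear projection
with ReLU to 16 features, a single-layer LSTM with 24 hidden units, and a
linear head. ROI crops are resized to 16×16 and scaled to [0, 1]. The
config path allows deeper encoders, stacked LSTMs and larger inputs; the
implementation is plain numpy (im2col convolution, BPTT, Adam) in float64,
single-threaded-deterministic and bit-reproducible under a fixed seed.

**Losses.** Regression uses MAE `(1/N) Σ|y_i − ŷ_i|` on the level scale,
preferred over squared error for outlier robustness. Classification uses
two-class cross-entropy `−Σ y_i log p̂_i` (natural log) on softmax
probabilities, with predictions clamped to `[1e-12, 1]` before the log.

**Output scaling.** The network regresses `level/8` internally and
predictions are rescaled ×8. Because MAE gradients have constant magnitude,
Adam's effective step is ~lr per update regardless of residual size;
normalizing the output range keeps convergence fast without touching the
level-scale API.

**Training defaults:** Adam, learning rate 1e-3, batch size 8, 150 epochs.
Batches group sequences of equal length, so one fitted model accepts any
frame count `k ≥ 1` — the same model evaluates 3-frame and 12-frame
sequences in the duration sweep. Targets are the chart levels 0–8
(higher concentration ⇒ larger number), which makes `score_to_level`
trivial and places the binary threshold (default 0.5, strict inequality)
between blank and the lowest positive level. Class weighting is uniform.

**HSV augmentation.** Each training sample contributes its RGB crop plus
the same crop transformed to HSV and re-embedded as a 3-channel 8-bit
image, doubling the training set. This is implemented as dataset doubling
(augmentation), not 6-channel concatenation.

**Fine-tuning.** `fine_tune_binary` transplants every encoder, projection
and LSTM parameter of a trained regressor unchanged, re-initializes a
fresh 2-way head, and trains with cross-entropy on binary labels. The donor
regressor is never modified. Note that the cross-entropy loss is the
standard form with predicted probabilities; a label-only entropy
`−Σ y log y` would be identically zero for one-hot labels and cannot drive
learning.

## Evaluation

Sensitivity `100·TP/(TP+FN)`, specificity `100·TN/(TN+FP)` and accuracy
`100·(TP+TN)/n` are computed unrounded and displayed at one decimal.
ROC-AUC uses the exact Mann–Whitney rank formula (ties counted ½),
identical to trapezoidal ROC integration; the tests cross-check it against
both an exhaustive pairwise oracle and scikit-learn. The multiclass 5×5
confusion table counts per manifest record. The frames-vs-RMSE trade-off
trains a fresh seeded model per frame count `k` on front-truncated
sequences (ROI located on the full sequence first, since detection uses
late frames) and reports the median held-out RMSE over seeds; the resource
proxy is `k / max(k)` — frame count stands in for compute and memory,
which scale monotonically with sequence length, so no hardware measurement
is involved.

## Study conditions for the shipped checks

The standard panel is the 8-point, 2-fold ladder from 50 ng/mL with 10
replicates per point plus 10 blanks (90 records, 12 frames each at 10 s),
default noise, 3 held-out replicates per level, 10% validation split.
Headline checks train three seeds and take medians: held-out binary
accuracy, exact-level match rate, AUC, RMSE, the k = 3 vs k = 12 trade-off,
and fine-tuning on the separable binary subset (levels ≥ 5 vs blanks).
These sizes keep a full from-scratch reproduction in the tens of minutes
on a single CPU core while leaving the conclusions unchanged at larger
replicate counts.

## Known limitations

- The kinetic model is first-order and monotone; assays with transient
  overshoot, hook effect, or non-monotone wash dynamics are outside it.
- The detector assumes a fixed-geometry reader image with horizontal flow
  and exactly one test line; its single-peak fallback assumes the control
  line is the visible one.
- The level regression is trained and evaluated on ladder-aligned
  concentrations; intermediate concentrations would produce intermediate
  scores but have no ground-truth level.
- MAE training with small batches can leave a small constant offset on
  rare classes (occasionally pushing blank predictions toward level 1 for
  an unlucky seed); the shipped checks use 3-seed medians, which is also
  how the package is recommended to be run.
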