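# Methods

## Problem and approach

Sleep spindles are brief (>= 0.5 s) bursts of 11-16 Hz (sigma-band)
oscillatory activity in N2-sleep EEG. `spindleseg` treats their detection as
one-dimensional semantic segmentation: a slim fully-convolutional U-Net maps
a z-scored 100 Hz single-channel segment to per-sample spindle /
no-spindle probabilities, and post-processing converts the probability
track into (onset, duration) annotations. Detections are evaluated by
event, not by sample, so long spindles do not dominate the metrics.

## Signal conditioning

Segments are band-passed with a phase-preserving Butterworth filter of
effective order 10 (passband 0.3-30 Hz), downsampled to 100 Hz, and
z-transformed per segment (zero mean, unit population variance). Numerical
choices:

- The zero-phase filter is realized as forward-backward application of a
  5th-order design in second-order sections; squaring the magnitude yields
  the effective 10th-order response while keeping the recursion stable.
- Resampling is polyphase-rational (e.g. 256 -> 100 Hz is up 25 / down 64);
  the output is trimmed to `round(n * fs_out / fs_in)` samples. The 30 Hz
  low-pass edge sits below the 50 Hz target Nyquist, so aliasing is handled
  before decimation. There is no upsampling path.
- The z-transform uses the population convention (divisor N). At segment
  lengths of 11500 samples the difference from the sample convention is
  immaterial, but the convention must be fixed for exact tests. Constant
  segments raise an error rather than silently becoming zeros.

The order band-pass -> resample -> z-score is part of the contract; the
z-transform must come last so the network input is scale-free.

## Architecture

The encoder has `levels` resolution levels (default 3, the last acting as
bottleneck) of two composite layers each — convolution, ReLU, batch
normalization, in that order — with equal channel counts within a level and
doubling across levels (default filters 16/32/64). Compression is
non-overlapping max pooling (widths 4 and 4 by default); expansion is
nearest-neighbor upsampling followed by a convolution with kernel equal to
the pool width mapping to half the incoming channels, concatenated with the
matching encoder activations. A width-1 convolution to two channels and a
channel softmax produce the probability head.

Kernel and dilation default to 9 and 1, so every composite convolution has
an effective extent of (9-1)*1 = 8 samples. This is the unique calibration
under which the third-level receptive field — computed as
`1 + sum (extent - 1) * cumulative stride` along the encoder — equals 1.48,
3.52 and 6.24 s at 100 Hz for second pool widths 1, 4 and 8 (in closed
form, `rf = 80 + 68 * w2` samples). The ~3.5 s field of the default is a
few spindle durations wide; larger fields add little because spindles are
0.5-1.5 s events.

Inputs whose length is not divisible by the pooling product (11500 is not
divisible by 16) are right-padded with zeros before the encoder and cropped
after the decoder, so the output always matches the input length.

### The compute engine

The layers, Kaiming-uniform initialization (bound `sqrt(6 / fan_in)`), Adam
and backpropagation are implemented directly on numpy arrays in
`spindleseg.nn`. Convolutions are evaluated tap-by-tap as K small matrix
products rather than via an im2col intermediate, which is memory-bound at
T ~ 1e4. Training runs in float32; a float64 path exists and is used by the
finite-difference gradient check, which verifies the full network gradient
to ~1e-7 relative error.

## Training

The loss is the generalized dice loss over the two classes with weights
`w_l = 1 / (sum_n r_ln)^2` computed per batch, floored at 1e-8 when a class
is absent. The loss consumes the raw (unsmoothed) probability tracks;
smoothing is an inference-time step only. Optimization is Adam with
learning rate 0.005, beta1 0.9, beta2 0.999, epsilon 1e-8, on minibatches
of 12 whole segments; segments are reshuffled each epoch with the run seed
and the final short batch is kept (hence steps/epoch = ceil(n / 12), e.g.
45 for a 535-segment training set).

After each epoch the model is scored on the validation fold by F1-bar, the
trapezoidal integral of event-level F1 over overlap thresholds 0.05-1.00
(step 0.05) normalized by the grid span. The best-scoring parameters are
retained; training stops after 300 epochs without improvement or at epoch
800 (both configurable). F1-bar is used consistently for early stopping and
model selection; plain F1 at the 20% threshold is available via
configuration.

Cross-validation splits subjects, never segments: ten-segment subjects are
dealt round-robin across the k folds first, then remaining subjects fill
folds to equal size (144 subjects -> six folds of 24 subjects, 5
ten-segment each, 107 segments per fold).

## Post-processing

Both probability channels are smoothed with a centered moving-average
filter. The configured width is nominal (default 42 samples = 0.42 s); the
kernel is forced odd (43) so smoothing is phase-free — an asymmetric kernel
would shift every event boundary systematically. Edges are mirrored
(symmetric padding), which preserves constant tracks. The class decision is
the pointwise maximum, i.e. spindle wins when its smoothed probability
strictly exceeds 0.5; exact ties resolve to no-spindle (conservative).
Consecutive positive samples are joined into events on the half-open
convention [onset, onset + duration). No minimum-duration filter is applied
by default: the 0.5 s floor is a property of the reference annotations, not
a stated post-processing rule; a `--min-duration` option exists.

## Evaluation

Relative overlap of two events is intersection over union ("joined
duration" read as the union span — the alternative reading, sum of
durations, could never reach 1 for identical events). Matching is
one-to-one greedy by descending overlap with deterministic tie-breaks;
pairs with overlap strictly above the threshold are true positives. A
per-reference "closest detection" rule without one-to-one enforcement can
credit a single detection twice; the greedy rule avoids that and is
validated against an exhaustive optimal-assignment oracle (deviating in
<5% of random small instances and never by more than one match). Because
F1 = 2*TP / (n_detected + n_reference) under one-to-one matching, the F1
curve is provably non-increasing in the threshold.

Empty-denominator conventions: all metrics are 1 when both event sets are
empty; precision is 0 when there are detections but no matches against a
non-empty reference, and symmetrically for recall.

By-subject analysis pools all of a subject's segments: density = events per
pooled minute, duration = pooled mean. Detector and reference summaries are
related by Pearson r (with Fisher z = atanh r for cross-detector
comparison, SE = sqrt(1/(n1-3) + 1/(n2-3))) and the OLS slope of detector
on reference values.

Test-split selection draws candidate splits under the constraints (split by
subject, ten-segment subjects in training, equal younger/older test
counts), scores a pluggable detector on each candidate's test segments, and
keeps the candidate with the median F1@20% — the held-out set then neither
flatters nor punishes that reference detector. The bundled
`sigma_baseline_detector` (sigma band-pass, moving RMS, threshold at 2.5x
the median envelope, 0.5 s minimum duration) fills the pluggable role; its
threshold was calibrated once on the generator defaults and frozen.

## Synthetic data

The generator emulates the study conditions the package targets:
artifact-free 115 s N2 segments at 100 Hz, 1/f background (spectral
exponent 1, FFT-shaped Gaussian noise), spindles as Hann-windowed sinusoids
with frequency ~ U(11, 16) Hz and duration ~ U(0.5, 1.5) s — reconciling
the 0.5 s scoring minimum and the typical sub-second duration while
exercising longer events — placed uniformly with >= 0.5 s separation.
Each subject draws a density once from an equal-weight two-mode Gaussian
mixture centered at 1 and 5.25 spindles/min (SDs 0.3 and 1.0, floored at
0.2), matching the bimodal density distribution reported for
expert-consensus annotations; per-segment counts are Poisson. Burst
amplitude is `snr` times the background's in-band RMS; the default snr of 4
is a moderately salient burst, and the test suite's "high-SNR" fixtures use
10. An older cohort is emulated by scaling amplitude by 0.7 and duration by
0.85 (floored at 0.5 s) — generator conventions that reproduce the
qualitative age effect, not measured values.

What the generator does not model: real spindle morphology (chirp,
asymmetric envelopes), non-stationary background, artifacts, sleep-stage
transitions, and annotator label noise. Passing tests therefore demonstrate
that the pipeline recovers planted events under controlled conditions —
parameter recovery — not field performance on clinical recordings.

## Problem sizes used in the test suite

The parameter-recovery experiment trains the reduced model (filters
8/16/32) on 24 synthetic subjects (16 train / 4 validation / 4 held-out,
3 segments each) for at most 50 epochs; fold-stability and determinism
checks use 30 s segments and narrower models. These sizes were chosen so
the full suite runs on a single CPU in minutes while still exercising every
training-path branch; the architecture itself is the full-size default
wherever the check is structural rather than statistical.

## Known limitations

- The numpy engine is single-device and eager; it is sized for this model
  class (hundreds of thousands of parameters), not for general deep
  learning.
- Batched training assumes equal-length segments within a batch (the study
  design guarantees 115 s segments); variable-length corpora would need
  bucketing.
- EDF writing covers the single-record, 16-bit case the pipeline needs;
  it is not a general-purpose EDF+ writer (reading handles standard EDF via
  MNE).
- The greedy matcher can differ from the optimal assignment by one match in
  rare pathological overlap configurations; the oracle-equivalence test
  bounds this.
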