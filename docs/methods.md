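# Methods

## Problem and model

`memoaffect` implements a four-class emotion classifier for 14-channel EEG
recorded while a cue word triggers a 10-s autobiographical memory recall.
Each trial carries an integer self-annotation of valence and arousal on a
-4..4 grid; the sign pair maps the trial into one of the quadrants HVHA,
HVLA, LVHA, LVLA (high/low valence x high/low arousal). Annotations with a
zero on either axis belong to no quadrant and are excluded from the
four-class problem — the only symmetric rule that reproduces the existence
of unlabeled trials in the published per-word table, which the source never
defines. The underlying dataset (69 subjects, 16 affect words x 3 sessions
= 48 trials each) is available only on request, so all empirical claims
here are made on synthetic cohorts from `memoaffect.synthgen`.

The classifier is a two-stage pipeline:

1. **1D-CRNN feature extractor.** One convolution block — 16 kernels of
   length 8, stride 1, shared across the 14 channels, right zero-padding of
   7 so the 128-sample length is preserved — followed by per-kernel batch
   normalization, ReLU, size-2 stride-1 max pooling (zero-padded at the
   right edge), and dropout at p = 0.5. The resulting 14 x 128 x 16 tensor
   is flattened to 28,672 values and fed as a *single time step* into an
   LSTM with 32 units (sigmoid gates, tanh state). The single-time-step
   packaging is forced by the layer's parameter count,
   4·32 x (28,672 + 32 + 1) = 3,674,240, which fixes the LSTM input
   dimension at 28,672. A softmax head trains the network end to end
   (cross-entropy, Adam, learning rate 1e-3, batch 240, default 90 epochs);
   after training the 32-dimensional LSTM hidden state is the frozen
   feature vector. Parameter accounting: conv 16 x 9 = 144, batch norm
   16 x 2 = 32, LSTM 3,674,240, head 4 x 33 = 132.
2. **Extreme Learning Machine.** A single hidden layer of 9000 sigmoid
   neurons with input weights uniform on [-1, 1] and biases uniform on
   [0, 1], drawn once and never trained; output weights are the minimum-norm
   least-squares solution beta = pinv(H) T (SVD-based). With 32-dimensional
   inputs, H is rank-limited far below 9000 — the pseudoinverse handles
   this without regularization. An internal stratified 80:20 split of the
   training pool yields a validation accuracy that is reported but never
   used for tuning.

The network is implemented directly in NumPy — forward passes, analytic
backpropagation and Adam are written out layer by layer — so that every
stage can be checked against brute-force oracles (direct-summation
convolution, two-pass batch-norm statistics, hand-rolled LSTM gate
equations, normal-equations residual for the ELM).

## Preprocessing

Order of operations: downsample to 128 Hz (polyphase, anti-aliased) ->
common average reference -> zero-phase 1-50 Hz band-pass -> epoch ->
baseline subtraction -> per-channel z-score -> rhythm decomposition.
Per marker, the baseline is the 128 samples immediately before recall
onset and the recall epoch the 1280 samples after it; the recall period is
cut into ten 1-s segments and the baseline is subtracted from *each* of
them, so every segment keeps only activity that differs from the neutral
pre-cue second. Each 14 x 128 segment is z-scored per channel (matching
the channel-shared convolution downstream; a zero-variance channel is a
configuration error and raises, naming the channel).

Numerical choices:

- The 1-50 Hz filter is an order-8 Butterworth SOS applied
  forward-backward. The order is chosen so that mains-frequency content
  (60 Hz, representable at fs = 128) stays >= 20 dB below the 10 Hz
  passband response after the bidirectional pass; a 4th-order design only
  reaches about -15 dB there.
- Rhythm bands delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma
  30-49 Hz are zero-phase Chebyshev type-II band-passes with the published
  10 dB stopband attenuation (an unusually weak figure, implemented
  literally; the bidirectional pass doubles it to 20 dB). Stopband edges
  sit 1 Hz outside each passband edge (0.5 Hz below delta). Order 6 is the
  lowest even order that separates adjacent bands cleanly at 128 Hz. On
  1-s windows the filters use constant-value edge padding: odd-reflection
  padding injects drift-like energy into the delta band on windows
  comparable in length to the filter's impulse response.
- Batch normalization divides by sqrt(var + 1e-5). A
  `literal_variance_denominator` switch divides by (var + eps) instead,
  reproducing the normalization equation exactly as printed, for fidelity
  experiments only.
- Adam's "gradient decay factor 0.99" is mapped to the second-moment
  (squared-gradient) coefficient, the convention of the toolbox family
  that vocabulary comes from; the first moment stays at 0.9.
- Max pooling's right edge pads with zero, harmless in place because the
  input is post-ReLU and non-negative.
- Class balancing discards segments uniformly at random (seeded) down to
  the smallest class count, once, on the full segment set before any
  split — replicating the published order of operations. The leakage-safe
  alternative (balance within the training side) is available via the
  library API by balancing after splitting.

## Synthetic cohorts: what they emulate and what they do not

`synthgen` reproduces the acquisition protocol geometry exactly: per trial
a 1-s baseline, a 10-s recall, a 10-s annotation gap; 48 trials per
subject; continuous recording at a native 512 Hz so the downsampling stage
is genuinely exercised; markers at recall onsets. Annotations are drawn
per word from the published means and standard deviations
(Gaussian, rounded, clipped to [-4, 4]); an alternative categorical
sampler draws the quadrant directly from the published per-word quadrant
counts when exact marginal control matters. The published table is stored
with its row sums (207 presentations per word) and column totals
(1471 / 163 / 599 / 879 / 200) verified in tests.

Signal content is declared, not fitted: unit-variance 1/f ("pink") noise
everywhere, plus band-limited oscillations (six random-phase sinusoids per
band, phases independent across channels so common-average referencing
cannot cancel them) during recall only. Each quadrant's
:class:`ClassSignature` fixes the per-band oscillation RMS relative to the
noise floor; the default assigns each quadrant one dominant rhythm
(HVHA: beta+gamma, HVLA: alpha, LVHA: theta, LVLA: delta), scaled by a
global effect size. Effect size 0 produces a null cohort with no class
information. Inter-subject variability is a log-normal multiplicative
factor drawn per (class, band) and per subject, with configurable sigma;
it perturbs each subject's spectral signature, not merely its
signal-to-noise ratio, which is what makes subject-independent validation
measurably harder. What the generator does **not** emulate: ocular/EMG
artifacts, volume conduction and channel covariance structure,
non-stationarity within recall, word-level semantics beyond the annotation
table. Passing tests therefore demonstrate that the pipeline recovers
planted spectral class structure and behaves honestly on null data — not
that it would reach any particular accuracy on real recordings.

## Evaluation protocols and a note on leakage

Metrics follow the published conventions: confusion matrices with rows =
predicted and columns = true class; per-class one-vs-rest precision,
sensitivity, specificity and F-measure; accuracy = trace/total; undefined
ratios (zero denominator) are flagged, not reported as 0. Aggregation over
the three random 80/20 splits uses the population (divide-by-N) standard
deviation — the convention that reconciles the published per-split values
(65.64, 66.03, 65.26) with their printed mean 65.64 and std 0.31.

The replication-mode random split operates at *segment* level, which lets
sibling segments of one trial straddle the train/test boundary. Measured
on null cohorts, this is not benign: all ten segments of a trial share the
subtracted baseline (and autocorrelated background noise), so a test
segment's nearest training neighbors are its own siblings and the ELM
recalls the trial's label — about 67% "accuracy" on data containing no
class information at all. The package therefore exposes group-aware
splitting (by trial or by subject); the generator-validation tests use
trial-grouped splits, under which null cohorts sit at chance (~25%) while
separable cohorts remain near-perfect. The segment-level mode is retained
as the faithful replication of the published protocol — and this leakage
is plausibly part of why subject-independent validation looks so much
worse than random splits in the published numbers.

Leave-one-subject-out retrains the CRNN and ELM per fold (the stricter
reading of "trained on 68 subjects"). The all-band combination
concatenates the five per-band 32-dimensional feature vectors into a
160-dimensional ELM input; the source does not define "combining these
bands", and this is the package's interpretation (the broadband 1-50 Hz
pipeline is also available). The classifier-comparison harness runs ELM,
multinomial logistic regression (the softmax stand-in), SVM, kNN and
random forest on identical folds at library defaults.

## Desk-scale problem sizes

The test suite exercises the full chain at sizes a single CPU handles
comfortably: 8-subject cohorts trained 20 epochs for the
separable-vs-null contrast; 4-subject cohorts, 6-10 epochs, for the
leave-one-subject-out degradation (5 paired repetitions, one-sided paired
t-test) and the band-construct check (classes encoded only in alpha must
make the alpha-band pipeline beat the theta-band one). The replication
defaults (69 subjects, 90 epochs, 9000 hidden neurons) remain the
package defaults and run unchanged, just longer.

## Known limitations

- The single-time-step LSTM packaging makes the recurrent weight matrix
  mathematically inert (its gradient is zero from a zero initial state);
  it is kept for parameter-count fidelity. A sequence-mode variant
  (128 frames of 224 values) would be the natural extension but is not the
  replication target.
- ELM with 9000 neurons on 32-dimensional features is heavily
  over-parameterized; its behavior is interpolation-like, which is exactly
  what makes it sensitive to the sibling-segment leakage described above.
- Real-data accuracies are out of reach by construction (request-only
  dataset); no number produced on synthetic cohorts should be read as an
  estimate of them.
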