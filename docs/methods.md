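# Methods

This note documents the models, algorithms and numerical choices behind
`eegannot`, and what its synthetic experiments do and do not demonstrate.

## Problem setting

Expert annotation of artifacts in multichannel resting-state EEG is slow and
error-prone, yet it remains the ground truth ("gold standard") that automated
artifact detectors are trained on and judged against.  The package implements
a decision-support loop around a convolutional classifier:

1. train a CNN on expert-annotated 1-s EEG segments;
2. find segments where the fitted model *confidently disagrees* with the
   expert (probable annotation errors);
3. send those segments — and their temporal neighbours — to two independent
   raters, merge their decisions, and update the gold standard;
4. retrain on the revised labels.

Because clinical recordings with expert annotations are generally private,
the package ships a synthetic-data module that emulates the relevant
structure of such data, making every stage testable end to end.

## Data model

A **recording** is a `(channels x samples)` array in volts with a sampling
rate (2048 Hz by default), subject/recording identifiers, and a list of
half-open artifact intervals `[onset, onset + duration)` in seconds.
A **segment** is a 1-s window on a 0.5-s onset grid (50% overlap).  Each
segment is labelled from the intervals:

* *nonartifact* — no interval overlaps the window;
* *artifact* — some single interval overlaps it by ≥ 0.1 s, or an interval
  of duration ≤ 0.1 s overlaps it at all (brief events such as electrode
  pops count in full);
* *ignored* — only marginal (< 0.1 s) overlaps with longer intervals;
  excluded from training/evaluation, kept in an audit table.

The artifact test is per-interval; overlaps from different intervals are not
summed.  Intersections are computed in continuous seconds, before any
sampling-grid rounding, so labels are independent of the sampling rate.

## Minimal preprocessing

Signals are band-pass filtered 0.5–45 Hz with a Hamming-window linear-phase
FIR filter.  The filter length is `(3.3 * SR) / TB` rounded **up to the
nearest even integer**, where TB is the shorter of the two transition bands
(0.5 Hz at the low edge, 11.25 Hz at the high edge); at 2048 Hz this gives
13,518 taps.  Application is zero-phase up to the irreducible half-sample
delay of an even-length filter: reflection padding, one forward convolution,
then a shift of `(n_taps - 1) // 2` samples.

Nineteen standard 10–20 channels are then selected in a fixed order (Fp1,
F7, T3, T5, F3, C3, P3, O1, Fp2, F8, T4, T6, F4, C4, P4, O2, Fz, Cz, Pz);
matching is case-insensitive and accepts the modern T7/T8/P7/P8 names for
T3/T4/T5/T6.  Finally the instantaneous across-channel mean is subtracted
(common average reference).  Whether the average reference should be
computed over the original cap or over the 19 retained channels is genuinely
ambiguous in practice; the pipeline computes it over the 19 selected
channels by default and exposes the other order behind a flag
(`reref_before_select`).  Bad-channel spherical-spline interpolation is a
deliberate no-op hook: synthetic recordings declare no bad channels, and
real pipelines can substitute an external implementation.

## Time-frequency representation

Each segment is presented to the network as a Z-scored `19 x 45 x 100`
power tensor (channels x frequencies x time):

* 45 geometrically spaced frequencies, 0.5–45 Hz;
* one complex Morlet wavelet per frequency,
  `w(t) = exp(i 2 pi f t) * exp(-4 ln2 t^2 / h^2)`, where `h` is the
  envelope's full width at half maximum; `h` shrinks geometrically from
  1.2 s at 0.5 Hz to 0.2 s at 45 Hz (finer temporal resolution at higher
  frequencies).  Wavelets are truncated at ±2h (≈ ±4.7 Gaussian SDs) and
  amplitude-normalized so that a unit sinusoid at the bin frequency yields
  unit peak power;
* power is the squared magnitude of the convolution.  Convolution runs over
  the **whole recording** (a 1.2-s-FWHM wavelet has no support inside an
  isolated 1-s excerpt); the power array is then polyphase-resampled along
  time to 100 Hz with the exact rational factor `100 / SR` (a Kaiser
  β = 14 anti-aliasing window, whose flat passband preserves constants and
  ramps to ~1e-8) and sliced into 100-sample windows at the segment onsets;
* each segment's tensor is Z-scored jointly over all
  `19 x 45 x 100` elements.  No dataset-level statistics are used.

## Network

A three-stage grouped-convolution CNN over (frequency, time), with ReLU
after each convolution, max-pooling between stages, and a linear layer to
two softmax logits (no padding anywhere):

| layer            | groups | kernel | output          | parameters |
|------------------|--------|--------|-----------------|------------|
| conv + ReLU      | 19     | 1 x 5  | 950 x 45 x 96   | 5,700      |
| max-pool 2 x 2   | –      |        | 950 x 22 x 48   | 0          |
| conv + ReLU      | 50     | 5 x 5  | 1900 x 18 x 44  | 904,400    |
| max-pool 2 x 2   | –      |        | 1900 x 9 x 22   | 0          |
| conv + ReLU      | 1      | 3 x 3  | 150 x 7 x 20    | 2,565,150  |
| max-pool 1 x 1   | –      |        | 150 x 7 x 20    | 0          |
| linear (no bias) | –      |        | 2               | 42,000     |

The first convolution is fully depthwise — each EEG channel is filtered
independently — and the second remains grouped (50 groups), so early
features stay channel-local; only the third convolution mixes all channels.
Convolutions carry biases; the final linear layer does not (21,000 x 2
weights exactly).  Pooling never crosses the channel axis.  Weights use
Kaiming-uniform initialization (bound `1 / sqrt(fan_in)`), seeded.

The network is implemented directly in NumPy: im2col + BLAS sgemm per
group, with hand-written backward passes for every layer, all in float32.
Internally activations are kept channel-major `(C, B, H, W)` so that each
group's slab is contiguous and convolution outputs are written in place.
The max-pool backward recovers the winning positions by comparing the
cached input with the pooled output; ties at positive values have
probability zero on continuous activations, and tied zeros receive no
gradient anyway because the preceding ReLU's gradient mask removes them, so
the dynamics match an argmax-routed implementation.

## Training and evaluation

* **Loss** — class-weighted cross-entropy, weight `1 / n_class` computed on
  each training set, normalized by the summed applied weights (equal
  weights reduce exactly to the unweighted mean).
* **Optimizer** — averaged stochastic gradient descent (ASGD): SGD with
  decoupled decay `lambd = 1e-4`, step-size annealing
  `lr / (1 + lambd * lr * t)^0.75`, and Polyak–Ruppert tail averaging that
  activates after `t0 = 1e6` steps.  The live parameters are used for
  prediction.  Full-scale defaults: batch 64, learning rate 1e-4, 70
  cross-validation epochs, 100 final epochs.
* **Cross-validation** — subject-wise, k = 5: subjects are shuffled once
  into five holdout groups; per fold, the held-out ~20% of subjects is
  split evenly between a validation set (loss monitored each epoch, no
  model selection or early stopping) and a test set; the remaining ~80%
  train.  After the epoch loop the train and validation sets are pooled for
  exactly one additional epoch, then test metrics are computed.  No subject
  ever spans train and test.  Note that with a 20% holdout shared between
  validation and test, the five test sets are pairwise disjoint but cover
  only half the subjects; the holdouts (validation ∪ test) partition them.
* **Metrics** — sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`,
  precision `TP/(TP+FP)` and balanced accuracy
  `(sensitivity + specificity)/2`, with artifact the positive class and
  prediction = artifact iff `p ≥ 0.5`.  Undefined ratios (empty class in a
  small test set) are reported as NaN with a warning and skipped in
  mean ± SD summaries; pooled-across-folds metrics are also provided and
  are the stable aggregate at small scale.

## Revision loop

Given the final model's fitted predictions on every segment:

* candidates = nonartifact-labelled segments with `p ∈ [0.65, 1]` (putative
  false positives) ∪ artifact-labelled segments with `p ∈ [0, 0.40]`
  (putative false negatives) ∪ the immediately adjacent windows
  (onset ± 0.5 s, same recording — the only windows sharing samples with a
  selected one), regardless of probability.  Neighbours of neighbours are
  not added.
* two raters each answer keep / artifact / nonartifact / uncertain / gray.
  Merging: gray from either rater drops the segment entirely; two matching
  concrete votes (with "keep" resolving to the original label) replace the
  annotation; everything else — disagreement, or both uncertain — keeps the
  original label.  One rater uncertain plus one concrete vote counts as
  disagreement: replacement requires explicit two-rater agreement.
* inter-rater agreement is Cohen's κ = (p_o − p_e)/(1 − p_e) with chance
  agreement from the raters' marginal category counts, with the standard
  interpretive bands attached (e.g. 0.41–0.60 moderate).  κ is undefined
  (NaN) when both raters are constant and identical.
* after applying the merge, surviving segments are partitioned into
  revision-changed / revision-agreed / non-revised subsets so that any
  model can be scored on each stratum.  Reviewed segments kept through
  disagreement are counted in the "agreed" (annotation-survived) stratum.

## Probability traces

For display, overlapping-window predictions are turned into a per-sample
trace: each time sample takes the arithmetic mean of the three windows whose
centres are nearest in time (two within the first and last second of the
recording, where no third overlapping window exists).  The trace is banded
into five equal-width probability categories ([0, 0.2) … [0.8, 1.0] → 1–5).
The mean over the named window sets is the simplest interpolation
satisfying the display contract; both the operator and the band edges are
configurable.

## Synthetic data

The generator emulates 19-channel resting EEG: per-channel 1/f pink noise
(β = 1, 15 µV RMS) plus an amplitude-modulated 10-Hz alpha rhythm on
posterior channels, with artifact events from a homogeneous Poisson process
per family:

| kind     | pattern                                   | site            |
|----------|-------------------------------------------|-----------------|
| ocular   | slow squared-sine pulse, ~150 µV          | frontal         |
| muscle   | 20–45 Hz noise burst, ~60 µV              | temporal chain  |
| pop      | step offset, ~200 µV                      | single channel  |
| movement | broadband low-frequency transient, ~120 µV| all channels    |

Default rates (6, 3, 1, 1 events/min) put roughly a tenth of recording time
inside artifact intervals, leaving artifacts the minority class after
windowing.  Durations are uniform per family; onsets are uniform over
positions where the event fits, so intervals never cross the recording end.
Everything is a deterministic function of `(seed, subject_index)`, and the
event sampler is exposed separately so tests can re-draw the event process
independently of waveform rendering.

Simulated raters reproduce the true label with probability `p_agree_true`,
vote uncertain/gray with configured probabilities, and otherwise flip the
label; the two raters are independent.

**What the synthetic data is not:** it is not forward-modelled
electrophysiology — no volume conduction, no realistic spatial covariance,
no cardiac/glossokinetic artifacts, no drowsiness or maturation effects,
and its artifact classes are cleaner and more stereotyped than clinical
ones.  Passing the synthetic experiments therefore demonstrates that the
pipeline's machinery — features, network, training protocol, revision
bookkeeping — works and can learn genuinely separable structure under
subject-wise validation; it does not establish clinical-grade detection
performance.

## Scaled experiments

The shipped learning and revision experiments
(`eegannot.experiments`) run the full pipeline on one CPU in minutes,
which dictates their size.  The cross-validation study uses 10 subjects x
5-s recordings at 2048 Hz with a high-rate artifact menu (~85 usable
segments, both classes present in nearly every subject), 2
cross-validation epochs plus the pooled epoch, batch size 8, learning rate
0.05.  The learning rate is far above the full-scale default because these
runs take two orders of magnitude fewer gradient steps; it was chosen for
stable convergence at this scale.  The band-pass stage is skipped in these
runs — its 6.6-s impulse response exceeds the short recordings, and the
generator produces no out-of-band interference — while montage selection
and average referencing stay in the loop; the filter is validated
separately at full length.

The revision experiment flips 15% of gold labels, uses perfect raters on
the candidate set, and measures recovery among band-selected segments plus
balanced accuracy against the true labels before and after revision.  It
runs on 8-s recordings (~145 segments) with six final epochs: enough data
that the network cannot simply memorize the flipped labels (which would
hide them from band selection), and enough training that its disagreements
with them become confident.  Predictions in this experiment come from the
ASGD tail average over the final epoch, so the pre/post comparison
reflects the label sets rather than the noise of the last few small-batch
gradient steps.

## Known limitations

* The NumPy network targets correctness and reproducibility, not speed:
  roughly 0.1–0.3 s per training example per step on one core, so
  full-scale (tens of thousands of segments, 70–100 epochs) training is
  out of reach without a GPU framework.
* EDF/BDF support is read-only, and no EDF writer is available in the test
  environment, so that path is exercised only manually; the native
  float32 + JSON format is the canonical, fully tested container.
* Per-fold metric summaries on very small test sets can contain NaNs
  (single-class test subjects); use the pooled metrics at small scale.
* The revision merge treats "keep" as a vote for the original label and
  requires explicit two-rater agreement to change it; alternative
  conventions for uncertain-vs-concrete splits are conceivable and would
  change only `merge_decisions`.
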