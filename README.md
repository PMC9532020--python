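# eegannot

CNN-guided annotation of artifacts in multichannel resting-state EEG.

Manual annotation of EEG artifacts (eye blinks, muscle bursts, electrode
pops, movement) is the de-facto gold standard in research and clinic, but it
is slow and error-prone — and automated detectors trained against it inherit
its mistakes.  `eegannot` implements an iterative loop that uses a
convolutional classifier both to *predict* artifacts and to *improve the
gold standard itself*: the fitted model's confident disagreements with the
expert are exactly the segments worth re-examining.  It is aimed at EEG
methodologists and annotation teams who want model-guided review of interval
annotations on resting-state recordings.

## The method

Recordings (19 standard 10–20 channels, average-referenced, band-pass
filtered 0.5–45 Hz with a Hamming FIR whose length is
`(3.3 · SR)/TB` rounded up to even — 13,518 taps at 2048 Hz) are cut into
1-s segments on a 0.5-s grid.  A segment is an *artifact* if an annotated
interval overlaps it by ≥ 0.1 s (or the interval itself is ≤ 0.1 s long),
a *nonartifact* if nothing overlaps it, and *ignored* otherwise.

Each segment X⁽ⁱ⁾ becomes a Z-scored 19 × 45 × 100 Morlet-wavelet power
tensor (channels × log-spaced frequencies 0.5–45 Hz × time at 100 Hz, with
frequency-dependent FWHM time resolution 1.2 s → 0.2 s).  The classifier
f(X; θ) is a grouped-convolution CNN — depthwise 1×5 convolution per EEG
channel, a 50-group 5×5 stage, an ungrouped 3×3 stage, then a bias-free
linear layer and softmax (3,517,250 parameters in total) — trained with
class-weighted cross-entropy (weights 1/n_class) under ASGD, and evaluated
subject-wise: five folds, each holding out 20% of subjects split between
validation and test, with one extra epoch on train+validation pooled before
testing.  Performance is reported as sensitivity, specificity, precision and
balanced accuracy bAcc = (sensitivity + specificity)/2 at threshold 0.5.

For revision, a final model fitted to the whole dataset flags
nonartifact-labelled segments predicted with p ∈ [0.65, 1] and
artifact-labelled segments with p ∈ [0, 0.40], plus their temporal
neighbours.  Two raters re-annotate; agreement is summarized by Cohen's
κ = (p_o − p_e)/(1 − p_e); unanimous decisions replace labels, "gray"
votes drop segments, everything else keeps the original.  The network is
implemented from scratch in NumPy (im2col + BLAS, hand-written backprop),
so the whole loop runs anywhere Python runs.

See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

```python
from eegannot.network import build_model, count_parameters, layer_output_shapes
from eegannot.synthetic import SimConfig, generate_recording
from eegannot.segmentation import segment_recording

print(count_parameters(build_model(seed=0)))
# {'conv1': 5700, 'pool1': 0, 'conv2': 904400, 'pool2': 0,
#  'conv3': 2565150, 'pool3': 0, 'fc': 42000, 'total': 3517250}

print(layer_output_shapes()[:3])
# [(950, 45, 96), (950, 22, 48), (1900, 18, 44)]

rec = generate_recording(SimConfig(n_subjects=1, duration_s=60.0, seed=7), 0)
table = segment_recording(rec)
print(len(rec.annotations), "artifact intervals,",
      table["label"].value_counts().to_dict())
# 6 artifact intervals, {'nonartifact': 92, 'artifact': 25, 'ignored': 2}
```

The parameter counts and shape chain are the network's defining arithmetic:
e.g. conv2 has 1900 output maps each seeing 19 input maps through a 5×5
kernel (1900·19·25 + 1900 biases = 904,400 parameters).  The 60-s synthetic
recording yields 119 overlapping windows; windows overlapping an injected
event by ≥ 0.1 s are artifact segments, and the handful of marginal
overlaps are ignored rather than mislabelled.

A shell workflow is also available:

```bash
eegannot simulate --subjects 10 --duration 60 --seed 1 --out data/
eegannot segment --recordings data/ --out work/
eegannot train-cv --data work/ --epochs 70 --out runs/cv/
eegannot train-final --data work/ --out runs/final/
eegannot select-revision --predictions runs/final/predictions.csv --out review.csv
eegannot trace --predictions runs/final/predictions.csv --duration 60 --out trace.csv
```

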