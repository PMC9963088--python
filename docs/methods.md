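# Methods

This note documents the models, conventions and numerical choices behind
`vcgpeaks`, including the places where the design was genuinely open and a
choice had to be made.

## Problem and signal model

The target is a single R-peak timing per cardiac cycle, representative of
the onset of ventricular systole, in multi-lead ECG. R-peak polarity and
timing vary between leads; working on the 3-axis vectorcardiogram (VCG)
instead of individual leads removes the arbitrary choice of lead and makes
the detector independent of the acquisition montage, provided eight
independent leads (I, II, V1–V6) are available.

The VCG is obtained by the Kors regression transformation V = E·M with the
fixed 8×3 coefficient matrix M. The transform is linear, so scaling or
mixing of leads propagates predictably; the implementation refuses
12-column input rather than silently sub-selecting, because the four
augmented leads are derived quantities.

All records are resampled (polyphase, band-limited) to 500 Hz before
windowing. This rate reproduces the published per-record window counts for
30-minute recordings (439 non-overlapping 2048-sample windows) and
preserves QRS slope content (~10–25 Hz) far below Nyquist. Annotation
indices map through the same rational ratio with rounding.

## Labels and windows

Each annotated R-peak is dilated to a 5-sample run of 1s in a binary
per-sample mask; overlapping runs merge by union, and runs are truncated at
window borders rather than spilled into neighbors. Training windows tile
the record without overlap (ragged tails dropped); inference windows use
stride = length/2 so every sample of the tiled span is predicted once or
twice, and overlapping predictions are averaged per sample. Each window is
min–max scaled to [−1, 1] per channel; a constant channel maps to zeros
(warned). Per-window scaling makes inference invariant to record-level
amplitude drift.

## Network

A 1D U-Net:

* Encoder: six convolutions, kernels (9, 9, 6, 6, 3, 3), filters
  (16, 16, 32, 32, 64, 64), 'same' padding, leaky-ReLU (negative slope
  0.25). Each of the last five is followed by batch normalization and
  factor-2 max-pooling; bottleneck length = input_length/32.
* Decoder: five stride-2 transposed convolutions, kernels (3, 3, 6, 6, 9)
  and filters (64, 32, 32, 16, 16) — the exact mirror of encoder layers
  6…2 — each followed by leaky-ReLU and batch normalization, then
  concatenation with the tensor that entered the mirrored encoder
  convolution. Dropout (0.25) acts on the first decoder block only.
* Head: a kernel-9, single-filter convolution with sigmoid activation
  (mirroring the first encoder convolution, which also carries no batch
  normalization).

The published description underdetermines the decoder wiring. The wiring
above was selected because it is the unique fully mirror-symmetric
completion of the stated encoder schedule whose trainable-parameter count
equals the published figure of 79,409 (convolution kernels and biases plus
batch-norm scale/shift; running statistics excluded). The count doubles as
an architecture fingerprint and is asserted exactly in the tests; changing
the input channel count from 3 to 8 changes it by exactly (8−3)·9·16 = 720,
confirming only the first convolution touches the input.

Implementation: layers, reverse-mode gradients and the Adam optimizer are
written directly on numpy arrays (float32), with convolutions as im2col
matrix products. Weights use Xavier-uniform initialization. Transposed
convolutions crop (k−s)/2 leading samples so output length is exactly
2× input length; convolution 'same' padding puts the smaller pad on the
left. Batch-norm uses eps 1e-3 and momentum 0.99. Binary cross-entropy is
computed on logits for numerical stability. Training is bitwise
reproducible for a fixed seed on one machine.

## Training

Adam, learning rate 0.001, batch size 64, binary cross-entropy, no weight
decay, at most 500 epochs — with early stopping: training halts when the
epoch-mean **training** loss has not decreased by more than 1e-6 for 10
consecutive epochs, and the best-loss weights are restored. No validation
split is used; with ~1% positive samples the plain (unweighted) loss is
retained. Windows are reshuffled each epoch from the run seed.

Protocols: leave-one-out (per-record fold, held-out record never
contributes windows; macro and pooled aggregations both reported) and
cross-database (single model, disjoint record-id sets enforced).

## Detection rule

Candidates are samples with averaged probability strictly above 0.5. Each
candidate hill-climbs to a local maximum: step to the strictly greater
neighbor; when both neighbors are greater, to the greater of the two, ties
toward the left; a plateau maximum is represented by its leftmost sample.
This makes the rule deterministic and order-independent. A maximum
supported by at least five candidates yields one detection. No refractory
or plausibility filtering is applied afterwards — the consensus rule is the
whole post-inference logic.

## Scoring

Matching is greedy one-to-one in increasing |time difference| (ties toward
the earlier annotation), with the 75 ms tolerance compared inclusively in
seconds. A brute-force optimal-matching oracle in the tests confirms the
greedy pair count is optimal on small instances; with beats ≥ 200 ms apart
and a 75 ms window, ambiguity is rare. Detections before the first or
after the last annotation (± tolerance) are excluded, since first/last
cycles are often unannotated. Precision with zero detections is reported
as undefined (None), never 0 or 100, and excluded from macro averages with
a warning.

HRV: RR intervals are formed within records only; pooled statistics
concatenate the per-record interval lists. AVG-HR and SD-HR are the mean
and population standard deviation of instantaneous 60/RR; RMSSD is the
root mean square of successive RR differences (ms). Pooling across a
database is a convention choice (per-record averaging would weight
records equally); both per-record and pooled entry points exist.

## Pan–Tompkins baseline

The canonical 1985 cascade with the standard constants: 5–15 Hz band-pass
(zero-phase Butterworth — a deliberate deviation from the causal original
that removes filter-delay bookkeeping; the algorithm is otherwise
unchanged), five-point derivative, squaring, 150 ms moving-window
integration, adaptive dual signal/noise thresholds (blend 0.125, threshold
coefficient 0.25), 200 ms refractory period, 360 ms T-wave slope check,
search-back at 1.66× the running RR. Detections snap to the dominant
band-passed extremum within the integration span. Published single-lead
comparisons used an unspecified open-source variant, so metric gaps of a
few tenths of a percent against printed tables are expected.

## Synthetic generator

Beats are Gaussian wave templates (P, Q, R, S, T) on a 3-axis dipole —
ECGSYN-style, chosen over recorded templates for closed-form ground truth.
Defaults: 500 Hz, mean HR 60 beats/min, Gaussian RR jitter with sd 0.05 s
(truncated at ±3σ, floored at 0.3 s), R amplitude (1.2, 0.6, −0.45) mV on
(X, Y, Z). The per-beat annotation is the dipole-magnitude maximum within
±50 ms of the nominal R time, computed before noise — so ground truth is
exact by construction. Ectopic beats are premature (RR×0.6) with doubled
QRS width, inverted S and suppressed P, mimicking the extrasystole
missed-beat failure mode; pacemaker spikes are single-sample pulses 60 ms
before the QRS. The default lead projection is the Kors pseudo-inverse
M(MᵀM)⁻¹, so the Kors transform of a clean synthetic record recovers the
dipole exactly — making the generator a self-consistent oracle for the
whole VCG pipeline.

Noise is strictly additive (annotations unchanged): sinusoidal baseline
wander (default 0.33 Hz), 50 Hz powerline, broadband Gaussian, and
Hanning-windowed muscle-artifact bursts. One integer seed determines
everything; components draw from derived sub-generators.

What the generator does **not** emulate: realistic 12-lead morphology
variation between patients, non-stationary rhythm (drift, arrhythmia
runs), electrode motion artifacts, or annotation jitter of human experts.
Passing the synthetic end-to-end experiment therefore demonstrates that
the pipeline's mechanics (windowing, training, consensus extraction,
scoring) are correct and that the network can learn the segmentation task;
it does not certify clinical-grade accuracy on real Holter data.

## Experiment sizes

The end-to-end acceptance experiment uses 60 clean 60-second records
(≈3,540 beats), 40 for training and 20 held out, with the published
hyperparameters capped at 30 epochs; training converges to BCE ≈ 0.002 and
the held-out pooled F1 exceeds 99%. The same trained model is compared
against Pan–Tompkins on the test records with baseline wander (0.15 mV)
and powerline (0.05 mV) noise injected. These sizes were chosen as the
smallest at which the recovery claim is comfortably demonstrated on a
single CPU.

## Known limitations

* The decoder wiring is a reconstruction constrained by the parameter
  fingerprint, not a copy of a published layer table.
* WFDB support covers headers, signal formats 16 and 212, and MIT
  annotation streams — enough for the relevant databases and the
  package's own fixtures, not the full format family.
* The Pan–Tompkins variant is canonical, not byte-compatible with any
  specific open-source implementation.
* Training on CPU in numpy is practical at study scale (tens of minutes
  for ~10⁵ windows would be optimistic); full-database replication would
  want a GPU port of the same architecture.
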