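# Methods

## Problem

Per-cycle annotation of continuous cyclic sensor data (gait strides, other
repetitive movement) is the main cost in training segmentation and
classification models.  cycleseg implements a semi-supervised alternative:
the annotator marks only contiguous single-class sections (*primitives*) and
counts the cycles in each.  The pipeline converts those repetition counts
into per-cycle boundaries, and the models it trains along the way segment
and classify unseen continuous recordings.

## Model

Each cycle class *c* is a hidden Markov model with `n` internal states in a
strictly circular topology: state *i* can self-loop or advance to state
*i + 1*, and the last state wraps to the first, starting a new cycle.  Each
state emits feature vectors from a Gaussian mixture with diagonal
covariance (default 10 components, fitted with exactly 10 EM iterations
from a k-means start).  A cycle boundary is, by definition, an entry into
state 0.

The class models plus a small rest model (3 states) form a hierarchical
HMM.  A class may be left only through its wrap transition, and the wrap
mass is split equally over all classes' entry states (including re-entry) —
the inter-class transition model is deliberately naive and untrained, and
no class-sequence prior beyond this first-order structure exists.  Viterbi
decoding of the flat composite simultaneously segments and classifies
continuous data.

## Smart annotation

For primitives with repetition count R the loop is:

1. **Linear division** — split each primitive into R equal parts; label
   frames inside each part linearly across the internal states.
2. **Viterbi training** — per iteration: hard state assignment by
   constrained Viterbi decoding of each cycle (one full traversal of the
   circular chain, so every state keeps at least one frame per cycle);
   transition re-estimation from assigned bigram counts restricted to the
   topology; emission re-estimation by a short (3-iteration) EM
   warm-started from the previous mixtures.  The first iteration of each
   round consumes the provided labels instead of decoding — that is what
   makes the first pass semi-supervised.
3. **Forced alignment** — decode each primitive against a left-to-right
   chain of R concatenated copies of its class model (the wrap feeds the
   next copy; the path must start in the first and end in the last state of
   the chain), yielding exactly R contiguous cycles.

Training iterations per round follow the increasing schedule
`Ti = [1, 2, 5, 8, 13, 21]` — six rounds — so the model is never trained
long against a segmentation that is still poor.  All primitives of all
classes advance through the rounds together; per-class models train only on
their own class's primitives (forced alignment is intra-class by
construction, and the rounds are what couples the classes in time).  The
final forced alignment is the annotation output.

The boundary-supervised baseline (`supervised_train`) runs the identical
machinery with the segmentation pinned to given reference boundaries;
internal states are still initialized linearly and Viterbi-trained.

## Features

Per selected channel and per sample: the raw calibrated value, the windowed
variance (population formula), and the three coefficients of a
least-squares quadratic fit over the window.  Windows trail the current
sample with overlap `window − 1`, giving exactly one feature row per sample;
leading rows use truncated, refitted windows so the row count is preserved.
The polynomial abscissa is normalized to [0, 1] per window, which keeps
coefficients comparable across window lengths.  Features are standardized
per subject (zero mean, unit s.d.; s.d. floored at 1e−8) and the statistics
are retained for transforming unseen data of the same subject.  No
filtering is applied.

Defaults mirror the best configuration found on real gait data: sagittal
gyroscope (GZ) only, 0.5 s windows, 4 internal states per cyclic class.
The classical search grid (states {4, 8, 10} × windows {0.25, 0.5, 1.0} s ×
five axis combinations, 45 cells) is available through `grid_search`, with
the segmentation-error criterion for annotation models and subject-disjoint
3-fold cross-validated macro F1 for the supervised baseline.

## Synthetic data generator

The generator emulates continuous ankle-IMU recordings: six channels
(AX–AZ accelerometer with gravity on AX, GX–GZ gyroscope) at 200 Hz, with
rest / walk / run regimes.  Each cyclic class is a pattern of localized
periodic Gaussian "events" (swing and impact analogs); the dominant cyclic
component sits on GZ.  Phase 0 of every template is its minimum-motion
point, so ground-truth boundaries realize the mid-stance ("sensor
stationary") convention; keeping that stationary phase brief is what makes
the boundary physically localizable, as it is in real gait.  Per-cycle tempo
jitter is realized by resampling the template (closure stays exact),
amplitude jitter by scaling the deviation from the resting value, and
inter-regime transitions by linear cross-fades whose extents are recorded
and masked out of evaluation.

Reference conditions used by the test suite and the acceptance script:
walk cycles of 1.0 s, run cycles of 0.7 s, 12 cycles per class per subject
bounded by rest, additive white noise of s.d. 0.1 (≈ 20 dB SNR on GZ), and
for the jittered corpus 5% tempo and 5% amplitude s.d.  Segmentation
experiments use 6 subjects (12 primitives of 5–20 cycles); classification
experiments use 9 subjects in a subject-disjoint 6:3 train/test split, a
scaled-down analog of the 12:6 split used with real data.

What the generator does **not** emulate: biomechanical waveform realism,
sensor drift and saturation, orientation change, within-subject fatigue
effects, and annotator disagreement about the boundary instant.  Passing
tests therefore demonstrate the correctness and self-consistency of the
algorithms under controlled quasi-periodicity, not field performance on
real recordings.

## Numerical choices

* All probability arithmetic is in the log domain; Viterbi ties break
  toward the lowest predecessor state index (determinism).
* Emission variances are floored at 1e−3 (features are z-scored, so this is
  a 3% s.d. floor) — both a numerical guard and a brake on overconfident
  single-frame states.
* Transition counts get a +1 pseudocount on the two admissible transitions
  of every state, keeping both strictly positive; mass outside the circular
  topology is exactly zero by construction.
* Re-estimated mixtures use a 3-iteration EM warm-started from the previous
  parameters (a full 10-iteration k-means restart is used only at
  initialization).  If a state's frames no longer support the component
  count, the mixture is re-initialized with fewer components (warning); a
  state left with no frames is re-seeded from its neighbours' frames.
* Because floored variances and fixed-length EM updates make late training
  steps only approximately monotone, each round's retrained class model is
  accepted only if its forced-alignment log-probability did not decrease
  (keep-best coordinate ascent); the per-round diagnostic is therefore
  non-decreasing.
* Models persist across rounds: each round's training warm-starts from the
  previous round's model, and the first assignment of a round reuses the
  state labels carried by the previous forced alignment.
* The random seed affects only GMM initialization; everything else is
  deterministic.

## Design choices where the design was open

* **Window placement** — trailing (window ends at the current sample),
  truncated-and-refit at the edges: preserves causality and the
  one-row-per-sample contract.
* **"Raw data" feature** — interpreted as the current sample's value per
  selected channel.
* **Circular topology** — self-loop plus single forward step only; no skip
  transitions, no duration model (one-sample states are tolerated).
* **Class switching** — only at cycle completion (the wrap transition);
  entry only at a class's initial state.  This prevents mid-cycle class
  flips and makes boundaries well-defined.
* **Initial composite distribution** — uniform over all classes' entry
  states.
* **Boundary error** — measured on cycle-start boundaries of
  maximum-overlap matched pairs; within a bout the end of cycle *k* is the
  start of *k + 1*, so start boundaries carry all the information.
* **Averaging order** — metrics per person, then unweighted per class; the
  overall figure is the unweighted class mean.  Confusion rows are
  normalized to 100% per person before averaging.
* **Intervals** — 0-based, half-open `[start, end)` everywhere.

## Limitations

* Repetition counts and class labels of primitives must be supplied; the
  method neither estimates cycle counts nor splits long recordings into
  primitives automatically.
* The equal inter-class transition model is untrained by design; heavily
  imbalanced class sequences would benefit from learned transitions.
* Forced alignment guarantees exactly R cycles, so a wrong repetition count
  silently produces a wrong segmentation.
* Boundary precision is limited by the feature window: a long window
  relative to the cycle smears the evidence that localizes the boundary.
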