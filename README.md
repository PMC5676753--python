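# cycleseg

Semi-supervised segmentation and classification of cyclic wearable-sensor
signals with hierarchical hidden Markov models.

Analyzing cyclic movement data — gait strides from an ankle-worn IMU, or
any quasi-periodic single-sensor signal — normally requires per-cycle
boundary annotations, which are expensive to produce.  cycleseg needs only
*primitives*: contiguous single-class sections annotated with their class
and the number of cycle repetitions they contain.  From that it:

1. **annotates** — recovers the individual cycle boundaries inside every
   primitive ("smart annotation"), and
2. **decodes** — reuses the trained models to simultaneously segment and
   classify continuous, unseen multi-class recordings.

## Method in brief

Each cycle class is a circular hidden Markov model: `n` internal states
with self-loops, a single forward transition, and a wrap from the last
state back to the first that starts a new cycle; emissions are diagonal
Gaussian mixtures over sliding-window features (raw value, windowed
variance, quadratic-fit coefficients, standardized per subject).

Given primitives with repetition count R, the smart-annotation loop
alternates

* **Viterbi training** from the current segmentation (round 1 starts from
  a naive linear division into R equal parts), with
* **forced alignment**: Viterbi decoding against R concatenated copies of
  the class model, which can only produce paths with exactly R cycles and
  hence yields refined boundaries,

with the training-iteration schedule `Ti = [1, 2, 5, 8, 13, 21]` over six
rounds.  For continuous data, the class models plus a 3-state rest model
are assembled into a hierarchical HMM with equal, untrained inter-class
transition probabilities; one Viterbi decode of the flat composite yields
per-sample class labels and cycle boundaries at every entry into a class's
initial state.  See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
import cycleseg as cs

# synthetic ankle-IMU corpus: rest/walk/run at 200 Hz, 5% tempo jitter
recordings, truths = cs.gen_subject_pool(3, walk_cycles=12, run_cycles=12, seed=11)

config = cs.RunConfig()          # GZ axis, 0.5 s windows, 4 states, Ti schedule
features, _ = cs.normalize_per_subject({
    sid: cs.compute_features(rec, config.axes_combo, config.window_len_s)
    for sid, rec in recordings.items()
})

# primitives: class + repetition count only, no boundaries
primitives = []
for sid in ["S00", "S01"]:
    primitives += cs.gen_primitive_set(recordings[sid], truths[sid], 5, 20, seed=2)

result = cs.smart_annotate(primitives, features, config)
pairs = []
for p, est in zip(primitives, result.boundaries):
    ref = cs.reference_boundaries_for_primitive(truths[p.subject_id], p)
    pairs += cs.match_cycles(est, ref)
mean_s, sd_s = cs.segmentation_error(pairs, 200.0)
print(f"boundary error: {mean_s:.4f} +/- {sd_s:.4f} s")

# continuous decoding of the held-out subject
rest = cs.train_rest_model(
    [features[sid].values[e.start:e.end]
     for sid in ["S00", "S01"] for e in truths[sid].boundaries.of_class("rest")],
    config=config,
)
models = dict(result.trained_models, rest=rest)
out = cs.decode_continuous(cs.build_hhmm(models), features["S02"])
n = recordings["S02"].n_samples
report = cs.classification_report({
    "S02": (out.class_labels,
            truths["S02"].boundaries.per_sample_labels(n),
            truths["S02"].evaluation_mask(n))
})
print(f"macro F1: {report.overall_f1:.1f}%")
```

Output:

```
boundary error: 0.0226 +/- 0.0224 s
macro F1: 99.2%
```

The boundary error says the recovered cycle starts sit about 23 ms
(≈ 2.6% of a cycle) from the ground-truth mid-stance instants although the
training saw only repetition counts; the macro F1 is the
per-sample rest/walk/run score on a subject the models never saw, with
transition samples masked.

A command-line interface mirrors the library:

```sh
cycleseg simulate --out data --seed 4
cycleseg annotate --recording data/S00_recording.csv \
    --primitives data/S00_primitives.csv --out-labels est.csv
cycleseg evaluate --estimated est.csv --reference data/S00_labels.csv
```

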