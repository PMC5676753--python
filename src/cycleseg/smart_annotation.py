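"""Smart annotation: repetition counts → per-cycle boundaries.

The core semi-supervised loop.  Each training *primitive* is a contiguous
section of one cycle class annotated only with its class and repetition
count R.  The loop starts from a naive linear division of every primitive
into R equal parts, trains one circular HMM per class by Viterbi training,
then forced-aligns every primitive against its class model to obtain refined
boundaries, which supervise the next round.  The number of training
iterations per round follows the increasing schedule Ti = [1, 2, 5, 8, 13,
21] (six outer loops), which avoids over-fitting to the initially incorrect
uniform segmentation.  All primitives of all classes are processed jointly
in each loop.  The final forced alignment is the annotation output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix, compute_features, normalize_per_subject
from .hmm_core import (
    ClassHMM,
    forced_alignment,
    init_class_hmm,
    near_equal_partition,
    viterbi_train,
)
from .io_formats import (
    RunConfig,
    Segment,
    SegmentBoundarySet,
    SensorRecording,
    ValidationError,
)


@dataclass
class CyclePrimitive:
    """A contiguous single-class section with a known repetition count.

    The semi-supervised training unit: only the class label and the number
    of cycles are known, not where the individual cycles start and end.
    """

    recording: SensorRecording
    start: int
    end: int
    class_name: str
    repetition_count: int

    def __post_init__(self) -> None:
        if self.repetition_count < 1:
            raise ValidationError("repetition_count must be >= 1")
        if not 0 <= self.start < self.end <= self.recording.n_samples:
            raise ValidationError(
                f"interval [{self.start}, {self.end}) outside recording"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def subject_id(self) -> str:
        return self.recording.subject_id


@dataclass
class AnnotationResult:
    """Output of the smart-annotation loop."""

    boundaries: list[SegmentBoundarySet]  # one per primitive, absolute samples
    trained_models: dict[str, ClassHMM]
    loop_log_probs: list[float] = field(default_factory=list)


def linear_divide(primitive: CyclePrimitive) -> SegmentBoundarySet:
    """Divide a primitive into R contiguous near-equal intervals.

    The initial, naive segmentation: remainder samples are spread over the
    earliest intervals.  Returned in absolute sample coordinates.
    """
    R = primitive.repetition_count
    if primitive.length < R:
        raise ValidationError(
            f"primitive of {primitive.length} samples cannot hold {R} cycles"
        )
    lengths = near_equal_partition(primitive.length, R)
    entries = []
    pos = primitive.start
    for ln in lengths:
        entries.append(Segment(pos, pos + ln, primitive.class_name))
        pos += ln
    return SegmentBoundarySet(entries)


def _feat_values(features, subject_id: str) -> np.ndarray:
    fm = features[subject_id]
    return fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)


def _cycle_arrays(
    feats: np.ndarray, boundaries: SegmentBoundarySet
) -> list[np.ndarray]:
    return [feats[e.start : e.end] for e in boundaries]


def smart_annotate(
    primitives: Sequence[CyclePrimitive],
    features: Mapping[str, FeatureMatrix],
    config: RunConfig,
) -> AnnotationResult:
    """Run the full smart-annotation loop.

    ``features`` maps subject id → per-sample feature matrix of that
    subject's recording (normalized per subject); feature rows align 1:1
    with samples, so boundaries in feature coordinates are boundaries in
    sample coordinates.

    Per outer loop ℓ: every class model is Viterbi-trained for
    ``ti_schedule[ℓ]`` iterations from the current segmentations (loop 1
    uses the linear division and linear internal-state initialization), then
    every primitive is forced-aligned with its class model to produce the
    next segmentation.  The summed alignment log-probability is recorded per
    loop as a diagnostic.  The random seed affects only GMM initialization.
    """
    if not primitives:
        raise ValidationError("no primitives given")
    classes = sorted({p.class_name for p in primitives})
    seg = [linear_divide(p) for p in primitives]
    state_labels: list[list[np.ndarray] | None] = [None] * len(primitives)
    models: dict[str, ClassHMM] = {}
    cls_log_prob: dict[str, float] = {}
    loop_log_probs: list[float] = []

    def _align_all(model: ClassHMM, idxs: list[int]):
        out = []
        total = 0.0
        for i in idxs:
            p = primitives[i]
            feats = _feat_values(features, p.subject_id)[p.start : p.end]
            try:
                bset, path = forced_alignment(model, feats, p.repetition_count)
            except ValidationError as exc:
                raise ValidationError(
                    f"forced alignment failed for primitive {i} "
                    f"({p.class_name}, [{p.start},{p.end}), "
                    f"R={p.repetition_count}): {exc}"
                ) from exc
            out.append((i, bset, path))
            total += path.log_prob
        return out, total

    for li, ti in enumerate(config.ti_schedule):
        for cls in classes:
            idxs = [i for i, p in enumerate(primitives) if p.class_name == cls]
            sequences = [
                _cycle_arrays(_feat_values(features, primitives[i].subject_id), seg[i])
                for i in idxs
            ]
            cls_seed = config.seed + 7919 * classes.index(cls)
            if li == 0:
                candidate, _ = init_class_hmm(
                    sequences,
                    config.n_states,
                    cls,
                    gmm_components=config.gmm_components,
                    gmm_em_iters=config.gmm_em_iters,
                    seed=cls_seed,
                )
                if ti > 1:
                    candidate = viterbi_train(
                        candidate,
                        sequences,
                        ti - 1,
                        gmm_update_iters=config.gmm_update_iters,
                        seed=cls_seed + li,
                    )
            else:
                candidate = viterbi_train(
                    models[cls],
                    sequences,
                    ti,
                    initial_labels=[state_labels[i] for i in idxs],
                    gmm_update_iters=config.gmm_update_iters,
                    seed=cls_seed + li,
                )
            aligned, total = _align_all(candidate, idxs)
            # keep-best safeguard: with floored variances and fixed-length EM
            # updates a longer training round can slightly lower the
            # alignment score; reject such a step and keep the previous model
            if li > 0 and total < cls_log_prob[cls]:
                continue
            models[cls] = candidate
            cls_log_prob[cls] = total
            for i, bset, path in aligned:
                seg[i] = bset.shifted(primitives[i].start)
                state_labels[i] = [path.states[e.start : e.end] for e in bset]
        loop_log_probs.append(sum(cls_log_prob.values()))

    return AnnotationResult(seg, models, loop_log_probs)


def supervised_train(
    primitives: Sequence[CyclePrimitive],
    reference_boundaries: Sequence[SegmentBoundarySet],
    features: Mapping[str, FeatureMatrix],
    config: RunConfig,
) -> dict[str, ClassHMM]:
    """Boundary-supervised baseline: same machinery, fixed segmentations.

    Identical training loop to :func:`smart_annotate`, but the cycle
    boundaries are pinned to the given reference throughout (internal states
    are still linearly initialized, then Viterbi-trained).
    """
    if len(reference_boundaries) != len(primitives):
        raise ValidationError("need one boundary set per primitive")
    for p, b in zip(primitives, reference_boundaries):
        if len(b) != p.repetition_count:
            raise ValidationError(
                f"boundary set implies {len(b)} cycles but repetition_count "
                f"is {p.repetition_count}"
            )
        if b.entries[0].start != p.start or b.entries[-1].end != p.end:
            raise ValidationError("boundaries do not cover the primitive exactly")
        for a, c in zip(b.entries, b.entries[1:]):
            if a.end != c.start:
                raise ValidationError("supervised cycles must be contiguous")

    classes = sorted({p.class_name for p in primitives})
    models: dict[str, ClassHMM] = {}
    for li, ti in enumerate(config.ti_schedule):
        for cls in classes:
            idxs = [i for i, p in enumerate(primitives) if p.class_name == cls]
            sequences = [
                _cycle_arrays(
                    _feat_values(features, primitives[i].subject_id),
                    reference_boundaries[i],
                )
                for i in idxs
            ]
            cls_seed = config.seed + 7919 * classes.index(cls)
            if li == 0:
                models[cls], _ = init_class_hmm(
                    sequences,
                    config.n_states,
                    cls,
                    gmm_components=config.gmm_components,
                    gmm_em_iters=config.gmm_em_iters,
                    seed=cls_seed,
                )
                if ti > 1:
                    models[cls] = viterbi_train(
                        models[cls], sequences, ti - 1,
                        gmm_update_iters=config.gmm_update_iters,
                        seed=cls_seed + li,
                    )
            else:
                models[cls] = viterbi_train(
                    models[cls], sequences, ti,
                    gmm_update_iters=config.gmm_update_iters,
                    seed=cls_seed + li,
                )
    return models


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

_GRID_KEYS = ("n_states", "window_len_s", "axes_combo")


def expand_grid(grid: Mapping[str, Sequence], base_config: RunConfig | None = None):
    """Expand a parameter grid into concrete configurations.

    Grid keys may be any of ``n_states``, ``window_len_s`` and
    ``axes_combo``; remaining settings come from ``base_config``.
    """
    import dataclasses

    base = base_config or RunConfig()
    unknown = set(grid) - set(_GRID_KEYS)
    if unknown:
        raise ValidationError(f"unknown grid keys: {sorted(unknown)}")
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValidationError("grid must be non-empty")
    keys = [k for k in _GRID_KEYS if k in grid]
    configs = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        configs.append(dataclasses.replace(base, **dict(zip(keys, combo))))
    return configs


def reference_boundaries_for_primitive(truth, primitive: CyclePrimitive) -> SegmentBoundarySet:
    """True per-cycle boundaries of the cycles a primitive covers."""
    entries = [
        e
        for e in truth.boundaries
        if e.class_name == primitive.class_name
        and e.start >= primitive.start
        and e.end <= primitive.end
    ]
    return SegmentBoundarySet(entries)


def _featurize_subjects(
    recordings: Mapping[str, SensorRecording], config: RunConfig
):
    raw = {
        sid: compute_features(rec, config.axes_combo, config.window_len_s)
        for sid, rec in recordings.items()
    }
    normalized, stats = normalize_per_subject(raw)
    return normalized, stats


def grid_search(
    primitives: Sequence[CyclePrimitive],
    recordings: Mapping[str, SensorRecording],
    grid: Mapping[str, Sequence],
    criterion: str,
    truths: Mapping[str, "GroundTruth"],
    base_config: RunConfig | None = None,
) -> tuple[RunConfig, pd.DataFrame]:
    """Evaluate every grid cell and return the best configuration.

    ``criterion``:

    * ``"segmentation_error"`` — smart-annotate the primitives and score the
      mean absolute cycle-start boundary error against the ground truth
      (lower is better); model selection as used for the annotation task.
    * ``"f1_cv3"`` — subject-disjoint 3-fold cross-validation: per fold, a
      boundary-supervised model (plus rest model) is trained on two thirds
      of the subjects and the continuous recordings of the held-out third
      are decoded; the criterion is the macro F1 over classes, averaged over
      folds (higher is better).
    """
    from .evaluation import classification_report, match_cycles, segmentation_error
    from .hierarchical import build_hhmm, decode_continuous, train_rest_model

    if criterion not in ("segmentation_error", "f1_cv3"):
        raise ValidationError(f"unknown criterion {criterion!r}")
    configs = expand_grid(grid, base_config)
    rows = []

    subjects = sorted({p.subject_id for p in primitives})
    if criterion == "f1_cv3" and len(subjects) < 3:
        raise ValidationError("f1_cv3 needs at least 3 subjects")

    for config in configs:
        feats, _ = _featurize_subjects(recordings, config)
        if criterion == "segmentation_error":
            result = smart_annotate(primitives, feats, config)
            pairs = []
            for p, est in zip(primitives, result.boundaries):
                ref = reference_boundaries_for_primitive(truths[p.subject_id], p)
                pairs.extend(match_cycles(est, ref))
            value, _ = segmentation_error(
                pairs, next(iter(recordings.values())).sampling_rate
            )
        else:
            fold_f1 = []
            for fold in range(3):
                held = set(subjects[fold::3])
                train_prims = [p for p in primitives if p.subject_id not in held]
                refs = [
                    reference_boundaries_for_primitive(truths[p.subject_id], p)
                    for p in train_prims
                ]
                models = supervised_train(train_prims, refs, feats, config)
                rest_segs = [
                    feats[sid].values[e.start : e.end]
                    for sid in sorted({p.subject_id for p in train_prims})
                    for e in truths[sid].boundaries.of_class("rest")
                ]
                if rest_segs:
                    models["rest"] = train_rest_model(
                        rest_segs, n_states=config.n_rest_states, config=config
                    )
                hhmm = build_hhmm(models)
                per_person = {}
                for sid in sorted(held):
                    decode = decode_continuous(hhmm, feats[sid])
                    n = recordings[sid].n_samples
                    ref_labels = truths[sid].boundaries.per_sample_labels(n)
                    mask = truths[sid].evaluation_mask(n)
                    per_person[sid] = (decode.class_labels, ref_labels, mask)
                report = classification_report(per_person)
                fold_f1.append(report.overall_f1)
            value = float(np.mean(fold_f1))
        rows.append(
            {
                "n_states": config.n_states,
                "window_len_s": config.window_len_s,
                "axes_combo": "".join(config.axes_combo),
                "criterion": criterion,
                "value": value,
            }
        )
    report_df = pd.DataFrame(rows)
    values = report_df["value"].to_numpy()
    best_idx = int(np.argmin(values)) if criterion == "segmentation_error" else int(np.argmax(values))
    return configs[best_idx], report_df
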