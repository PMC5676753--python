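"""Evaluation metrics: boundary errors and per-sample classification.

Estimated cycles are matched to reference cycles by greatest overlap; only
matched pairs enter the boundary and duration errors (spurious or missed
cycles show up in the classification metrics instead, and — because cycles
within a bout are contiguous — as large duration errors on their
neighbours).  Classification metrics are computed per sample, for each test
person separately, then averaged per class over persons; the overall column
is the unweighted class mean.  Confusion matrices are row-normalized to
100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import Segment, SegmentBoundarySet, ValidationError


@dataclass(frozen=True)
class MatchedCyclePair:
    """An estimated cycle paired with its maximum-overlap reference cycle."""

    estimated: Segment
    reference: Segment
    overlap_samples: int


def _overlap(a: Segment, b: Segment) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def match_cycles(
    estimated: SegmentBoundarySet, reference: SegmentBoundarySet
) -> list[MatchedCyclePair]:
    """Greedy maximum-overlap one-to-one matching of cycles.

    When two estimated cycles overlap one reference cycle, only the one with
    the larger overlap is retained (and symmetrically), so each cycle
    appears in at most one pair.  Ties break on earlier reference, then
    earlier estimate.  Pairs are returned in reference order.
    """
    candidates = []
    for ref in reference:
        for est in estimated:
            ov = _overlap(est, ref)
            if ov > 0:
                candidates.append((ov, ref, est))
    candidates.sort(key=lambda t: (-t[0], t[1].start, t[2].start))
    used_ref: set[tuple[int, int]] = set()
    used_est: set[tuple[int, int]] = set()
    pairs = []
    for ov, ref, est in candidates:
        rk, ek = (ref.start, ref.end), (est.start, est.end)
        if rk in used_ref or ek in used_est:
            continue
        used_ref.add(rk)
        used_est.add(ek)
        pairs.append(MatchedCyclePair(est, ref, ov))
    pairs.sort(key=lambda p: p.reference.start)
    return pairs


def segmentation_error(
    pairs: Sequence[MatchedCyclePair], sampling_rate: float
) -> tuple[float, float]:
    """Mean ± s.d. absolute cycle-start boundary error in seconds."""
    if not pairs:
        raise ValidationError("no matched pairs")
    errs = np.array(
        [abs(p.estimated.start - p.reference.start) for p in pairs], dtype=float
    ) / sampling_rate
    return float(errs.mean()), float(errs.std())


def duration_error(
    pairs: Sequence[MatchedCyclePair], sampling_rate: float
) -> tuple[float, float]:
    """Mean ± s.d. absolute cycle-duration (stride-time) error in seconds."""
    if not pairs:
        raise ValidationError("no matched pairs")
    errs = np.array(
        [abs(p.estimated.length - p.reference.length) for p in pairs], dtype=float
    ) / sampling_rate
    return float(errs.mean()), float(errs.std())


@dataclass
class EvaluationReport:
    """Per-class classification metrics (percentages)."""

    classes: tuple[str, ...]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    f1: dict[str, float]
    overall_sensitivity: float
    overall_specificity: float
    overall_f1: float
    confusion: pd.DataFrame  # row-normalized to 100%
    per_person: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"{'':12s}" + "".join(f"{c:>12s}" for c in ("overall",) + self.classes)
        ]
        for name, overall, per in (
            ("sensitivity", self.overall_sensitivity, self.sensitivity),
            ("specificity", self.overall_specificity, self.specificity),
            ("f1", self.overall_f1, self.f1),
        ):
            vals = [overall] + [per[c] for c in self.classes]
            lines.append(f"{name:12s}" + "".join(f"{v:12.1f}" for v in vals))
        return "\n".join(lines)


def _person_metrics(est, ref, classes):
    out = {}
    for c in classes:
        tp = int(np.sum((est == c) & (ref == c)))
        fn = int(np.sum((est != c) & (ref == c)))
        fp = int(np.sum((est == c) & (ref != c)))
        tn = int(np.sum((est != c) & (ref != c)))
        if tp + fn == 0:
            continue  # class absent for this person
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp > 0 else 0.0
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
        out[c] = (100 * sens, 100 * spec, 100 * f1)
    return out


def classification_report(
    per_person: Mapping[str, tuple],
) -> EvaluationReport:
    """Per-sample classification metrics, averaged per person then per class.

    ``per_person`` maps person id → ``(est_labels, ref_labels)`` or
    ``(est_labels, ref_labels, mask)`` where all three are per-sample arrays
    of equal length; masked-out samples (transitions, unsure annotations)
    are excluded.  Classes absent from a person's reference are skipped for
    that person with a warning.
    """
    if not per_person:
        raise ValidationError("no persons given")
    cleaned = {}
    for person, item in per_person.items():
        est, ref = np.asarray(item[0], dtype=object), np.asarray(item[1], dtype=object)
        if est.shape != ref.shape:
            raise ValidationError(f"label length mismatch for person {person!r}")
        keep = np.ones(est.shape[0], dtype=bool)
        if len(item) > 2 and item[2] is not None:
            keep &= np.asarray(item[2], dtype=bool)
        keep &= ref != ""
        cleaned[person] = (est[keep], ref[keep])

    classes = tuple(
        sorted({str(c) for _, ref in cleaned.values() for c in np.unique(ref)})
    )
    all_labels = tuple(
        sorted(
            set(classes)
            | {str(c) for est, _ in cleaned.values() for c in np.unique(est)}
        )
    )

    per_person_metrics = {}
    conf_rows: dict[str, list[np.ndarray]] = {c: [] for c in classes}
    for person, (est, ref) in cleaned.items():
        metrics = _person_metrics(est, ref, classes)
        missing = set(classes) - set(metrics)
        if missing:
            warnings.warn(
                f"classes {sorted(missing)} absent for person {person!r}; skipped",
                stacklevel=2,
            )
        per_person_metrics[person] = metrics
        for c in metrics:
            sel = ref == c
            row = np.array([np.sum(est[sel] == lab) for lab in all_labels], dtype=float)
            conf_rows[c].append(100 * row / row.sum())

    sensitivity, specificity, f1 = {}, {}, {}
    for c in classes:
        vals = [m[c] for m in per_person_metrics.values() if c in m]
        if not vals:
            raise ValidationError(f"class {c!r} absent for every person")
        arr = np.array(vals)
        sensitivity[c], specificity[c], f1[c] = arr.mean(axis=0)
    confusion = pd.DataFrame(
        [np.mean(conf_rows[c], axis=0) for c in classes],
        index=list(classes),
        columns=list(all_labels),
    )
    return EvaluationReport(
        classes=classes,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        overall_sensitivity=float(np.mean(list(sensitivity.values()))),
        overall_specificity=float(np.mean(list(specificity.values()))),
        overall_f1=float(np.mean(list(f1.values()))),
        confusion=confusion,
        per_person=per_person_metrics,
    )
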