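"""Hierarchical HMM: class-level transitions over per-class cycle models.

Trained class models (plus a small rest model) are assembled into one
composite state space.  Inter-class transitions are naive: a class may be
left only through its wrap transition (cycle completion), and the wrap mass
is divided equally over all classes' initial states, including re-entering
the same class — no class-sequence prior beyond these first-order equal
transitions is imposed.  Viterbi decoding of the composite simultaneously
segments and classifies continuous, unseen data: the class label per sample
comes from the owning class model and cycle boundaries are entries into a
class's initial state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import FeatureMatrix
from .hmm_core import (
    ClassHMM,
    StatePath,
    init_class_hmm,
    viterbi_dense,
    viterbi_train,
)
from .io_formats import RunConfig, Segment, SegmentBoundarySet, ValidationError

NEG_INF = -np.inf


def train_rest_model(
    rest_segments: Sequence[np.ndarray],
    n_states: int = 3,
    config: RunConfig | None = None,
    n_iterations: int = 5,
) -> ClassHMM:
    """Train the rest (standing) model with the usual training machinery.

    Rest has no repetition structure; each contiguous rest segment is
    treated as a single "cycle" through a small linear-initialized chain
    (three states by default).
    """
    if not rest_segments:
        raise ValidationError("no rest segments given")
    config = config or RunConfig()
    sequences = [[np.atleast_2d(np.asarray(s, dtype=float))] for s in rest_segments]
    hmm, _ = init_class_hmm(
        sequences,
        n_states,
        "rest",
        gmm_components=config.gmm_components,
        gmm_em_iters=config.gmm_em_iters,
        seed=config.seed + 104729,
    )
    if n_iterations > 0:
        hmm = viterbi_train(
            hmm,
            sequences,
            n_iterations,
            gmm_update_iters=config.gmm_update_iters,
            seed=config.seed + 104729,
        )
    return hmm


@dataclass
class HierarchicalHMM:
    """Composite model over all cycle classes."""

    class_models: dict[str, ClassHMM]
    class_order: tuple[str, ...]
    class_log_transitions: np.ndarray  # (C, C), rows normalize

    def __post_init__(self) -> None:
        self.class_log_transitions = np.asarray(
            self.class_log_transitions, dtype=float
        )
        C = len(self.class_order)
        if self.class_log_transitions.shape != (C, C):
            raise ValidationError("class transition matrix shape mismatch")
        rows = np.exp(self.class_log_transitions).sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValidationError("class transition rows must sum to 1")
        dims = {m.n_features for m in self.class_models.values()}
        if len(dims) != 1:
            raise ValidationError("class models disagree on feature dimension")

    @property
    def n_states(self) -> int:
        return sum(self.class_models[c].n_states for c in self.class_order)

    def state_offsets(self) -> dict[str, int]:
        offsets = {}
        pos = 0
        for c in self.class_order:
            offsets[c] = pos
            pos += self.class_models[c].n_states
        return offsets

    def composite_log_transitions(self) -> np.ndarray:
        """Flat expansion of the hierarchy into one stochastic matrix.

        Within a class: the circular topology minus its wrap transition.
        The wrap mass of each class's last state is divided equally over all
        classes' initial states (a class may only be left — or re-entered —
        at cycle completion).
        """
        S = self.n_states
        C = len(self.class_order)
        log_A = np.full((S, S), NEG_INF)
        offsets = self.state_offsets()
        for c in self.class_order:
            m = self.class_models[c]
            off = offsets[c]
            n = m.n_states
            for i in range(n):
                log_A[off + i, off + i] = m.log_transitions[i, i]
                if i + 1 < n:
                    log_A[off + i, off + i + 1] = m.log_transitions[i, i + 1]
            wrap = m.log_transitions[n - 1, 0]
            for ci, c2 in enumerate(self.class_order):
                log_A[off + n - 1, offsets[c2]] = (
                    wrap + self.class_log_transitions[self.class_order.index(c), ci]
                )
        return log_A

    def composite_log_init(self) -> np.ndarray:
        """Uniform over all classes' initial states."""
        log_init = np.full(self.n_states, NEG_INF)
        offsets = self.state_offsets()
        for c in self.class_order:
            log_init[offsets[c]] = -np.log(len(self.class_order))
        return log_init


def build_hhmm(
    class_models: Mapping[str, ClassHMM], equal_transitions: bool = True
) -> HierarchicalHMM:
    """Assemble class models into a hierarchical model.

    With ``equal_transitions`` all possible successor classes (including
    staying in the current class) are given equal probability — naively
    initiated and not trained.
    """
    if not class_models:
        raise ValidationError("need at least one class model")
    order = tuple(sorted(class_models))
    C = len(order)
    if not equal_transitions:
        raise NotImplementedError("only equal class transitions are supported")
    class_log_transitions = np.full((C, C), -np.log(C))
    return HierarchicalHMM(dict(class_models), order, class_log_transitions)


@dataclass
class DecodeResult:
    """Simultaneous segmentation and classification of a continuous signal."""

    cycles: SegmentBoundarySet  # one entry per decoded cycle / rest visit
    bouts: SegmentBoundarySet  # contiguous same-class cycles merged
    path: StatePath  # composite state indices
    class_labels: np.ndarray  # class name per sample


def decode_continuous(hhmm: HierarchicalHMM, features) -> DecodeResult:
    """Viterbi-decode a continuous recording against the composite model.

    Every sample receives exactly one class label.  A new cycle starts at
    every entry into a class's initial state (from the same class's wrap or
    from another class).
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    values = np.atleast_2d(values)
    if values.shape[0] == 0:
        raise ValidationError("empty input")
    log_B = np.hstack(
        [hhmm.class_models[c].emission_log_probs(values) for c in hhmm.class_order]
    )
    path = viterbi_dense(
        hhmm.composite_log_init(), hhmm.composite_log_transitions(), log_B
    )
    offsets = hhmm.state_offsets()
    bounds_sorted = sorted(offsets.items(), key=lambda kv: kv[1])
    edges = np.array([v for _, v in bounds_sorted] + [hhmm.n_states])
    names = [k for k, _ in bounds_sorted]
    class_idx = np.searchsorted(edges, path.states, side="right") - 1
    class_labels = np.array([names[i] for i in class_idx], dtype=object)

    init_states = {offsets[c] for c in hhmm.class_order}
    T = values.shape[0]
    starts = [0]
    for t in range(1, T):
        if path.states[t] in init_states and path.states[t] != path.states[t - 1]:
            starts.append(t)
    starts.append(T)
    entries = [
        Segment(a, b, str(class_labels[a])) for a, b in zip(starts, starts[1:])
    ]
    cycles = SegmentBoundarySet(entries)
    return DecodeResult(
        cycles=cycles,
        bouts=cycles.merged_bouts(),
        path=path,
        class_labels=class_labels,
    )
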