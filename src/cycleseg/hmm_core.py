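"""Circular hidden Markov models with diagonal-covariance GMM emissions.

One :class:`ClassHMM` models one class of cycle (e.g. a walking stride).  Its
internal-state topology is strictly circular: state *i* may only self-loop or
advance to state *i + 1*, and the last state wraps to the first, beginning a
new cycle.  Parameters are learned by Viterbi training (hard state
assignments from the best path, followed by count-based transition updates
and short warm-started EM updates of the per-state mixtures).  Segmenting a
section known to contain *R* repetitions is done by forced alignment: Viterbi
decoding against a left-to-right chain of *R* concatenated copies of the
model, which can only produce paths with exactly *R* full cycles.

All probability arithmetic is in the log domain.  Viterbi ties are broken
toward the lowest predecessor state index so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .io_formats import Segment, SegmentBoundarySet, ValidationError

VAR_FLOOR = 1e-3  # on per-subject standardized features (unit variance)
_TRANS_PSEUDOCOUNT = 1.0

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------


@dataclass
class GaussianMixtureDiag:
    """Diagonal-covariance Gaussian mixture over feature vectors."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, D)
    variances: np.ndarray  # (K, D)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-8):
            raise ValidationError("mixture weights must sum to 1")
        if np.any(self.variances < VAR_FLOOR * (1 - 1e-12)):
            self.variances = np.maximum(self.variances, VAR_FLOOR)

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def log_pdf(self, X: np.ndarray) -> np.ndarray:
        """Log density of each row of ``X`` (shape ``(T, D)``)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"observation dimension {X.shape[1]} != model {self.n_features}"
            )
        # (T, K): log w_k + log N(x | mu_k, diag(var_k))
        diff = X[:, None, :] - self.means[None, :, :]
        log_norm = -0.5 * np.sum(np.log(2 * np.pi * self.variances), axis=1)
        quad = -0.5 * np.sum(diff * diff / self.variances[None, :, :], axis=2)
        logc = np.log(self.weights)[None, :] + log_norm[None, :] + quad
        return logsumexp(logc, axis=1)


def _from_sklearn(gm: GaussianMixture) -> GaussianMixtureDiag:
    return GaussianMixtureDiag(
        gm.weights_.copy(), gm.means_.copy(), np.maximum(gm.covariances_, VAR_FLOOR)
    )


def init_gmm(
    data: np.ndarray,
    n_components: int = 10,
    em_iters: int = 10,
    seed: int = 0,
    allow_reduce: bool = True,
    track_loglik: bool = False,
):
    """Fit a diagonal GMM with a fixed number of EM iterations.

    EM is run for exactly ``em_iters`` iterations from a k-means
    initialization (no early stopping).  If the data hold fewer frames than
    components, the component count is reduced with a warning when
    ``allow_reduce`` is set, otherwise an error is raised.  With
    ``track_loglik`` the EM is stepped one iteration at a time and the mean
    per-frame log-likelihood after each iteration is returned alongside the
    mixture.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    if n < n_components:
        if not allow_reduce:
            raise ValidationError(
                f"{n} frames < {n_components} mixture components"
            )
        warnings.warn(
            f"reducing GMM components from {n_components} to {n} (few frames)",
            stacklevel=2,
        )
        n_components = max(1, n)
    kwargs = dict(
        n_components=n_components,
        covariance_type="diag",
        tol=0.0,
        reg_covar=VAR_FLOOR,
        init_params="kmeans",
        n_init=1,
        random_state=int(seed) % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if not track_loglik:
            gm = GaussianMixture(max_iter=em_iters, **kwargs)
            gm.fit(data)
            return _from_sklearn(gm)
        gm = GaussianMixture(max_iter=1, warm_start=True, **kwargs)
        loglik = []
        for _ in range(em_iters):
            gm.fit(data)
            loglik.append(float(_from_sklearn(gm).log_pdf(data).mean()))
    return _from_sklearn(gm), np.array(loglik)


def refit_gmm(
    gmm: GaussianMixtureDiag,
    data: np.ndarray,
    em_iters: int = 3,
    seed: int = 0,
) -> GaussianMixtureDiag:
    """Short EM update warm-started from an existing mixture.

    Used inside Viterbi training to re-estimate a state's emission model on
    its newly assigned frames.  If the frames no longer support the current
    component count, the mixture is re-initialized with fewer components.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < gmm.n_components:
        return init_gmm(data, gmm.n_components, em_iters=em_iters, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm = GaussianMixture(
            n_components=gmm.n_components,
            covariance_type="diag",
            tol=0.0,
            reg_covar=VAR_FLOOR,
            max_iter=em_iters,
            weights_init=gmm.weights / gmm.weights.sum(),
            means_init=gmm.means,
            precisions_init=1.0 / gmm.variances,
            random_state=int(seed) % (2**31),
        )
        gm.fit(data)
    return _from_sklearn(gm)


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class ClassHMM:
    """Circular-topology HMM for one cycle class."""

    class_name: str
    n_states: int
    log_transitions: np.ndarray  # (n, n); mass only on self and next (mod n)
    emissions: list  # one GaussianMixtureDiag per state

    def __post_init__(self) -> None:
        self.log_transitions = np.asarray(self.log_transitions, dtype=float)
        if self.log_transitions.shape != (self.n_states, self.n_states):
            raise ValidationError("transition matrix shape mismatch")
        if len(self.emissions) != self.n_states:
            raise ValidationError("need one emission model per state")
        check_circular_topology(self.log_transitions)

    @property
    def n_features(self) -> int:
        return self.emissions[0].n_features

    def emission_log_probs(self, obs: np.ndarray) -> np.ndarray:
        """Per-frame emission log density under every state: ``(T, n)``."""
        obs = np.atleast_2d(np.asarray(obs, dtype=float))
        return np.column_stack([g.log_pdf(obs) for g in self.emissions])

    def self_loop_probs(self) -> np.ndarray:
        return np.exp(np.diag(self.log_transitions))


@dataclass
class StatePath:
    """Best internal-state sequence and its joint log-likelihood."""

    states: np.ndarray
    log_prob: float


def check_circular_topology(log_A: np.ndarray) -> None:
    n = log_A.shape[0]
    rows = np.exp(log_A)
    if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("transition rows must sum to 1")
    mask = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    mask[idx, idx] = True
    mask[idx, (idx + 1) % n] = True
    if np.any(rows[~mask] > 0):
        raise ValidationError("transition mass outside circular topology")


def circular_log_transitions(self_probs: np.ndarray) -> np.ndarray:
    """Build a circular log-transition matrix from self-loop probabilities."""
    self_probs = np.asarray(self_probs, dtype=float)
    n = self_probs.shape[0]
    log_A = np.full((n, n), NEG_INF)
    idx = np.arange(n)
    with np.errstate(divide="ignore"):
        log_A[idx, idx] = np.log(self_probs)
        log_A[idx, (idx + 1) % n] = np.log(1.0 - self_probs)
    return log_A


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def viterbi_dense(
    log_init: np.ndarray,
    log_A: np.ndarray,
    log_B: np.ndarray,
    end_states: Sequence[int] | None = None,
) -> StatePath:
    """Generic log-domain Viterbi over a dense transition matrix.

    Ties are broken toward the lowest predecessor (and final) state index.
    ``end_states`` restricts which states the path may terminate in.
    """
    T, S = log_B.shape
    delta = log_init + log_B[0]
    psi = np.empty((T, S), dtype=np.int32)
    for t in range(1, T):
        scores = delta[:, None] + log_A  # (from, to)
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(S)] + log_B[t]
    if end_states is not None:
        mask = np.full(S, NEG_INF)
        mask[list(end_states)] = 0.0
        delta = delta + mask
    last = int(np.argmax(delta))
    if not np.isfinite(delta[last]):
        raise ValidationError("no admissible state path (infeasible decode)")
    states = np.empty(T, dtype=np.int32)
    states[-1] = last
    for t in range(T - 1, 0, -1):
        states[t - 1] = psi[t, states[t]]
    return StatePath(states=states, log_prob=float(delta[last]))


def viterbi_decode(
    hmm: ClassHMM, obs: np.ndarray, start_state: int | None = None
) -> StatePath:
    """Most probable internal-state sequence for one class model.

    The initial distribution is uniform over states unless ``start_state``
    pins the first frame (used when decoding from a known cycle start).
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if obs.shape[0] == 0:
        raise ValidationError("empty observation sequence")
    log_B = hmm.emission_log_probs(obs)
    if start_state is None:
        log_init = np.full(hmm.n_states, -np.log(hmm.n_states))
    else:
        log_init = np.full(hmm.n_states, NEG_INF)
        log_init[start_state] = 0.0
    return viterbi_dense(log_init, hmm.log_transitions, log_B)


def _expanded_chain(hmm: ClassHMM, R: int) -> np.ndarray:
    """Left-to-right chain of R copies of the circular model.

    The wrap transition of copy r feeds the first state of copy r + 1; the
    final copy has no exit, which forces any admissible path to contain
    exactly R full cycles.
    """
    n = hmm.n_states
    S = R * n
    log_A = np.full((S, S), NEG_INF)
    for r in range(R):
        off = r * n
        for i in range(n):
            log_A[off + i, off + i] = hmm.log_transitions[i, i]
            if i + 1 < n:
                log_A[off + i, off + i + 1] = hmm.log_transitions[i, i + 1]
            elif r + 1 < R:
                log_A[off + i, off + n] = hmm.log_transitions[i, 0]
    return log_A


def forced_alignment(
    hmm: ClassHMM, obs: np.ndarray, repetition_count: int
) -> tuple[SegmentBoundarySet, StatePath]:
    """Segment ``obs`` into exactly R cycles by constrained Viterbi decoding.

    The path starts in the first state of the first copy and must end in the
    last state of the last copy, so it traverses all R copies.  Cycle
    boundary *k* is the first frame assigned to copy *k*.  Returns the R
    contiguous cycle intervals (frame coordinates, covering ``[0, T)``) and
    the internal-state path (copy-folded indices).
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    T = obs.shape[0]
    R = int(repetition_count)
    n = hmm.n_states
    if R < 1:
        raise ValidationError("repetition_count must be >= 1")
    if T < R * n:
        raise ValidationError(
            f"{T} frames cannot hold {R} cycles of {n} states each"
        )
    log_B = np.tile(hmm.emission_log_probs(obs), (1, R))
    log_A = _expanded_chain(hmm, R)
    S = R * n
    log_init = np.full(S, NEG_INF)
    log_init[0] = 0.0
    path = viterbi_dense(log_init, log_A, log_B, end_states=[S - 1])
    copies = path.states // n
    bounds = [int(np.argmax(copies >= r)) for r in range(R)] + [T]
    entries = [
        Segment(bounds[r], bounds[r + 1], hmm.class_name) for r in range(R)
    ]
    folded = StatePath(states=path.states % n, log_prob=path.log_prob)
    return SegmentBoundarySet(entries), folded


# ---------------------------------------------------------------------------
# initialization and training
# ---------------------------------------------------------------------------


def near_equal_partition(total: int, k: int) -> list[int]:
    """Split ``total`` into k near-equal integer parts, remainder first."""
    base, rem = divmod(total, k)
    return [base + 1 if i < rem else base for i in range(k)]


def linear_state_init(cycle_segments, n_states: int) -> list[np.ndarray]:
    """Linear (uniform-in-time) internal-state labeling of each cycle.

    Each cycle's frames are divided into ``n_states`` contiguous runs of
    near-equal length (remainder spread over the earliest runs), labeled
    ``0 .. n_states − 1`` in order.
    """
    labels = []
    for seg in cycle_segments:
        length = seg if isinstance(seg, (int, np.integer)) else np.asarray(seg).shape[0]
        if length < n_states:
            raise ValidationError(
                f"cycle of {length} frames shorter than {n_states} states"
            )
        runs = near_equal_partition(int(length), n_states)
        labels.append(np.repeat(np.arange(n_states), runs).astype(np.int32))
    return labels


def _transitions_from_labels(
    label_sequences: Sequence[Sequence[np.ndarray]], n_states: int
) -> np.ndarray:
    """Count state bigrams (circular topology only) and normalize.

    ``label_sequences`` is nested per primitive → per cycle; cycles within a
    primitive are contiguous, so the junction between consecutive cycles
    contributes a (typically wrap) bigram.  A pseudocount keeps both allowed
    transitions of every state strictly positive.
    """
    counts = np.zeros((n_states, 2))  # [:, 0] self, [:, 1] next
    for cycles in label_sequences:
        seq = np.concatenate([np.asarray(c) for c in cycles])
        a, b = seq[:-1], seq[1:]
        self_mask = a == b
        next_mask = b == (a + 1) % n_states
        np.add.at(counts[:, 0], a[self_mask], 1)
        np.add.at(counts[:, 1], a[next_mask], 1)
    counts += _TRANS_PSEUDOCOUNT
    self_probs = counts[:, 0] / counts.sum(axis=1)
    return circular_log_transitions(self_probs)


def init_class_hmm(
    sequences: Sequence[Sequence[np.ndarray]],
    n_states: int,
    class_name: str,
    gmm_components: int = 10,
    gmm_em_iters: int = 10,
    seed: int = 0,
) -> tuple[ClassHMM, list[list[np.ndarray]]]:
    """Build a class model from linearly state-initialized cycle segments.

    ``sequences`` is nested per primitive → per cycle feature array.  This
    performs the first, label-driven training pass: linear state labels,
    count-based transitions, and full k-means + EM initialization of every
    state's mixture.  Returns the model and the labels used.
    """
    all_cycles = [c for cycles in sequences for c in cycles]
    if not all_cycles:
        raise ValidationError("no cycles to initialize from")
    labels = [linear_state_init(cycles, n_states) for cycles in sequences]
    log_A = _transitions_from_labels(labels, n_states)
    emissions = []
    for s in range(n_states):
        frames = np.vstack(
            [
                c[l == s]
                for cycles, labs in zip(sequences, labels)
                for c, l in zip(cycles, labs)
            ]
        )
        emissions.append(
            init_gmm(
                frames,
                n_components=gmm_components,
                em_iters=gmm_em_iters,
                seed=seed + 1009 * s,
            )
        )
    hmm = ClassHMM(class_name, n_states, log_A, emissions)
    return hmm, labels


def assign_states(
    hmm: ClassHMM,
    sequences: Sequence[Sequence[np.ndarray]],
    assignment: str = "cycle",
) -> tuple[list[list[np.ndarray]], float]:
    """Hard Viterbi state assignment of every segment.

    With ``assignment="cycle"`` each segment is a single cycle and is decoded
    against one full traversal of the circular model (forced alignment with
    R = 1), so every state receives at least one frame per cycle.  With
    ``"free"`` a segment may span any number of wraps and is decoded with the
    unconstrained circular model, starting in state 0.  Returns the nested
    labels and the summed path log-probability (the Viterbi-training
    objective).
    """
    labels: list[list[np.ndarray]] = []
    total = 0.0
    for cycles in sequences:
        labs = []
        for c in cycles:
            if assignment == "cycle":
                _, path = forced_alignment(hmm, c, 1)
            else:
                path = viterbi_decode(hmm, c, start_state=0)
            labs.append(path.states)
            total += path.log_prob
        labels.append(labs)
    return labels, total


def viterbi_train(
    hmm: ClassHMM,
    sequences: Sequence[Sequence[np.ndarray]],
    n_iterations: int,
    initial_labels: Sequence[Sequence[np.ndarray]] | None = None,
    gmm_update_iters: int = 3,
    seed: int = 0,
    assignment: str = "cycle",
) -> ClassHMM:
    """Viterbi (segmental k-means) training of a class model.

    Per iteration: (a) hard state assignment of every segment by Viterbi
    decoding (see :func:`assign_states`) — or the provided labeling on the
    first pass, which is what makes the first pass semi-supervised;
    (b) transition re-estimation from assigned-state bigram counts
    restricted to the circular topology; (c) per-state emission
    re-estimation by a short EM warm-started from the previous mixture.
    Returns the updated model (input is not mutated).
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    for cycles in sequences:
        for c in cycles:
            if np.asarray(c).shape[0] < hmm.n_states:
                raise ValidationError("cycle shorter than the state chain")
    current = hmm
    for it in range(n_iterations):
        if it == 0 and initial_labels is not None:
            labels = [[np.asarray(l) for l in labs] for labs in initial_labels]
        else:
            labels, _ = assign_states(current, sequences, assignment=assignment)
        log_A = _transitions_from_labels(labels, current.n_states)
        emissions = []
        for s in range(current.n_states):
            frames = [
                c[np.asarray(l) == s]
                for cycles, labs in zip(sequences, labels)
                for c, l in zip(cycles, labs)
            ]
            stacked = np.vstack(frames)
            if stacked.shape[0] == 0:
                warnings.warn(
                    f"state {s} received no frames; re-seeding from neighbors",
                    stacklevel=2,
                )
                neighbors = [
                    c[np.isin(np.asarray(l), [(s - 1) % current.n_states, (s + 1) % current.n_states])]
                    for cycles, labs in zip(sequences, labels)
                    for c, l in zip(cycles, labs)
                ]
                stacked = np.vstack(neighbors)
            emissions.append(
                refit_gmm(
                    current.emissions[s],
                    stacked,
                    em_iters=gmm_update_iters,
                    seed=seed + 1009 * s + 31 * it,
                )
            )
        current = ClassHMM(current.class_name, current.n_states, log_A, emissions)
    return current


def sample_class_hmm(
    hmm: ClassHMM, n_frames: int, seed: int = 0, start_state: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a state path and observations from the model (for simulation)."""
    rng = np.random.default_rng(seed)
    A = np.exp(hmm.log_transitions)
    states = np.empty(n_frames, dtype=np.int32)
    X = np.empty((n_frames, hmm.n_features))
    s = start_state
    for t in range(n_frames):
        states[t] = s
        g = hmm.emissions[s]
        k = rng.choice(g.n_components, p=g.weights / g.weights.sum())
        X[t] = rng.normal(g.means[k], np.sqrt(g.variances[k]))
        s = rng.choice(hmm.n_states, p=A[s] / A[s].sum())
    return X, states
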