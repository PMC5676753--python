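"""Independent brute-force oracles used to validate the dynamic programs."""

import itertools

import numpy as np


def enumerate_viterbi(log_init, log_A, log_B, start=None, end=None):
    """Exhaustive maximum over all state sequences.

    Scores every sequence in S^T directly from the joint log-likelihood;
    independent of any dynamic-programming shortcut.  ``start``/``end``
    optionally constrain the first/last state.
    """
    T, S = log_B.shape
    paths = np.array(list(itertools.product(range(S), repeat=T)), dtype=int)
    if start is not None:
        paths = paths[paths[:, 0] == start]
    if end is not None:
        paths = paths[paths[:, -1] == end]
    scores = log_init[paths[:, 0]] + log_B[0, paths[:, 0]]
    for t in range(1, T):
        scores = scores + log_A[paths[:, t - 1], paths[:, t]] + log_B[t, paths[:, t]]
    best = int(np.argmax(scores))
    return paths[best], float(scores[best])


def enumerate_forced_boundaries(hmm, obs, R):
    """Best R-cycle segmentation by exhaustive search.

    Enumerates every admissible path through the R-copy left-to-right chain
    (start in the first state of copy 0, end in the last state of copy R−1)
    and returns its cycle-change points and score.
    """
    obs = np.atleast_2d(obs)
    T = obs.shape[0]
    n = hmm.n_states
    S = R * n
    log_B_class = hmm.emission_log_probs(obs)
    log_B = np.tile(log_B_class, (1, R))
    log_A = np.full((S, S), -np.inf)
    for r in range(R):
        off = r * n
        for i in range(n):
            log_A[off + i, off + i] = hmm.log_transitions[i, i]
            nxt = off + i + 1
            if i + 1 == n:
                nxt = off + n  # into next copy
            if nxt < S:
                log_A[off + i, nxt] = hmm.log_transitions[i, (i + 1) % n]
    log_init = np.full(S, -np.inf)
    log_init[0] = 0.0
    path, score = enumerate_viterbi(log_init, log_A, log_B, start=0, end=S - 1)
    copies = path // n
    bounds = [int(np.argmax(copies >= r)) for r in range(R)] + [T]
    return bounds, score


def greedy_max_overlap(est_intervals, ref_intervals):
    """Reference matching: repeatedly take the globally largest overlap."""
    pairs = []
    used_e, used_r = set(), set()
    cand = []
    for ri, r in enumerate(ref_intervals):
        for ei, e in enumerate(est_intervals):
            ov = max(0, min(e[1], r[1]) - max(e[0], r[0]))
            if ov > 0:
                cand.append((ov, ri, ei))
    for ov, ri, ei in sorted(cand, key=lambda t: (-t[0], t[1], t[2])):
        if ri in used_r or ei in used_e:
            continue
        used_r.add(ri)
        used_e.add(ei)
        pairs.append((ei, ri, ov))
    return sorted(pairs, key=lambda p: p[1])
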