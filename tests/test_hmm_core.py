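import numpy as np
import pytest

import cycleseg as cs
from cycleseg.hmm_core import (
    assign_states,
    circular_log_transitions,
    near_equal_partition,
)
from conftest import random_circular_hmm
from oracles import enumerate_forced_boundaries, enumerate_viterbi


class TestInitGMM:
    def test_single_component_matches_moments(self):
        rng = np.random.default_rng(0)
        data = rng.normal(1.5, 2.0, size=(800, 1))
        gmm = cs.init_gmm(data, n_components=1, em_iters=10, seed=0)
        np.testing.assert_allclose(gmm.means[0, 0], data.mean(), atol=0.01)
        np.testing.assert_allclose(gmm.variances[0, 0], data.var(), rtol=0.05)

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(1)
        data = np.vstack(
            [rng.normal(-2, 0.5, size=(150, 2)), rng.normal(2, 0.5, size=(150, 2))]
        )
        _, loglik = cs.init_gmm(data, 4, em_iters=10, seed=1, track_loglik=True)
        assert np.all(np.diff(loglik) >= -1e-8)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(100, 2))
        a = cs.init_gmm(data, 3, seed=5)
        b = cs.init_gmm(data, 3, seed=5)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_too_few_frames_reduces_with_warning(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(4, 2))
        with pytest.warns(UserWarning, match="reducing"):
            gmm = cs.init_gmm(data, 10, seed=0)
        assert gmm.n_components == 4
        with pytest.raises(cs.ValidationError):
            cs.init_gmm(data, 10, seed=0, allow_reduce=False)


class TestViterbiDecode:
    def test_single_state(self):
        g = cs.GaussianMixtureDiag([1.0], [[0.0]], [[1.0]])
        hmm = cs.ClassHMM("x", 1, np.array([[0.0]]), [g])
        obs = np.array([[0.3], [1.2], [-0.5]])
        path = cs.viterbi_decode(hmm, obs)
        np.testing.assert_array_equal(path.states, [0, 0, 0])
        np.testing.assert_allclose(path.log_prob, g.log_pdf(obs).sum(), atol=1e-12)

    def test_deterministic_chain(self):
        # self-loop probability 0 forces an advance every frame
        rng = np.random.default_rng(4)
        hmm = random_circular_hmm(rng, 3)
        hmm = cs.ClassHMM(
            "x", 3, circular_log_transitions(np.zeros(3) + 1e-12), hmm.emissions
        )
        obs = rng.normal(size=(6, 1))
        path = cs.viterbi_decode(hmm, obs, start_state=0)
        np.testing.assert_array_equal(path.states, [0, 1, 2, 0, 1, 2])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        T = int(rng.integers(3, 9))
        hmm = random_circular_hmm(rng, n)
        obs = rng.normal(0, 3, size=(T, 1))
        path = cs.viterbi_decode(hmm, obs)
        log_B = hmm.emission_log_probs(obs)
        log_init = np.full(n, -np.log(n))
        ref_path, ref_score = enumerate_viterbi(log_init, hmm.log_transitions, log_B)
        np.testing.assert_allclose(path.log_prob, ref_score, atol=1e-9)
        np.testing.assert_array_equal(path.states, ref_path)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(5)
        hmm = random_circular_hmm(rng, 2, n_features=2)
        with pytest.raises(cs.ValidationError):
            cs.viterbi_decode(hmm, np.zeros((4, 3)))


class TestLinearStateInit:
    @pytest.mark.parametrize(
        "length,n,expected",
        [(8, 4, [2, 2, 2, 2]), (10, 4, [3, 3, 2, 2]), (5, 5, [1, 1, 1, 1, 1])],
    )
    def test_run_lengths(self, length, n, expected):
        (labels,) = cs.linear_state_init([length], n)
        runs = [int(np.sum(labels == s)) for s in range(n)]
        assert runs == expected
        assert np.all(np.diff(labels) >= 0)  # contiguous, in order
        assert len(labels) == length

    def test_too_short_segment(self):
        with pytest.raises(cs.ValidationError):
            cs.linear_state_init([3], 4)

    def test_partition_helper(self):
        assert near_equal_partition(1003, 5) == [201, 201, 201, 200, 200]


class TestForcedAlignment:
    def test_single_repetition_covers_all(self):
        rng = np.random.default_rng(6)
        hmm = random_circular_hmm(rng, 3)
        obs = rng.normal(size=(10, 1))
        bset, path = cs.forced_alignment(hmm, obs, 1)
        assert len(bset) == 1
        assert (bset.entries[0].start, bset.entries[0].end) == (0, 10)
        assert path.states[0] == 0 and path.states[-1] == 2

    def test_two_identical_cycles_split_at_midpoint(self):
        # a model whose states emit distinct values; observation = the
        # model's own mean sequence twice → boundary exactly at midpoint
        g = lambda m: cs.GaussianMixtureDiag([1.0], [[m]], [[0.5]])
        hmm = cs.ClassHMM(
            "x", 2, circular_log_transitions(np.array([0.5, 0.5])), [g(-3.0), g(3.0)]
        )
        cycle = np.array([[-3.0], [-3.0], [3.0], [3.0]])
        obs = np.vstack([cycle, cycle])
        bset, _ = cs.forced_alignment(hmm, obs, 2)
        assert [e.start for e in bset] == [0, 4]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 2
        R = 2
        T = 8
        hmm = random_circular_hmm(rng, n)
        obs = rng.normal(0, 3, size=(T, 1))
        bset, path = cs.forced_alignment(hmm, obs, R)
        ref_bounds, ref_score = enumerate_forced_boundaries(hmm, obs, R)
        assert [e.start for e in bset] + [bset.entries[-1].end] == ref_bounds
        np.testing.assert_allclose(path.log_prob, ref_score, atol=1e-9)

    def test_partition_invariant(self):
        rng = np.random.default_rng(7)
        hmm = random_circular_hmm(rng, 3)
        obs = rng.normal(size=(40, 1))
        bset, _ = cs.forced_alignment(hmm, obs, 4)
        assert len(bset) == 4
        assert bset.entries[0].start == 0 and bset.entries[-1].end == 40
        for a, b in zip(bset.entries, bset.entries[1:]):
            assert a.end == b.start

    def test_too_short_rejected(self):
        rng = np.random.default_rng(8)
        hmm = random_circular_hmm(rng, 4)
        with pytest.raises(cs.ValidationError):
            cs.forced_alignment(hmm, np.zeros((7, 1)), 2)


class TestViterbiTrain:
    def _toy_model(self, self_probs, means, var=0.3):
        emissions = [
            cs.GaussianMixtureDiag([1.0], [[m]], [[var]]) for m in means
        ]
        return cs.ClassHMM(
            "x", len(means), circular_log_transitions(np.asarray(self_probs)), emissions
        )

    def test_recovers_self_loops(self):
        true = self._toy_model([0.8, 0.9], [-2.0, 2.0])
        X, _ = cs.sample_class_hmm(true, 2000, seed=0)
        init = self._toy_model([0.7, 0.8], [-1.5, 1.5], var=0.5)
        trained = cs.viterbi_train(init, [[X]], 5, assignment="free", seed=0)
        np.testing.assert_allclose(
            trained.self_loop_probs(), [0.8, 0.9], atol=0.05
        )

    def test_topology_preserved_after_training(self):
        rng = np.random.default_rng(9)
        hmm = random_circular_hmm(rng, 4)
        cycles = [rng.normal(size=(12, 1)) for _ in range(6)]
        trained = cs.viterbi_train(hmm, [cycles], 2, seed=1)
        A = np.exp(trained.log_transitions)
        mask = np.zeros((4, 4), dtype=bool)
        idx = np.arange(4)
        mask[idx, idx] = mask[idx, (idx + 1) % 4] = True
        assert np.all(A[~mask] == 0.0)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_fixed_point_on_identical_cycles(self):
        rng = np.random.default_rng(10)
        cycle = np.repeat(np.array([[-4.0], [-1.0], [2.0], [5.0]]), 3, axis=0)
        cycles = [cycle.copy() for _ in range(5)]
        labels = cs.linear_state_init(cycles, 4)
        hmm, _ = cs.init_class_hmm([cycles], 4, "x", gmm_components=1, seed=0)
        l1, _ = assign_states(hmm, [cycles])
        trained = cs.viterbi_train(hmm, [cycles], 3, seed=0)
        l2, _ = assign_states(trained, [cycles])
        for a, b in zip(l1[0], l2[0]):
            np.testing.assert_array_equal(a, b)

    def test_objective_nondecreasing(self):
        rng = np.random.default_rng(11)
        true = self._toy_model([0.7, 0.8, 0.9], [-3.0, 0.0, 3.0])
        cycles = []
        for s in range(6):
            X, _ = cs.sample_class_hmm(true, 15, seed=s)
            cycles.append(X)
        hmm, _ = cs.init_class_hmm([cycles], 3, "x", gmm_components=1, seed=2)
        scores = []
        current = hmm
        for it in range(6):
            _, score = assign_states(current, [cycles])
            scores.append(score)
            current = cs.viterbi_train(current, [cycles], 1, seed=2)
        assert np.all(np.diff(scores) >= -1e-6)

    def test_zero_iterations_rejected(self):
        rng = np.random.default_rng(12)
        hmm = random_circular_hmm(rng, 2)
        with pytest.raises(cs.ValidationError):
            cs.viterbi_train(hmm, [[np.zeros((5, 1))]], 0)
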