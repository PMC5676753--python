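import numpy as np
import pytest

import cycleseg as cs
from oracles import greedy_max_overlap


def _set(intervals, cls="walk"):
    return cs.SegmentBoundarySet([(a, b, cls) for a, b in intervals])


class TestMatchCycles:
    def test_identical_sets_fully_matched(self):
        s = _set([(0, 100), (100, 220), (220, 300)])
        pairs = cs.match_cycles(s, s)
        assert len(pairs) == 3
        for p in pairs:
            assert p.overlap_samples == p.reference.length

    def test_oversegmentation_keeps_larger_overlap(self):
        ref = _set([(0, 100)])
        est = _set([(0, 60), (60, 100)])
        pairs = cs.match_cycles(est, ref)
        assert len(pairs) == 1
        assert (pairs[0].estimated.start, pairs[0].estimated.end) == (0, 60)
        assert pairs[0].overlap_samples == 60

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def random_set():
            cuts = np.sort(rng.choice(np.arange(1, 50), size=4, replace=False))
            bounds = [0, *cuts, 50]
            return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

        est_iv, ref_iv = random_set(), random_set()
        pairs = cs.match_cycles(_set(est_iv), _set(ref_iv))
        oracle = greedy_max_overlap(est_iv, ref_iv)
        assert len(pairs) == len(oracle)
        got = {
            ((p.estimated.start, p.estimated.end), (p.reference.start, p.reference.end))
            for p in pairs
        }
        want = {(tuple(est_iv[ei]), tuple(ref_iv[ri])) for ei, ri, _ in oracle}
        assert got == want

    def test_empty_inputs(self):
        assert cs.match_cycles(_set([]), _set([(0, 10)])) == []


class TestBoundaryErrors:
    def test_self_comparison_is_zero(self):
        s = _set([(0, 200), (200, 400)])
        pairs = cs.match_cycles(s, s)
        assert cs.segmentation_error(pairs, 200.0) == (0.0, 0.0)
        assert cs.duration_error(pairs, 200.0) == (0.0, 0.0)

    def test_constant_shift(self):
        ref = _set([(0, 200), (200, 400), (400, 600)])
        est = _set([(10, 210), (210, 410), (410, 610)])
        pairs = cs.match_cycles(est, ref)
        mean, sd = cs.segmentation_error(pairs, 200.0)
        assert mean == pytest.approx(0.050, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_mixed_offsets(self):
        ref = _set([(0, 100), (100, 200), (200, 300)])
        est = _set([(2, 96), (96, 206), (206, 300)])
        pairs = cs.match_cycles(est, ref)
        mean, _ = cs.segmentation_error(pairs, 200.0)
        assert mean == pytest.approx((2 + 4 + 6) / 3 / 200.0, abs=1e-12)

    def test_uniform_duration_inflation(self):
        ref = _set([(0, 200), (200, 400)])
        est = _set([(0, 220), (220, 440)])
        pairs = cs.match_cycles(est, ref)
        mean, _ = cs.duration_error(pairs, 200.0)
        assert mean == pytest.approx(0.1, abs=1e-12)

    def test_duration_error_symmetric(self):
        a = _set([(0, 190), (190, 420)])
        b = _set([(0, 200), (200, 400)])
        fwd, _ = cs.duration_error(cs.match_cycles(a, b), 200.0)
        rev, _ = cs.duration_error(cs.match_cycles(b, a), 200.0)
        assert fwd == rev

    def test_empty_pairs_rejected(self):
        with pytest.raises(cs.ValidationError):
            cs.segmentation_error([], 200.0)


class TestClassificationReport:
    def test_perfect_labels(self):
        labels = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        report = cs.classification_report({"p": (labels, labels)})
        for c in ("a", "b"):
            assert report.sensitivity[c] == 100.0
            assert report.specificity[c] == 100.0
            assert report.f1[c] == 100.0
        assert report.overall_f1 == 100.0

    def test_single_class_predictor(self):
        ref = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        est = np.array(["a"] * 100, dtype=object)
        report = cs.classification_report({"p": (est, ref)})
        assert report.sensitivity["a"] == 100.0
        assert report.sensitivity["b"] == 0.0

    def test_hand_built_three_class_fixture(self):
        # person 1: rest 10/10 correct; walk 8/10 (2 as run); run 9/10 (1 as walk)
        ref = np.array(
            ["rest"] * 10 + ["walk"] * 10 + ["run"] * 10, dtype=object
        )
        est = np.array(
            ["rest"] * 10
            + ["walk"] * 8 + ["run"] * 2
            + ["run"] * 9 + ["walk"] * 1,
            dtype=object,
        )
        report = cs.classification_report({"p": (est, ref)})
        assert report.sensitivity["walk"] == pytest.approx(80.0)
        assert report.sensitivity["run"] == pytest.approx(90.0)
        # walk: tp=8 fp=1 -> precision 8/9; f1 = 2*8/9*0.8/(8/9+0.8)
        prec = 8 / 9
        f1_walk = 200 * prec * 0.8 / (prec + 0.8)
        assert report.f1["walk"] == pytest.approx(f1_walk)
        # specificity walk: tn=19, fp=1
        assert report.specificity["walk"] == pytest.approx(100 * 19 / 20)
        # confusion row for true walk: 80% walk, 20% run
        assert report.confusion.loc["walk", "run"] == pytest.approx(20.0)
        assert report.confusion.loc["walk", "walk"] == pytest.approx(80.0)

    def test_matches_sklearn_for_single_person(self):
        from sklearn.metrics import f1_score, recall_score

        rng = np.random.default_rng(3)
        ref = rng.choice(["a", "b", "c"], size=300)
        est = np.where(rng.random(300) < 0.8, ref, rng.choice(["a", "b", "c"], size=300))
        report = cs.classification_report({"p": (est, ref)})
        sk_recall = recall_score(ref, est, average="macro")
        sk_f1 = f1_score(ref, est, average="macro")
        assert report.overall_sensitivity == pytest.approx(100 * sk_recall, abs=1e-9)
        assert report.overall_f1 == pytest.approx(100 * sk_f1, abs=1e-9)

    def test_confusion_rows_sum_to_100(self):
        rng = np.random.default_rng(4)
        people = {}
        for p in range(3):
            ref = rng.choice(["a", "b", "c"], size=200)
            est = rng.choice(["a", "b", "c"], size=200)
            people[f"p{p}"] = (est, ref)
        report = cs.classification_report(people)
        np.testing.assert_allclose(
            report.confusion.sum(axis=1).to_numpy(), 100.0, atol=0.1
        )

    def test_mask_excludes_samples(self):
        ref = np.array(["a"] * 10, dtype=object)
        est = np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        mask = np.array([True] * 5 + [False] * 5)
        report = cs.classification_report({"p": (est, ref, mask)})
        assert report.sensitivity["a"] == 100.0

    def test_absent_class_warns(self):
        people = {
            "p1": (np.array(["a", "b"], dtype=object), np.array(["a", "b"], dtype=object)),
            "p2": (np.array(["a", "a"], dtype=object), np.array(["a", "a"], dtype=object)),
        }
        with pytest.warns(UserWarning, match="absent"):
            report = cs.classification_report(people)
        assert report.sensitivity["b"] == 100.0  # from p1 only

    def test_person_averaging_order(self):
        # class "a": person 1 scores 100%, person 2 scores 50% -> mean 75%
        p1 = (np.array(["a", "a"], dtype=object), np.array(["a", "a"], dtype=object))
        p2 = (
            np.array(["a", "b", "b", "b"], dtype=object),
            np.array(["a", "a", "b", "b"], dtype=object),
        )
        with pytest.warns(UserWarning):
            report = cs.classification_report({"p1": p1, "p2": p2})
        assert report.sensitivity["a"] == pytest.approx((100 + 50) / 2)
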