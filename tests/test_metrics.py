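"""Evaluation metrics against brute-force and scikit-learn oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from col6fl import (
    ConfusionMatrix,
    accuracy,
    binarize,
    confusion,
    evaluate_predictions,
    macro_f1,
    precision_recall_f1,
    summarize_trials,
)


def _brute_force_metrics(y_true, y_pred, k):
    """Independent tally: explicit counting loops, no shared code path."""
    cm = [[0] * k for _ in range(k)]
    for t, p in zip(y_true, y_pred):
        cm[t - 1][p - 1] += 1
    prec, rec, f1 = [], [], []
    for c in range(k):
        tp = cm[c][c]
        fp = sum(cm[r][c] for r in range(k)) - tp
        fn = sum(cm[c][r] for r in range(k)) - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(2 * p * r / (p + r) if p + r else 0.0)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
    return np.array(cm), np.array(prec), np.array(rec), np.array(f1), acc


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = [1, 2, 2, 3, 4, 4]
        cm = confusion(y, y, 4)
        assert np.array_equal(np.diag(cm.counts), [1, 2, 1, 2])
        assert cm.counts.sum() == cm.n == 6

    def test_small_forced_example(self):
        cm = confusion([1, 1, 2, 2], [1, 2, 2, 2], 2)
        assert np.array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_errors_on_bad_input(self):
        with pytest.raises(ValueError, match="length"):
            confusion([1, 2], [1], 2)
        with pytest.raises(ValueError, match="out-of-range"):
            confusion([1, 5], [1, 1], 4)

    def test_random_instances_match_brute_force_tally(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(1, 200))
            yt = rng.integers(1, k + 1, n)
            yp = rng.integers(1, k + 1, n)
            cm_b, p_b, r_b, f_b, acc_b = _brute_force_metrics(yt, yp, k)
            cm = confusion(yt, yp, k)
            p, r, f = precision_recall_f1(cm)
            assert np.array_equal(cm.counts, cm_b)
            assert np.allclose(p, p_b, atol=0) and np.allclose(r, r_b, atol=0)
            assert np.allclose(f, f_b, atol=0)
            assert accuracy(yt, yp) == acc_b


class TestPrecisionRecallF1:
    def test_perfect_classifier_scores_one_everywhere(self):
        cm = confusion([1, 2, 3, 4], [1, 2, 3, 4], 4)
        p, r, f = precision_recall_f1(cm)
        assert (p == 1).all() and (r == 1).all() and (f == 1).all()

    def test_hand_computed_two_class_example(self):
        cm = ConfusionMatrix(np.array([[2, 1], [1, 2]]), ["a", "b"])
        p, r, f = precision_recall_f1(cm)
        assert p[0] == pytest.approx(2 / 3)
        assert r[0] == pytest.approx(2 / 3)
        assert f[0] == pytest.approx(2 / 3)

    def test_absent_class_scores_zero_by_convention(self):
        cm = ConfusionMatrix(np.array([[3, 0], [0, 0]]), ["a", "b"])
        p, r, f = precision_recall_f1(cm)
        assert p[1] == r[1] == f[1] == 0.0

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(5)
        yt = rng.integers(1, 5, 300)
        yp = rng.integers(1, 5, 300)
        p, r, f = precision_recall_f1(confusion(yt, yp, 4))
        sp, sr, sf, _ = precision_recall_fscore_support(
            yt, yp, labels=[1, 2, 3, 4], zero_division=0
        )
        assert np.allclose(p, sp) and np.allclose(r, sr) and np.allclose(f, sf)


class TestMacroF1AndAccuracy:
    def test_forced_examples(self):
        assert macro_f1([1.0, 1.0, 1.0]) == 1.0
        assert macro_f1([1.0, 0.5, 0.5, 0.0]) == pytest.approx(0.5)
        assert accuracy([1] * 24, [1] * 18 + [2] * 6) == pytest.approx(18 / 24)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            macro_f1([])
        with pytest.raises(ValueError):
            accuracy([], [])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_macro_f1_is_mean_and_accuracy_is_trace(self, seed):
        rng = np.random.default_rng(seed)
        yt = rng.integers(1, 5, 50)
        yp = rng.integers(1, 5, 50)
        rep = evaluate_predictions(yt, yp, 4)
        assert rep.macro_f1 == np.mean(rep.f1)
        assert rep.accuracy == np.trace(rep.confusion.counts) / rep.n
        assert 0 <= rep.macro_f1 <= 1 and 0 <= rep.accuracy <= 1


class TestBinarize:
    def test_canonical_mapping(self):
        assert list(binarize([1, 2, 3, 4])) == [0, 1, 1, 1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out-of-range"):
            binarize([0, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_binary_accuracy_dominates_four_class_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        yt = rng.integers(1, 5, 40)
        yp = rng.integers(1, 5, 40)
        assert accuracy(binarize(yt), binarize(yp)) >= accuracy(yt, yp)


class TestSummarizeTrials:
    @staticmethod
    def _report(f1, acc):
        yt = [1, 2]
        rep = evaluate_predictions(yt, yt, 2)
        rep.macro_f1, rep.accuracy = f1, acc
        return rep

    def test_identical_reports_have_zero_std(self):
        reps = [self._report(0.8, 0.7)] * 3
        s = summarize_trials(reps)
        assert s["macro_f1_std"] < 1e-12 and s["macro_f1_mean"] == pytest.approx(0.8)

    def test_hand_formula_example(self):
        s = summarize_trials([self._report(0.8, 0.8), self._report(0.6, 0.6)])
        assert s["macro_f1_mean"] == pytest.approx(0.7)
        assert s["macro_f1_std"] == pytest.approx(0.14142135, rel=1e-6)

    def test_mean_is_order_invariant(self):
        reps = [self._report(x, x) for x in (0.2, 0.5, 0.9)]
        assert (
            summarize_trials(reps)["macro_f1_mean"]
            == summarize_trials(reps[::-1])["macro_f1_mean"]
        )

    def test_std_requires_two_reports(self):
        with pytest.raises(ValueError, match="two"):
            summarize_trials([self._report(0.5, 0.5)])
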