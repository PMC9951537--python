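import math

import numpy as np
import pytest

from predaot.dataset import LabeledDataset
from predaot.fixtures import worked_confusion_example
from predaot.learners import (
    HyperGrid,
    compute_classifier_metrics,
    compute_regressor_metrics,
    grid_search_cv,
    rank_correlations,
)


def brute_force_auroc(scores, labels):
    """Independent oracle: exhaustive positive/negative pair concordance."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def mcc_formula(tp, fp, tn, fn):
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0


def _bit_dataset(n=200, d=64, bit=7, noise=0.0, seed=0, task="classification"):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, d)) < 0.5).astype(float)
    if task == "classification":
        y_label = X[:, bit].astype(int)
        y_log = rng.normal(3, 1, n)
    else:
        y_label = (rng.random(n) < 0.5).astype(int)
        y_log = 2.0 + 1.5 * X[:, bit] + 0.5 * X[:, bit + 1] + rng.normal(0, noise, n)
    return LabeledDataset(
        ids=np.array([f"r{i}" for i in range(n)], dtype=object),
        X=X, y_label=y_label, y_log=y_log,
        categories=np.array(["4"] * n), species="mouse", n_bits=d,
    )


class TestGridSearch:
    def test_singleton_grid_returns_that_candidate(self):
        ds = _bit_dataset()
        grid = HyperGrid({"n_estimators": [20], "max_depth": [4]})
        params, score = grid_search_cv(ds, grid, "classification", seed=1)
        assert params == {"n_estimators": 20, "max_depth": 4}
        assert 0 <= score <= 1

    def test_dominated_candidate_loses(self):
        # depth-1 stumps cannot represent a two-bit additive target; full-depth
        # forests strictly dominate on every fold
        ds = _bit_dataset(task="regression", noise=0.05, seed=2)
        grid = HyperGrid({"max_depth": [1, None], "n_estimators": [30]})
        params, rmse = grid_search_cv(ds, grid, "regression", seed=3)
        assert params["max_depth"] is None
        assert rmse < 0.3

    def test_single_bit_label_recovered(self):
        # label equals one fingerprint bit: CV accuracy of the selected
        # model must be near-perfect
        ds = _bit_dataset(seed=4)
        grid = HyperGrid({"n_estimators": [50]})
        _, acc = grid_search_cv(ds, grid, "classification", seed=5)
        assert acc >= 0.95

    def test_deterministic_given_seed(self):
        ds = _bit_dataset(seed=6)
        grid = HyperGrid({"n_estimators": [10, 20]})
        a = grid_search_cv(ds, grid, "classification", seed=7)
        b = grid_search_cv(ds, grid, "classification", seed=7)
        assert a == b

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid({})
        with pytest.raises(ValueError):
            HyperGrid({"n_estimators": []})

    def test_degenerate_class_counts_rejected(self):
        ds = _bit_dataset(n=60, seed=8)
        tiny = ds.subset(np.concatenate([np.flatnonzero(ds.y_label == 1)[:3],
                                         np.flatnonzero(ds.y_label == 0)]))
        with pytest.raises(ValueError, match="class"):
            grid_search_cv(tiny, HyperGrid({"n_estimators": [5]}), "classification")


class TestClassifierMetrics:
    def test_perfect_separation(self):
        m = compute_classifier_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (m.acc, m.auroc, m.mcc, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_all_tied_scores_give_auroc_half(self):
        m = compute_classifier_metrics([0.7] * 6, [1, 0, 1, 0, 1, 0])
        assert m.auroc == 0.5

    def test_mcc_matches_formula_oracle(self):
        # confusion (TP=40, FP=10, TN=35, FN=15) built from explicit scores
        scores = np.array([0.9] * 40 + [0.9] * 10 + [0.1] * 35 + [0.1] * 15)
        labels = np.array([1] * 40 + [0] * 10 + [0] * 35 + [1] * 15)
        m = compute_classifier_metrics(scores, labels)
        assert m.confusion == (40, 10, 35, 15)
        assert math.isclose(m.mcc, mcc_formula(40, 10, 35, 15), rel_tol=1e-12)

    def test_auroc_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=30)  # includes ties
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            m = compute_classifier_metrics(scores, labels)
            assert math.isclose(m.auroc, brute_force_auroc(scores, labels), rel_tol=1e-12)

    def test_single_class_flagged_undefined(self):
        m = compute_classifier_metrics([0.9, 0.8, 0.7], [1, 1, 1])
        assert m.auroc is None and m.mcc is None
        assert "auroc" in m.undefined and "mcc" in m.undefined
        assert m.npv is None and "npv" in m.undefined  # no negative calls either

    def test_permutation_invariance(self):
        scores, labels, _ = worked_confusion_example()
        perm = np.random.default_rng(3).permutation(len(scores))
        a = compute_classifier_metrics(scores, labels)
        b = compute_classifier_metrics(scores[perm], labels[perm])
        assert a.confusion == b.confusion
        for key in ("acc", "auroc", "mcc", "ppv", "npv"):
            assert math.isclose(getattr(a, key), getattr(b, key), rel_tol=1e-12)

    def test_worked_example_matches_independent_oracle(self):
        scores, labels, expected = worked_confusion_example()
        m = compute_classifier_metrics(scores, labels)
        assert m.confusion == expected["confusion"]
        for key in ("acc", "auroc", "mcc", "ppv", "npv"):
            assert math.isclose(getattr(m, key), expected[key], rel_tol=1e-12)


class TestRegressorMetrics:
    def test_identity_prediction(self):
        m = compute_regressor_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.rmse == 0.0 and m.r2 == 1.0

    def test_constant_offset_rmse(self):
        truth = np.array([1.0, 2.0, 5.0])
        m = compute_regressor_metrics(truth + 0.7, truth)
        assert math.isclose(m.rmse, 0.7, rel_tol=1e-12)

    def test_hand_computed_example(self):
        m = compute_regressor_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert math.isclose(m.rmse, math.sqrt(1 / 3), rel_tol=1e-12)

    def test_constant_truth_flags_r2(self):
        m = compute_regressor_metrics([1.0, 2.0], [3.0, 3.0])
        assert m.r2 is None and "r2" in m.undefined

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_regressor_metrics([1.0], [1.0, 2.0])


class TestRankCorrelations:
    def test_identity_and_antitone(self):
        v = np.array([1.0, 2.0, 5.0, 9.0])
        assert rank_correlations(v, v) == (1.0, 1.0)
        p, s = rank_correlations(-v, v)
        assert math.isclose(p, -1.0) and math.isclose(s, -1.0)

    def test_monotone_transform_preserves_spearman(self):
        truth = np.array([0.5, 1.0, 2.0, 3.5, 7.0])
        pred = np.exp(truth)  # strictly increasing, nonlinear
        p, s = rank_correlations(pred, truth)
        assert math.isclose(s, 1.0)
        assert p <= 1.0

    def test_constant_vector_flagged(self):
        assert rank_correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == (None, None)
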