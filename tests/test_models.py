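import numpy as np
import pandas as pd
import pytest

from actipredict.cohort_stats import anova_f_raw
from actipredict.models import (EvalConfig, ModelSpec, calibrate_threshold,
                                compute_metrics, loso_evaluate,
                                select_features, train_classifier)


def _toy_matrix(seed=0, n=30, d=6):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, d)),
                     columns=[f"f{i}" for i in range(d)])
    return X, rng


class TestSelectFeatures:
    def test_perfect_binary_separator_ranked_first(self):
        X, rng = _toy_matrix(1)
        y = rng.integers(0, 2, len(X))
        X["flag"] = y.astype(float)
        types = {c: "continuous" for c in X.columns}
        types["flag"] = "categorical"
        assert "flag" in select_features(X, y, types, k=1)

    def test_continuous_scores_agree_with_anova_oracle(self):
        """Rank order of continuous features equals the ANOVA-F order."""
        X, rng = _toy_matrix(2, n=40)
        y = rng.integers(0, 2, len(X))
        X["signal"] = y + rng.normal(0, 0.3, len(X))
        types = {c: "continuous" for c in X.columns}
        fs = {c: anova_f_raw([X[c][y == 0], X[c][y == 1]])["F"]
              for c in X.columns}
        best_by_oracle = max(fs, key=fs.get)
        assert select_features(X, y, types, k=1) == [best_by_oracle]

    def test_k_above_column_count_keeps_all(self):
        X, rng = _toy_matrix(3)
        y = rng.integers(0, 2, len(X))
        types = {c: "continuous" for c in X.columns}
        with pytest.warns(UserWarning):
            cols = select_features(X, y, types, k=100)
        assert cols == list(X.columns)

    def test_permuted_labels_selection_roughly_uniform(self):
        X, _ = _toy_matrix(4, n=60, d=8)
        counts = {c: 0 for c in X.columns}
        types = {c: "continuous" for c in X.columns}
        for seed in range(40):
            y = np.random.default_rng(seed).permutation(
                np.repeat([0, 1], 30))
            counts[select_features(X, y, types, k=1)[0]] += 1
        # no column should dominate under the null
        assert max(counts.values()) < 20


class TestTrainClassifier:
    def test_separable_data_fit_perfectly_by_linear_svm(self):
        X = np.vstack([np.full((10, 2), -2.0), np.full((10, 2), 2.0)])
        y = np.repeat([0, 1], 10)
        model = train_classifier(ModelSpec("svm_linear", seed=0), X, y)
        assert (model.predict(X) == y).all()

    def test_strong_l1_penalty_zeroes_noise_coefficients(self):
        rng = np.random.default_rng(5)
        n = 200
        signal = rng.normal(size=n)
        noise = rng.normal(size=(n, 5))
        y = (signal > 0).astype(int)
        X = np.column_stack([signal, noise])
        spec = ModelSpec("logreg_l1", {"C": [0.05], "l1_ratio": [1.0]}, seed=0)
        model = train_classifier(spec, X, y)
        coefs = model.named_steps["clf"].coef_.ravel()
        assert coefs[0] != 0
        assert np.all(coefs[1:] == 0)

    def test_fixed_seed_reproduces_identical_fit(self):
        X, rng = _toy_matrix(6, n=40)
        y = rng.integers(0, 2, len(X))
        spec = ModelSpec("random_forest",
                         {"n_estimators": [30], "max_depth": [3]}, seed=11)
        m1 = train_classifier(spec, X.to_numpy(), y)
        m2 = train_classifier(spec, X.to_numpy(), y)
        np.testing.assert_array_equal(m1.predict_proba(X.to_numpy()),
                                      m2.predict_proba(X.to_numpy()))

    def test_single_class_raises(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(ModelSpec("knn"), X, np.zeros(5, dtype=int))


class TestThreshold:
    def test_ten_positives_target_point_nine_admits_exactly_nine(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.uniform(size=10))
        neg = rng.uniform(size=15)
        probs = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(10), np.zeros(15)])
        t = calibrate_threshold(probs, labels, 0.9)
        assert int(np.sum(pos >= t)) == 9

    def test_perfect_separation_sensitivity_one(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        t = calibrate_threshold(probs, labels, 0.9)
        m = compute_metrics(probs, labels, t)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_target_one_admits_every_positive(self):
        rng = np.random.default_rng(2)
        probs = rng.uniform(size=20)
        labels = (rng.uniform(size=20) < 0.4).astype(int)
        labels[0] = 1
        t = calibrate_threshold(probs, labels, 1.0)
        assert t <= probs[labels == 1].min()

    def test_sensitivity_at_calibrated_threshold_meets_target(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            probs = rng.uniform(size=30)
            labels = (rng.uniform(size=30) < 0.4).astype(int)
            if labels.sum() in (0, 30):
                continue
            t = calibrate_threshold(probs, labels, 0.9)
            assert compute_metrics(probs, labels, t)["sensitivity"] >= 0.9


class TestMetrics:
    def test_perfect_separation(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        m = compute_metrics(probs, labels, 0.5)
        assert m["auroc"] == 1.0 and m["f1"] == 1.0

    def test_constant_probability_auroc_half(self):
        m = compute_metrics(np.full(10, 0.4),
                            np.array([1, 0] * 5), 0.5)
        assert m["auroc"] == 0.5

    def test_auroc_equals_pair_counting_oracle(self):
        rng = np.random.default_rng(9)
        probs = np.round(rng.uniform(size=6), 1)
        labels = np.array([1, 1, 0, 0, 1, 0])
        pos, neg = probs[labels == 1], probs[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        oracle = wins / (len(pos) * len(neg))
        m = compute_metrics(probs, labels, 0.5)
        assert m["auroc"] == pytest.approx(oracle)

    def test_auroc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(10)
        probs = rng.uniform(size=30)
        labels = (rng.uniform(size=30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        a = compute_metrics(probs, labels, 0.5)["auroc"]
        b = compute_metrics(1 / (1 + np.exp(-5 * probs)), labels, 0.5)["auroc"]
        assert a == pytest.approx(b)


class TestLoso:
    def _dataset(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        # signal bounded away from 0 so every fold ranks the held-out
        # patient on the correct side
        signal = rng.uniform(0.5, 2.0, n) * rng.choice([-1.0, 1.0], n)
        X = pd.DataFrame({"signal": signal, "noise": rng.normal(size=n)})
        y = (X["signal"] > 0).astype(int).to_numpy()
        types = {c: "continuous" for c in X.columns}
        return X, y, types

    def test_one_fold_per_patient_each_tested_once(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0], "b": [1.0, 0.0, 1.0, 0.0]})
        y = np.array([0, 0, 1, 1])
        spec = ModelSpec("knn", {"n_neighbors": [1]}, seed=0)
        res = loso_evaluate(X, y, {"a": "continuous", "b": "continuous"},
                            spec, EvalConfig(selection_k=2))
        assert len(res.probabilities) == 4
        assert res.patient_ids == list(X.index)

    def test_single_class_training_fold_error_names_patient(self):
        # with a class of size 1, the fold holding it out is single-class
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        y = np.array([0, 1, 1])
        with pytest.raises(ValueError, match="single-class"):
            loso_evaluate(X, y, {"a": "continuous"},
                          ModelSpec("knn", {"n_neighbors": [1]}),
                          EvalConfig(selection_k=1))

    def test_deterministic_single_feature_signal_gives_auroc_one(self):
        X, y, types = self._dataset(16, seed=1)
        spec = ModelSpec("logreg_l1", {"C": [10.0], "l1_ratio": [1.0]}, seed=0)
        res = loso_evaluate(X, y, types, spec, EvalConfig(selection_k=2))
        assert res.metrics["auroc"] == 1.0

    def test_no_leakage_test_label_cannot_affect_fold(self):
        """Flipping a held-out patient's label leaves that fold's
        out-of-fold probability unchanged."""
        X, y, types = self._dataset(14, seed=2)
        spec = ModelSpec("knn", {"n_neighbors": [3]}, seed=0)
        res1 = loso_evaluate(X, y, types, spec, EvalConfig(selection_k=2))
        y2 = y.copy()
        y2[0] = 1 - y2[0]
        if len(np.unique(y2[1:])) == 2:
            res2 = loso_evaluate(X, y2, types, spec, EvalConfig(selection_k=2))
            assert res2.probabilities[0] == res1.probabilities[0]

    def test_fewer_than_three_patients_rejected(self):
        X = pd.DataFrame({"a": [0.0, 1.0]})
        with pytest.raises(ValueError):
            loso_evaluate(X, np.array([0, 1]), {"a": "continuous"},
                          ModelSpec("knn"), EvalConfig())
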