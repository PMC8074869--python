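"""Shallow-model training and leave-one-subject-out evaluation.

Five classifier families (random forest, gradient-boosted trees, KNN,
linear-kernel SVM, L1-penalized logistic regression) are trained on the
patient feature matrix.  Everything fitted — median fill of residual gaps,
the mixed chi-square / ANOVA-F feature selector, scaling, grid search —
lives inside each training fold; leave-one-subject-out (LOSO) cross-
validation pools one out-of-fold probability per patient, the decision
threshold is calibrated on the pooled probabilities to a target sensitivity
(default 0.9), and the metric suite (AUROC, sensitivity, specificity,
precision, F1) is computed on the pooled predictions.  The positive class
is failure to achieve a textbook outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import chi2, f_classif
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FAMILIES = ("random_forest", "gradient_boosted_trees", "knn",
            "svm_linear", "logreg_l1")


#: small documented default grids (the tuned knobs, not exhaustive ranges)
DEFAULT_GRIDS: dict[str, dict] = {
    "random_forest": {"n_estimators": [300], "max_depth": [None, 4]},
    "gradient_boosted_trees": {"learning_rate": [0.05, 0.1],
                               "n_estimators": [100, 300],
                               "max_depth": [2, 3],
                               "reg_alpha": [0.0, 1.0],
                               "reg_lambda": [0.0, 1.0]},
    "knn": {"n_neighbors": [3, 5, 7]},
    "svm_linear": {"C": [0.1, 1.0, 10.0]},
    "logreg_l1": {"C": [0.1, 1.0, 10.0], "l1_ratio": [0.5, 1.0]},
}

#: single-point grids for quick experiments (no inner selection needed)
REDUCED_GRIDS: dict[str, dict] = {
    "random_forest": {"n_estimators": [200], "max_depth": [4]},
    "gradient_boosted_trees": {"learning_rate": [0.1], "n_estimators": [100],
                               "max_depth": [2], "reg_alpha": [0.0],
                               "reg_lambda": [1.0]},
    "knn": {"n_neighbors": [5]},
    "svm_linear": {"C": [1.0]},
    "logreg_l1": {"C": [1.0], "l1_ratio": [1.0]},
}


@dataclass
class ModelSpec:
    """One classifier family with its hyperparameter grid and seed."""

    family: str = "logreg_l1"
    grid: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}


@dataclass
class EvalConfig:
    """Evaluation settings: sensitivity anchor, selection size, feature set."""

    target_sensitivity: float = 0.9
    selection_k: int = 20
    feature_set: str = "combined"

    def __post_init__(self) -> None:
        if not 0 < self.target_sensitivity <= 1:
            raise ValueError("target_sensitivity must be in (0, 1]")
        if self.feature_set not in ("clinical_only", "activity_only",
                                    "combined", "baseline_score"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")


@dataclass
class CVResult:
    """Pooled LOSO output: one probability per patient plus the metric suite."""

    patient_ids: list
    probabilities: np.ndarray
    labels: np.ndarray
    threshold: float
    metrics: dict
    selected_features: list  # per fold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_ids,
            "probability": self.probabilities,
            "label": self.labels,
            "predicted": (self.probabilities >= self.threshold).astype(int),
        })


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def select_features(X: pd.DataFrame, y, feature_types: dict[str, str],
                    k: int) -> list[str]:
    """Top-k columns by univariate score, ranked within type class.

    Categorical (one-hot) columns are scored by the chi-square statistic,
    continuous columns by the ANOVA F statistic; columns are then merged by
    within-class rank (best ranks first), with ties broken by column order.
    k larger than the column count keeps everything (with a warning).
    """
    y = np.asarray(y)
    cols = list(X.columns)
    if k >= len(cols):
        if k > len(cols):
            warnings.warn(f"k={k} exceeds {len(cols)} columns; keeping all")
        return cols
    cat = [c for c in cols if feature_types.get(c) == "categorical"]
    cont = [c for c in cols if c not in cat]
    # merge key: (within-class rank, p-value, column order) — p-values are
    # comparable across the two test families and break cross-class rank ties
    scores: dict[str, tuple] = {}
    Xf = X.fillna(X.median(numeric_only=True)).fillna(0.0)
    for subset, scorer in ((cat, chi2), (cont, f_classif)):
        if not subset:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arr = Xf[subset].to_numpy()
            if scorer is chi2:
                arr = np.abs(arr)
            s, p = scorer(arr, y)
        s = np.nan_to_num(s, nan=0.0)
        p = np.nan_to_num(p, nan=1.0)
        for rank, idx in enumerate(np.argsort(-s, kind="stable")):
            scores[subset[idx]] = (rank, p[idx], cols.index(subset[idx]))
    ordered = sorted(cols, key=lambda c: scores[c])
    return ordered[:k]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _estimator(family: str, params: dict, seed: int):
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "gradient_boosted_trees":
        from lightgbm import LGBMClassifier
        kwargs = {"min_child_samples": 5, **params}
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                              **kwargs)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "svm_linear":
        return SVC(kernel="linear", probability=True, random_state=seed,
                   **params)
    if family == "logreg_l1":
        return LogisticRegression(solver="saga", max_iter=5000,
                                  random_state=seed, **params)
    raise ValueError(family)


def _pipeline(family: str, params: dict, seed: int) -> Pipeline:
    return Pipeline([
        ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
        ("scale", StandardScaler()),
        ("clf", _estimator(family, params, seed)),
    ])


def _predict_proba(model, X) -> np.ndarray:
    """predict_proba with lightgbm's cosmetic feature-name warning muted
    (its sklearn wrapper invents names at fit and complains on arrays)."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names")
        return model.predict_proba(X)


def _grid_points(grid: dict) -> list[dict]:
    points = [{}]
    for key, values in grid.items():
        points = [{**p, key: v} for p in points for v in values]
    return points


def train_classifier(spec: ModelSpec, X, y, inner_folds: int = 3) -> Pipeline:
    """Fit one family with grid search by inner cross-validated AUROC.

    With a single grid point the inner loop is skipped.  A fold that
    contains only one class raises.  Fixed seed => identical fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    points = _grid_points(spec.grid)
    best = points[0]
    if len(points) > 1:
        n_splits = min(inner_folds, int(np.bincount(y.astype(int)).min()))
        n_splits = max(n_splits, 2)
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                             random_state=spec.seed)
        best_score = -np.inf
        for params in points:
            aucs = []
            for tr, te in cv.split(X, y):
                if len(np.unique(y[te])) < 2:
                    continue
                pipe = _pipeline(spec.family, params, spec.seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pipe.fit(X[tr], y[tr])
                aucs.append(roc_auc_score(y[te],
                                          _predict_proba(pipe, X[te])[:, 1]))
            score = float(np.mean(aucs)) if aucs else -np.inf
            if score > best_score:
                best_score, best = score, params
    model = _pipeline(spec.family, best, spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    model.best_params_ = best
    return model


# ---------------------------------------------------------------------------
# thresholding and metrics
# ---------------------------------------------------------------------------

def calibrate_threshold(probs, labels, target_sensitivity: float = 0.9) -> float:
    """Largest threshold whose pooled sensitivity >= target.

    With n positives the threshold is the ceil(target*n)-th largest positive
    probability, so with 10 distinct positives and target 0.9 exactly 9 are
    admitted.  If the target is unreachable the threshold drops below
    min(probs) with a warning.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    pos = np.sort(probs[labels == 1])[::-1]
    if pos.size == 0:
        raise ValueError("no positive labels")
    need = int(np.ceil(target_sensitivity * pos.size))
    if need > pos.size:
        warnings.warn("target sensitivity unreachable; thresholding below min")
        return float(np.min(probs)) - 1e-9
    return float(pos[need - 1])


def compute_metrics(probs, labels, threshold: float) -> dict[str, float]:
    """AUROC (midrank tie handling) plus confusion metrics at a threshold.

    Positive class (label 1) is failure to achieve a textbook outcome;
    a prediction is positive when probability >= threshold.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (probs >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {
        "auroc": float(roc_auc_score(labels, probs)),
        "sensitivity": float(sens),
        "specificity": float(spec),
        "precision": float(prec),
        "f1": float(f1),
    }


# ---------------------------------------------------------------------------
# leave-one-subject-out evaluation
# ---------------------------------------------------------------------------

def loso_evaluate(X: pd.DataFrame, y, feature_types: dict[str, str],
                  spec: ModelSpec, cfg: EvalConfig | None = None,
                  patient_ids=None) -> CVResult:
    """Leave-one-subject-out evaluation with in-fold selection and tuning.

    One fold per patient; feature selection, imputation, scaling and grid
    search are fitted on the training fold only.  Out-of-fold probabilities
    are pooled, the threshold is calibrated to the target sensitivity, and
    the metric suite is computed on the pooled predictions.
    """
    cfg = cfg or EvalConfig()
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 3:
        raise ValueError("LOSO evaluation needs at least 3 patients")
    if patient_ids is None:
        patient_ids = list(X.index)
    probs = np.empty(n)
    selected_log = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training fold for patient {patient_ids[i]} is "
                             "single-class")
        cols = select_features(X.iloc[tr], y[tr], feature_types,
                               cfg.selection_k)
        selected_log.append(cols)
        model = train_classifier(spec, X.iloc[tr][cols].to_numpy(), y[tr])
        probs[i] = _predict_proba(
            model, X.iloc[[i]][cols].to_numpy())[0, 1]
    threshold = calibrate_threshold(probs, y, cfg.target_sensitivity)
    metrics = compute_metrics(probs, y, threshold)
    return CVResult(list(patient_ids), probs, y, threshold, metrics,
                    selected_log)


def baseline_evaluate(scores, y, cfg: EvalConfig | None = None) -> CVResult:
    """Evaluate a precomputed risk-score column (no model fitting).

    The score itself is the predicted probability of failure to achieve a
    textbook outcome; only threshold calibration and metrics are computed.
    """
    cfg = cfg or EvalConfig()
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    threshold = calibrate_threshold(scores, y, cfg.target_sensitivity)
    metrics = compute_metrics(scores, y, threshold)
    return CVResult(list(range(len(y))), scores, y, threshold, metrics, [])
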