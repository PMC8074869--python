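"""Model-agnostic Shapley-value feature attribution.

Attributions are estimated by the sampled-permutation algorithm with
marginal (interventional) background sampling: for each explained row and
each sampled feature permutation, features are switched one at a time from
a random background row's values to the explained row's values, and the
change in the model's positive-class probability when feature i switches is
one Monte-Carlo draw of that feature's Shapley contribution.  Per
permutation the contributions telescope to f(x) - f(z), so the mean
attributions satisfy the efficiency property
sum_i phi_i ~= f(x) - E_background[f] up to Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ImportanceReport:
    """Per-feature mean |Shapley| ranking plus per-row attributions."""

    feature_names: list
    attributions: np.ndarray      # (n_rows, n_features)
    base_value: float             # mean background prediction
    predictions: np.ndarray       # f(x) per explained row
    n_samples: int
    seed: int

    @property
    def mean_abs(self) -> pd.Series:
        s = pd.Series(np.abs(self.attributions).mean(axis=0),
                      index=self.feature_names, name="mean_abs_shap")
        return s.sort_values(ascending=False, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.attributions, columns=self.feature_names)


def _predict(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    return np.asarray(proba)[:, 1]


def shapley_importance(model, X, background, n_samples: int = 1000,
                       seed: int = 0, feature_names=None) -> ImportanceReport:
    """Sampled-permutation Shapley attributions for each row of ``X``.

    ``background`` is the reference population (typically the training
    cohort); ``n_samples`` permutations are drawn per explained row.  The
    model must expose ``predict_proba``; attributions are on the
    positive-class probability scale.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background set is empty")
    if background.ndim == 1:
        background = background[None, :]
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n_rows, d = X.shape
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(d)]

    phi = np.zeros((n_rows, d))
    base_value = float(_predict(model, background).mean())
    predictions = _predict(model, X)

    for _ in range(n_samples):
        order = rng.permutation(d)
        z = background[rng.integers(background.shape[0], size=n_rows)]
        # walk the permutation: switch features from background to x one by
        # one; batch all rows and all d+1 coalition states into one predict
        states = np.repeat(z[None, :, :], d + 1, axis=0)  # (d+1, n_rows, d)
        current = z.copy()
        for step, j in enumerate(order, start=1):
            current[:, j] = X[:, j]
            states[step] = current
        preds = _predict(model, states.reshape(-1, d)).reshape(d + 1, n_rows)
        contrib = np.diff(preds, axis=0)  # (d, n_rows)
        for step, j in enumerate(order):
            phi[:, j] += contrib[step]
    phi /= n_samples
    return ImportanceReport(list(feature_names), phi, base_value,
                            predictions, n_samples, seed)


def exact_shapley(model, x, background) -> np.ndarray:
    """Exhaustive Shapley values by enumeration of all 2^d coalitions.

    Independent oracle for small d: the value of a coalition S is the mean
    model output with features in S taken from x and the rest from each
    background row.  Exponential in d — use only for cross-checks.
    """
    from itertools import combinations
    from math import factorial

    x = np.asarray(x, dtype=float).ravel()
    background = np.asarray(background, dtype=float)
    d = x.size
    cache: dict[frozenset, float] = {}

    def value(S: frozenset) -> float:
        if S not in cache:
            Z = background.copy()
            for j in S:
                Z[:, j] = x[j]
            cache[S] = float(_predict(model, Z).mean())
        return cache[S]

    phi = np.zeros(d)
    feats = list(range(d))
    for i in feats:
        rest = [j for j in feats if j != i]
        for r in range(d):
            for S in combinations(rest, r):
                w = factorial(r) * factorial(d - r - 1) / factorial(d)
                phi[i] += w * (value(frozenset(S) | {i}) - value(frozenset(S)))
    return phi
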