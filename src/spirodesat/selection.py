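"""Filter and wrapper (floating) feature selection, scored by CV AUROC.

All selection statistics are computed on training rows only; the
:class:`FeatureMatrix` records whether test rows were ever read, which
the test suite uses to assert the absence of leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.feature_selection import (chi2, f_classif, mutual_info_classif)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import EmptySelectionError
from .models import make_model

__all__ = [
    "FeatureMatrix",
    "SelectionResult",
    "filter_select",
    "sffs",
    "sbfs",
    "fit_evaluate",
    "EvalResult",
    "FILTER_METHODS",
]

FILTER_METHODS = ("chi2", "anova_f", "mutual_info")


@dataclass
class FeatureMatrix:
    """Case-by-feature matrix with labels, split mask and CV folds."""

    X: pd.DataFrame
    y: np.ndarray
    test_mask: np.ndarray          # True for held-out rows
    folds: np.ndarray              # fold id per row; -1 on test rows
    seed: int = 0
    test_touched: bool = field(default=False, init=False)

    @classmethod
    def from_features(cls, X: pd.DataFrame, y, split, n_folds: int = 5,
                      seed: int = 0) -> "FeatureMatrix":
        y = np.asarray(y, dtype=int)
        split = np.asarray(split)
        test_mask = split == "test"
        if not np.isfinite(X.to_numpy(dtype=float)).all():
            raise ValueError("feature matrix contains non-finite values")
        folds = np.full(len(y), -1, dtype=int)
        train_idx = np.flatnonzero(~test_mask)
        if len(train_idx) >= n_folds:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=seed)
            for k, (_, val) in enumerate(skf.split(np.zeros(len(train_idx)),
                                                   y[train_idx])):
                folds[train_idx[val]] = k
        return cls(X=X, y=y, test_mask=test_mask, folds=folds, seed=seed)

    @property
    def n_folds(self) -> int:
        return int(self.folds.max()) + 1

    def train_data(self, columns=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y, folds) of the training rows."""
        m = ~self.test_mask
        X = self.X if columns is None else self.X[list(columns)]
        return X.to_numpy(dtype=float)[m], self.y[m], self.folds[m]

    def test_data(self, columns=None) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) of the held-out rows; flips the leakage flag."""
        self.test_touched = True
        X = self.X if columns is None else self.X[list(columns)]
        return X.to_numpy(dtype=float)[self.test_mask], self.y[self.test_mask]


@dataclass
class SelectionResult:
    method: str
    selected: list[str]
    scores: dict[str, float] | None = None       # filter: univariate scores
    score_trace: list[float] | None = None       # wrapper: CV AUROC per accepted step


def _cv_auroc(X: np.ndarray, y: np.ndarray, folds: np.ndarray,
              estimator) -> float:
    """Mean AUROC over the precomputed stratified folds."""
    aurocs = []
    for k in range(int(folds.max()) + 1):
        val = folds == k
        if len(np.unique(y[val])) < 2 or len(np.unique(y[~val])) < 2:
            raise ValueError(f"fold {k} is single-class")
        model = clone(estimator)
        model.fit(X[~val], y[~val])
        p = model.predict_proba(X[val])[:, 1]
        aurocs.append(roc_auc_score(y[val], p))
    return float(np.mean(aurocs))


def filter_select(matrix: FeatureMatrix, method: str, k: int = 10,
                  ) -> SelectionResult:
    """Top-k features by a univariate filter score on the training rows.

    Chi-square requires non-negative inputs, so features are min-max
    scaled (on training rows) first.  Ties break by registry order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if method not in FILTER_METHODS:
        raise ValueError(f"unknown filter method {method!r}")
    k = min(k, matrix.X.shape[1])
    X, y, _ = matrix.train_data()
    if method == "chi2":
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        scores, _ = chi2((X - lo) / span, y)
    elif method == "anova_f":
        scores, _ = f_classif(X, y)
    else:
        scores = mutual_info_classif(X, y, random_state=matrix.seed)
    scores = np.nan_to_num(np.asarray(scores, dtype=float), nan=0.0)
    order = np.argsort(-scores, kind="stable")[:k]
    names = list(matrix.X.columns)
    return SelectionResult(method=method,
                           selected=[names[i] for i in order],
                           scores={names[i]: float(scores[i]) for i in order})


def _wrapper_search(matrix: FeatureMatrix, model_spec: str, max_k: int,
                    forward: bool) -> SelectionResult:
    names = list(matrix.X.columns)
    if max_k <= 0 or max_k > len(names):
        raise ValueError("max_k must be in 1..n_features")
    estimator = make_model(model_spec, seed=matrix.seed)
    Xall, y, folds = matrix.train_data()
    col = {n: i for i, n in enumerate(names)}
    cache: dict[frozenset, float] = {}

    def score(subset: list[str]) -> float:
        key = frozenset(subset)
        if key not in cache:
            idx = [col[n] for n in subset]
            cache[key] = _cv_auroc(Xall[:, idx], y, folds, estimator)
        return cache[key]

    # best subset seen per size
    best: dict[int, tuple[float, list[str]]] = {}
    trace: list[float] = []

    def record(subset: list[str], s: float) -> None:
        trace.append(s)
        size = len(subset)
        if size not in best or s > best[size][0]:
            best[size] = (s, list(subset))

    current: list[str] = names.copy() if not forward else []
    if not forward:
        record(current, score(current))

    def best_addition(subset: list[str]) -> tuple[str | None, float]:
        cand_best, s_best = None, -np.inf
        for n in names:                      # registry order breaks ties
            if n in subset:
                continue
            s = score(subset + [n])
            if s > s_best:
                cand_best, s_best = n, s
        return cand_best, s_best

    def best_removal(subset: list[str]) -> tuple[str | None, float]:
        cand_best, s_best = None, -np.inf
        for n in subset:
            s = score([m for m in subset if m != n])
            if s > s_best:
                cand_best, s_best = n, s
        return cand_best, s_best

    if forward:  # SFFS
        while len(current) < max_k:
            add, s = best_addition(current)
            current.append(add)
            record(current, s)
            # conditional exclusion while it beats the best smaller subset
            while len(current) > 2:
                rem, s_rem = best_removal(current)
                if rem == current[-1]:
                    break
                if s_rem > best[len(current) - 1][0]:
                    current.remove(rem)
                    record(current, s_rem)
                else:
                    break
    else:  # SBFS
        while len(current) > 1:
            rem, s = best_removal(current)
            current.remove(rem)
            record(current, s)
            # conditional inclusion while it beats the best larger subset
            while len(current) < len(names) - 1:
                add, s_add = best_addition(current)
                if add == rem:
                    break
                if s_add > best[len(current) + 1][0]:
                    current.append(add)
                    record(current, s_add)
                else:
                    break

    sizes = [k for k in best if 1 <= k <= max_k] if forward else list(best)
    if not sizes:
        raise EmptySelectionError("wrapper search found no subset")
    top = max(sizes, key=lambda k: (best[k][0], -k))
    return SelectionResult(method="sffs" if forward else "sbfs",
                           selected=best[top][1], score_trace=trace)


def sffs(matrix: FeatureMatrix, model_spec: str = "rf", max_k: int = 10,
         ) -> SelectionResult:
    """Sequential floating forward selection scored by mean CV AUROC."""
    return _wrapper_search(matrix, model_spec, max_k, forward=True)


def sbfs(matrix: FeatureMatrix, model_spec: str = "rf") -> SelectionResult:
    """Sequential floating backward selection (search down to one feature)."""
    return _wrapper_search(matrix, model_spec,
                           max_k=matrix.X.shape[1], forward=False)


@dataclass
class EvalResult:
    model: str
    features: list[str]
    cv_aurocs: list[float]
    cv_mean_auroc: float
    test_auroc: float


def fit_evaluate(model_spec: str, matrix: FeatureMatrix,
                 selection: SelectionResult) -> EvalResult:
    """CV AUROC on the training folds and AUROC on the held-out rows."""
    if not selection.selected:
        raise EmptySelectionError("selection is empty")
    cols = selection.selected
    X, y, folds = matrix.train_data(cols)
    estimator = make_model(model_spec, seed=matrix.seed)
    cv_aurocs = []
    for k in range(int(folds.max()) + 1):
        val = folds == k
        model = clone(estimator)
        model.fit(X[~val], y[~val])
        cv_aurocs.append(float(roc_auc_score(y[val],
                                             model.predict_proba(X[val])[:, 1])))
    final = clone(estimator)
    final.fit(X, y)
    Xt, yt = matrix.test_data(cols)
    test_auroc = float(roc_auc_score(yt, final.predict_proba(Xt)[:, 1]))
    return EvalResult(model=model_spec, features=list(cols),
                      cv_aurocs=cv_aurocs,
                      cv_mean_auroc=float(np.mean(cv_aurocs)),
                      test_auroc=test_auroc)
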