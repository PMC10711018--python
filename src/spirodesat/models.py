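"""The five classifier specifications compared in the pipeline.

Hyperparameters favour small, regularized models: shallow trees, few
hundred estimators, K = 5 neighbours, an RBF kernel of moderate C.
Distance- and margin-based models are wrapped with a standardizer fitted
inside each CV fold so no scaling statistics leak across folds.
"""

from __future__ import annotations

import warnings

from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = ["MODEL_SPECS", "make_model"]

# cosmetic noise from the booster/SVC wrappers; results are unaffected
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names")
warnings.filterwarnings(
    "ignore", message="The `probability` parameter was deprecated")

MODEL_SPECS = ("rf", "xgb", "lgbm", "knn", "svm")


def make_model(spec: str, seed: int = 0, **overrides):
    """Instantiate a fresh, seeded estimator for ``spec``."""
    if spec == "rf":
        params = dict(n_estimators=200, max_depth=5, min_samples_leaf=2,
                      random_state=seed, n_jobs=1)
        params.update(overrides)
        return RandomForestClassifier(**params)
    if spec == "xgb":
        params = dict(n_estimators=150, max_depth=3, learning_rate=0.1,
                      subsample=0.8, colsample_bytree=0.8,
                      eval_metric="logloss", random_state=seed, n_jobs=1,
                      verbosity=0)
        params.update(overrides)
        return XGBClassifier(**params)
    if spec == "lgbm":
        params = dict(n_estimators=150, max_depth=3, num_leaves=7,
                      learning_rate=0.1, random_state=seed, n_jobs=1,
                      verbose=-1)
        params.update(overrides)
        return LGBMClassifier(**params)
    if spec == "knn":
        params = dict(n_neighbors=5)
        params.update(overrides)
        return Pipeline([("scale", StandardScaler()),
                         ("knn", KNeighborsClassifier(**params))])
    if spec == "svm":
        params = dict(C=1.0, kernel="rbf", gamma="scale", probability=True,
                      random_state=seed)
        params.update(overrides)
        return Pipeline([("scale", StandardScaler()), ("svm", SVC(**params))])
    raise ValueError(f"unknown model spec {spec!r}; choose from {MODEL_SPECS}")
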