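"""The linear Desaturation Prediction Index (DPI).

The wrapper-selected feature set is reduced further with an L1-penalized
(LASSO) linear fit — penalty chosen by 5-fold cross-validation with the
one-standard-error rule on standardized training features — and the
surviving features enter an ordinary-least-squares regression of the
binary desaturation label on the raw feature values.  The fitted
coefficients define the index

    DPI = intercept + sum_j  c_j * F_j

which is a linear probability score: higher DPI, higher predicted risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .errors import EmptySelectionError

__all__ = ["DPIModel", "lasso_select", "fit_dpi", "compute_dpi",
           "compute_dpi_matrix"]


@dataclass
class DPIModel:
    features: list[str]
    coefficients: np.ndarray
    intercept: float
    stderr: np.ndarray | None = None  # OLS standard errors, per coefficient

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.features) != self.coefficients.size:
            raise ValueError("one coefficient per feature required")
        if not np.isfinite(self.coefficients).all() or not np.isfinite(
                self.intercept):
            raise ValueError("coefficients must be finite")

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "stderr": ([float(s) for s in self.stderr]
                       if self.stderr is not None else None),
        }


def lasso_select(X: pd.DataFrame, y, seed: int = 0, cv: int = 5,
                 one_se: bool = True) -> list[str]:
    """Features with non-zero LASSO coefficient (training rows only).

    Features are standardized before the fit; the penalty is the largest
    alpha whose CV error is within one standard error of the minimum
    (falling back to the CV-optimal alpha when ``one_se`` is off).
    """
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    mu, sd = Xv.mean(axis=0), Xv.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xv - mu) / sd
    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
    search = LassoCV(alphas=100, cv=folds, max_iter=50_000).fit(Z, y)
    alpha = float(search.alpha_)
    if one_se:
        mean_mse = search.mse_path_.mean(axis=1)
        se_mse = search.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv)
        i_min = int(np.argmin(mean_mse))
        limit = mean_mse[i_min] + se_mse[i_min]
        ok = np.flatnonzero(mean_mse <= limit)
        # alphas_ is sorted descending: the first admissible one is largest
        alpha = float(search.alphas_[ok[0]])
    def survivors_at(a: float) -> list[str]:
        coefs = Lasso(alpha=a, max_iter=50_000).fit(Z, y).coef_
        # coordinate descent can leave O(eps) residues on dropped features
        return [name for name, c in zip(X.columns, coefs) if abs(c) > 1e-10]

    survivors = survivors_at(alpha)
    if not survivors and alpha != float(search.alpha_):
        # 1-SE rule can over-penalize small cohorts; fall back to CV optimum
        survivors = survivors_at(float(search.alpha_))
    if not survivors:
        raise EmptySelectionError("LASSO zeroed every coefficient")
    return survivors


def fit_dpi(X: pd.DataFrame, y) -> DPIModel:
    """OLS of the 0/1 label on the raw surviving features.

    This is a linear probability model: the index is linear in the raw
    feature values so it can be evaluated at the bedside without
    standardization constants.
    """
    y = np.asarray(y, dtype=float)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            "singular design: collinear features in the DPI fit")
    res = sm.OLS(y, design).fit()
    return DPIModel(features=list(X.columns),
                    coefficients=res.params[1:],
                    intercept=float(res.params[0]),
                    stderr=np.asarray(res.bse[1:]))


def compute_dpi(model: DPIModel, features: pd.Series | dict) -> float:
    """Evaluate the linear index on one case's feature vector."""
    values = []
    for name in model.features:
        try:
            values.append(float(features[name]))
        except KeyError:
            raise LookupError(f"feature {name!r} missing from input") from None
    return float(model.intercept + np.dot(model.coefficients, values))


def compute_dpi_matrix(model: DPIModel, X: pd.DataFrame) -> np.ndarray:
    """Vectorized index over a feature matrix."""
    missing = [n for n in model.features if n not in X.columns]
    if missing:
        raise LookupError(f"features missing from input: {missing}")
    return (model.intercept
            + X[model.features].to_numpy(dtype=float) @ model.coefficients)
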