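"""Normality-gated group comparisons, AUROC machinery and threshold tables.

The group test follows the clinical convention: Shapiro-Wilk on each
group at a stringent alpha of 0.01 (small samples over-reject, hence the
strict gate); if both groups look normal an independent t-test is used,
otherwise a two-sided Mann-Whitney U.  AUROC is computed in its
tie-corrected rank (Mann-Whitney) form with a percentile-bootstrap
confidence interval and a permutation test for the null of no
discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

__all__ = [
    "StatsConfig",
    "GroupTestResult",
    "group_compare",
    "auroc",
    "auroc_ci",
    "permutation_pvalue",
    "threshold_metrics",
]


@dataclass(frozen=True)
class StatsConfig:
    shapiro_alpha: float = 0.01
    group_test_alpha: float = 0.05
    n_boot: int = 2000
    dpi_thresholds: tuple = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))

    def __post_init__(self) -> None:
        if not (0 < self.shapiro_alpha < 1 and 0 < self.group_test_alpha < 1):
            raise ValueError("alphas must be in (0, 1)")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")


@dataclass(frozen=True)
class GroupTestResult:
    test: str       # "t-test" or "mann-whitney"
    p_value: float
    statistic: float


def group_compare(a, b, cfg: StatsConfig | None = None) -> GroupTestResult:
    """Shapiro-gated two-sample comparison of one feature."""
    cfg = cfg or StatsConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    normal = all(spstats.shapiro(g).pvalue > cfg.shapiro_alpha
                 for g in (a, b))
    if normal:
        res = spstats.ttest_ind(a, b)
        return GroupTestResult("t-test", float(res.pvalue),
                               float(res.statistic))
    res = spstats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupTestResult("mann-whitney", float(res.pvalue),
                           float(res.statistic))


def auroc(scores, labels) -> float:
    """AUROC via the tie-corrected rank (Mann-Whitney) statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = spstats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def auroc_ci(scores, labels, cfg: StatsConfig | None = None,
             seed: int = 0) -> tuple[float, tuple[float, float]]:
    """AUROC with a seeded percentile-bootstrap confidence interval."""
    cfg = cfg or StatsConfig()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    point = auroc(scores, labels)
    rng = np.random.default_rng(seed)
    n = labels.size
    boot = []
    while len(boot) < cfg.n_boot:
        idx = rng.integers(0, n, n)
        if labels[idx].min() == labels[idx].max():
            continue
        boot.append(auroc(scores[idx], labels[idx]))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return point, (float(lo), float(hi))


def permutation_pvalue(scores, labels, n_perm: int = 1000,
                       seed: int = 0) -> float:
    """One-sided permutation p-value for AUROC > 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    obs = auroc(scores, labels)
    rng = np.random.default_rng(seed)
    hits = sum(auroc(scores, rng.permutation(labels)) >= obs
               for _ in range(n_perm))
    return (1 + hits) / (n_perm + 1)


def threshold_metrics(scores, labels, cfg: StatsConfig | None = None,
                      ) -> pd.DataFrame:
    """Accuracy / sensitivity / specificity / PPV over a threshold grid.

    A score at or above the threshold is called positive.  Metrics whose
    denominator is empty (e.g. PPV with no positive calls) are NaN.
    """
    cfg = cfg or StatsConfig()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size:
        raise ValueError("scores and labels must have the same length")
    rows = []
    for thr in cfg.dpi_thresholds:
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        rows.append({
            "threshold": float(thr),
            "accuracy": (tp + tn) / labels.size,
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "ppv": tp / (tp + fp) if tp + fp else np.nan,
        })
    return pd.DataFrame(rows)
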