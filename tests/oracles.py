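"""Independent brute-force references used by the test suite only."""

import itertools
import math

import numpy as np


def kendall_tau_oracle(x, y):
    """O(n^2) Kendall tau-b with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    nc = nd = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = x[i] - x[j]
            b = y[i] - y[j]
            if a == 0 and b == 0:
                tx += 1
                ty += 1
            elif a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif (a > 0) == (b > 0):
                nc += 1
            else:
                nd += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    return (nc - nd) / denom


def dtw_oracle(a, b):
    """Full-table DTW (diagonal-preferring ties), normalized by path length.

    Written over plain Python lists, independently of the package kernel.
    """
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    n, m = len(a), len(b)
    INF = float("inf")
    D = [[INF] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = D[i - 1][j - 1]
            if D[i - 1][j] < best:
                best = D[i - 1][j]
            if D[i][j - 1] < best:
                best = D[i][j - 1]
            D[i][j] = abs(a[i - 1] - b[j - 1]) + best
    i, j, length = n, m, 0
    while i > 0 or j > 0:
        length += 1
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            best, step = D[i - 1][j - 1], 0
            if D[i - 1][j] < best:
                best, step = D[i - 1][j], 1
            if D[i][j - 1] < best:
                step = 2
            if step == 0:
                i, j = i - 1, j - 1
            elif step == 1:
                i -= 1
            else:
                j -= 1
    return D[n][m] / length


def exhaustive_best_subset(names, score_fn, max_k):
    """Best-scoring feature subset by brute force (all sizes 1..max_k)."""
    best_score, best_subset = -np.inf, None
    for k in range(1, max_k + 1):
        for combo in itertools.combinations(names, k):
            s = score_fn(list(combo))
            if s > best_score:
                best_score, best_subset = s, set(combo)
    return best_score, best_subset


def auroc_trapezoid(scores, labels):
    """AUROC by explicit trapezoidal integration of the ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    p = labels.sum()
    n = len(labels) - p
    for t in thresholds:
        pred = scores >= t
        tpr.append(np.sum(pred & (labels == 1)) / p)
        fpr.append(np.sum(pred & (labels == 0)) / n)
    return float(np.trapezoid(tpr, fpr))
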