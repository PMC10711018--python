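"""Dynamic time warping distance, path-length normalized.

Classic symmetric step pattern (diagonal / up / left), absolute-difference
local cost.  The accumulated cost is divided by the length of the optimal
warping path; ties between predecessors are broken in favour of the
diagonal step (then the vertical), which makes the path length — and hence
the normalized distance — deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dtw_distance"]


# finite sentinel instead of inf: safe under fastmath
_BIG = 1e300


@njit(cache=True, fastmath=True)
def _dtw_core(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover
    n, m = a.size, b.size
    D = np.empty((n + 1, m + 1))
    D[0, :] = _BIG
    D[:, 0] = _BIG
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        row = D[i]
        prev = D[i - 1]
        for j in range(1, m + 1):
            # strict < keeps the diagonal on ties, then the vertical step
            d = prev[j - 1]
            if prev[j] < d:
                d = prev[j]
            if row[j - 1] < d:
                d = row[j - 1]
            row[j] = abs(ai - b[j - 1]) + d
    # backtrack the optimal path with the same tie rule to get its length
    i, j, length = n, m, 0
    while i > 0 or j > 0:
        length += 1
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            d = D[i - 1, j - 1]
            step = 0
            if D[i - 1, j] < d:
                d = D[i - 1, j]
                step = 1
            if D[i, j - 1] < d:
                step = 2
            if step == 0:
                i -= 1
                j -= 1
            elif step == 1:
                i -= 1
            else:
                j -= 1
    return D[n, m] / length


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """DTW distance between two 1-D series, normalized by path length."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_distance requires non-empty series")
    return float(_dtw_core(a, b))


def warm_up() -> None:
    """Trigger JIT compilation on a tiny input (useful before timing)."""
    dtw_distance(np.zeros(2), np.ones(2))
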