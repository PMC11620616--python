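"""Greedy one-to-one matching of event times within a tolerance.

Shared by detector validation (detections vs true troughs) and spike-train
comparison (overlap scores): candidate pairs within the tolerance are taken
in order of ascending time difference, each event matched at most once.
Ties in |Δt| are broken deterministically by (first index, second index).
"""

from __future__ import annotations

import numpy as np

__all__ = ["greedy_match"]


def greedy_match(a: np.ndarray, b: np.ndarray, tolerance: float) -> np.ndarray:
    """Match sorted event times ``a`` against ``b`` within ``tolerance``.

    Returns an (m, 2) integer array of (index into a, index into b) pairs.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    lo = np.searchsorted(b, a - tolerance, side="left")
    hi = np.searchsorted(b, a + tolerance, side="right")
    ii, jj, dd = [], [], []
    for i in range(a.size):
        for j in range(lo[i], hi[i]):
            ii.append(i)
            jj.append(j)
            dd.append(abs(a[i] - b[j]))
    if not ii:
        return np.empty((0, 2), dtype=np.int64)
    order = np.lexsort((jj, ii, dd))
    used_a = np.zeros(a.size, dtype=bool)
    used_b = np.zeros(b.size, dtype=bool)
    pairs = []
    for k in order:
        i, j = ii[k], jj[k]
        if not used_a[i] and not used_b[j]:
            used_a[i] = True
            used_b[j] = True
            pairs.append((i, j))
    pairs.sort()
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
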