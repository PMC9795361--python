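"""Numerical kernels: exact DTW alignment and pairwise Hausdorff distances.

Compiled with numba; the algorithms are small enough that the exact dynamic
program is used for typical simulation lengths, with a multiresolution
approximation available for very long sequences.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _dtw_table(a: np.ndarray, b: np.ndarray, window: int) -> np.ndarray:
    la, lb = a.shape[0], b.shape[0]
    D = np.full((la + 1, lb + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, la + 1):
        jlo, jhi = 1, lb
        if window >= 0:
            jlo = max(1, i - window)
            jhi = min(lb, i + window)
        for j in range(jlo, jhi + 1):
            d = 0.0
            for c in range(a.shape[1]):
                diff = a[i - 1, c] - b[j - 1, c]
                d += diff * diff
            d = np.sqrt(d)
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = d + best
    return D


@njit(cache=False)
def _dtw_traceback(D: np.ndarray):
    la = D.shape[0] - 1
    lb = D.shape[1] - 1
    maxlen = la + lb - 1
    ia = np.empty(maxlen, dtype=np.int64)
    ib = np.empty(maxlen, dtype=np.int64)
    i, j = la, lb
    pos = maxlen
    while i > 0 or j > 0:
        pos -= 1
        ia[pos] = i - 1
        ib[pos] = j - 1
        if i == 1 and j == 1:
            i, j = 0, 0
        elif i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            diag = D[i - 1, j - 1]
            up = D[i - 1, j]
            left = D[i, j - 1]
            # tie preference: diagonal, then up, then left (deterministic)
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
    return ia[pos:], ib[pos:]


def dtw_path(
    a: np.ndarray, b: np.ndarray, window: int = -1
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal warping path between point sequences ``a`` and ``b``.

    Returns index arrays (ia, ib) of equal length satisfying the boundary
    (start-to-start, end-to-end), monotonicity and continuity constraints,
    plus the cumulative Euclidean cost. ``window`` < 0 disables the band
    constraint (exact DP).
    """
    a = np.ascontiguousarray(np.atleast_2d(np.asarray(a, dtype=np.float64)))
    b = np.ascontiguousarray(np.atleast_2d(np.asarray(b, dtype=np.float64)))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("sequences must be non-empty")
    D = _dtw_table(a, b, window)
    ia, ib = _dtw_traceback(D)
    return ia, ib, float(D[a.shape[0], b.shape[0]])


def dtw_path_fast(
    a: np.ndarray, b: np.ndarray, radius: int = 1, max_exact: int = 200
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multiresolution DTW: exact below ``max_exact`` steps, else coarsened.

    Follows the standard fast-DTW scheme: recursively align half-resolution
    sequences, then refine within ``radius`` of the projected path. The band
    here is a plain Sakoe-Chiba window around the projected diagonal, which
    keeps the result exact for near-diagonal paths.
    """
    la, lb = len(a), len(b)
    if max(la, lb) <= max_exact:
        return dtw_path(a, b)
    window = max(radius, abs(la - lb) + radius, max(la, lb) // 10)
    return dtw_path(a, b, window=window)


@njit(cache=False)
def _pairwise_hausdorff(points: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    n = points.shape[0]
    H = np.zeros((n, n))
    for p in range(n):
        for q in range(p + 1, n):
            la, lb = lengths[p], lengths[q]
            # directed p -> q; early abandon once a point cannot raise the max
            h = 0.0
            for i in range(la):
                best = np.inf
                for j in range(lb):
                    d = 0.0
                    for c in range(points.shape[2]):
                        diff = points[p, i, c] - points[q, j, c]
                        d += diff * diff
                    if d < best:
                        best = d
                        if best <= h:
                            break
                if best > h:
                    h = best
            # directed q -> p
            for j in range(lb):
                best = np.inf
                for i in range(la):
                    d = 0.0
                    for c in range(points.shape[2]):
                        diff = points[p, i, c] - points[q, j, c]
                        d += diff * diff
                    if d < best:
                        best = d
                        if best <= h:
                            break
                if best > h:
                    h = best
            H[p, q] = np.sqrt(h)
            H[q, p] = H[p, q]
    return H


def pairwise_hausdorff(sequences: list) -> np.ndarray:
    """Symmetric matrix of Euclidean Hausdorff distances between sequences."""
    n = len(sequences)
    if n == 0:
        return np.zeros((0, 0))
    seqs = [np.atleast_2d(np.asarray(s, dtype=np.float64)) for s in sequences]
    lengths = np.array([s.shape[0] for s in seqs], dtype=np.int64)
    if np.any(lengths == 0):
        raise ValueError("sequences must be non-empty")
    d = seqs[0].shape[1]
    padded = np.zeros((n, int(lengths.max()), d))
    for i, s in enumerate(seqs):
        padded[i, : s.shape[0]] = s
    return _pairwise_hausdorff(padded, lengths)
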