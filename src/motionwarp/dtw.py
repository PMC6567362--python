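"""Dynamic time warping of unequal-length motion sequences.

Implements the classic unconstrained DTW: the local cost between two samples
is their squared difference, costs are accumulated over an N x M grid by the
minimum-of-three recurrence

    sigma(n, m) = delta(n, m) + min(sigma(n-1, m), sigma(n, m-1), sigma(n-1, m-1)),

and the optimal warping path is recovered by traceback.  A lower total cost
means the two sequences are more similar; the alignment absorbs speed and
duration differences, which is what makes template matching on raw,
variable-length sensor traces possible.

No band constraint is applied: the full O(N*M) matrix is computed, matching
the intended use on short (tens of samples) motion segments.

Index convention: warping paths are reported as 1-based (n, m) pairs so that
a path runs from (1, 1) to (N, M); internal arrays are 0-based.
"""

from __future__ import annotations

import numpy as np

from .sequence import MotionSequence, WarpingResult

__all__ = [
    "local_cost",
    "accumulate_cost_matrix",
    "traceback_path",
    "dtw_distance",
]


def _as_vector(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty sequence passed to DTW")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values passed to DTW")
    return arr


def local_cost(a: float, b: float) -> float:
    """Squared difference (a - b)**2 between two samples.

    Symmetric, non-negative, and zero exactly when the samples coincide.
    """
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("local_cost requires finite inputs")
    d = float(a) - float(b)
    return d * d


def accumulate_cost_matrix(x, z) -> np.ndarray:
    """Accumulated-cost grid sigma for sequences ``x`` (length N) and ``z`` (length M).

    Boundary cells accumulate along their single admissible predecessor
    (first row to the left, first column upward); interior cells take the
    minimum of the three predecessors.
    """
    xv = _as_vector(x)
    zv = _as_vector(z)
    delta = (xv[:, None] - zv[None, :]) ** 2
    n, m = delta.shape
    sigma = np.empty_like(delta)
    sigma[0, 0] = delta[0, 0]
    for j in range(1, m):
        sigma[0, j] = sigma[0, j - 1] + delta[0, j]
    for i in range(1, n):
        row = sigma[i]
        prev = sigma[i - 1]
        drow = delta[i]
        row[0] = prev[0] + drow[0]
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if row[j - 1] < best:
                best = row[j - 1]
            row[j] = best + drow[j]
    return sigma


def traceback_path(cost_grid: np.ndarray) -> list:
    """Recover the optimal warping path from an accumulated-cost grid.

    Walks backward from (N, M) to (1, 1), at each step moving to the
    predecessor with minimal accumulated cost.  Ties prefer the diagonal,
    then the vertical (previous row), then the horizontal step, which yields
    the shortest path among equal-cost alternatives.  Returns 1-based pairs.
    """
    sigma = np.asarray(cost_grid, dtype=float)
    n, m = sigma.shape
    i, j = n - 1, m - 1
    path = [(i + 1, j + 1)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag = sigma[i - 1, j - 1]
            vert = sigma[i - 1, j]
            horiz = sigma[i, j - 1]
            best = min(diag, vert, horiz)
            if diag == best:
                i -= 1
                j -= 1
            elif vert == best:
                i -= 1
            else:
                j -= 1
        path.append((i + 1, j + 1))
    path.reverse()
    return path


def dtw_distance(x, z) -> WarpingResult:
    """Full DTW alignment of ``x`` and ``z``.

    Returns a :class:`~motionwarp.sequence.WarpingResult` whose
    ``total_cost`` equals both the bottom-right accumulated cost and the sum
    of local costs along the traced path.
    """
    sigma = accumulate_cost_matrix(x, z)
    path = traceback_path(sigma)
    total = float(sigma[-1, -1])
    return WarpingResult(cost_matrix=sigma, path=path, total_cost=total)


def dtw_cost(x, z) -> float:
    """Total warping cost only (no path), the quantity used for matching."""
    return float(accumulate_cost_matrix(x, z)[-1, -1])
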