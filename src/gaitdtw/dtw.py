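"""Banded dynamic time warping with a z-normalised pointwise distance.

The pointwise distance between sample i of u and sample j of v is

    d(u_i, v_j) = ((u_i - mean(u)) / sd(u) - (v_j - mean(v)) / sd(v))^2

with the mean and (population) standard deviation taken once over each
whole series, which makes the DTW distance invariant to a positive affine
rescaling of either input. The alignment path is boundary-anchored at
(0, 0) and (Nu-1, Nv-1), monotone with unit steps (1,0), (0,1), (1,1),
and confined to a Sakoe-Chiba-style band |j - i| <= maxsamp (non-strict,
so a band of 0 forces the diagonal). The reported distance is the plain
cumulative cost along the optimal path, not length-normalised.

The dynamic program is compiled with numba; :func:`dtw_bruteforce` is a
deliberately naive exhaustive path enumeration kept as an independent
oracle for testing on tiny inputs.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit

from .core import DtwResult, WarpingPath
from .errors import BandInfeasibleError, DegenerateSeriesError

__all__ = ["znorm", "dtw", "dtw_distance", "dtw_bruteforce"]


def znorm(series: Sequence[float]) -> np.ndarray:
    """Return the series rescaled to mean 0 and variance 1 (divisor N).

    Raises DegenerateSeriesError for series shorter than 2 samples or with
    zero standard deviation, for which the rescaling is undefined.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise DegenerateSeriesError(f"expected a 1-D series, got shape {x.shape}")
    if x.size < 2:
        raise DegenerateSeriesError(f"series of length {x.size} cannot be z-normalised")
    sd = float(np.std(x))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSeriesError("constant series: sigma = 0")
    return (x - float(np.mean(x))) / sd


@njit(cache=True)
def _dp_matrix(zu: np.ndarray, zv: np.ndarray, maxsamp: int) -> np.ndarray:  # pragma: no cover
    nu = zu.shape[0]
    nv = zv.shape[0]
    D = np.full((nu, nv), np.inf)
    for i in range(nu):
        jlo = i - maxsamp
        if jlo < 0:
            jlo = 0
        jhi = i + maxsamp
        if jhi > nv - 1:
            jhi = nv - 1
        for j in range(jlo, jhi + 1):
            diff = zu[i] - zv[j]
            d = diff * diff
            if i == 0 and j == 0:
                D[i, j] = d
            else:
                best = np.inf
                if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                    best = D[i - 1, j - 1]
                if i > 0 and D[i - 1, j] < best:
                    best = D[i - 1, j]
                if j > 0 and D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = d + best
    return D


def _resolve_band(nu: int, nv: int, maxsamp: Union[int, float, None]) -> int:
    if maxsamp is None or maxsamp == math.inf:
        return max(nu, nv)
    m = int(maxsamp)
    if m < 0:
        raise ValueError(f"maxsamp must be non-negative, got {maxsamp}")
    if abs(nu - nv) > m:
        raise BandInfeasibleError(
            f"length difference |{nu} - {nv}| = {abs(nu - nv)} exceeds maxsamp = {m}: "
            "no boundary-anchored path fits in the band"
        )
    return m


def _traceback(D: np.ndarray) -> WarpingPath:
    # Prefer diagonal, then vertical (advance in u), then horizontal, so the
    # returned path is unique and reproducible even with cost ties.
    i, j = D.shape[0] - 1, D.shape[1] - 1
    rev = [(i, j)]
    while (i, j) != (0, 0):
        cand = []
        if i > 0 and j > 0:
            cand.append((D[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            cand.append((D[i - 1, j], 1, (i - 1, j)))
        if j > 0:
            cand.append((D[i, j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(cand, key=lambda c: (c[0], c[1]))
        rev.append((i, j))
    return WarpingPath(tuple(reversed(rev)))


def _znorm_pair(u: Sequence[float], v: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    return znorm(u), znorm(v)


def dtw(
    u: Sequence[float],
    v: Sequence[float],
    maxsamp: Union[int, float, None] = 20,
) -> DtwResult:
    """Optimal banded alignment of u against v.

    Parameters
    ----------
    u, v
        1-D series, each of length >= 2 with non-zero variance.
    maxsamp
        Band half-width in samples; ``None`` or ``inf`` disables the band.

    Returns
    -------
    DtwResult with the cumulative distance and the warping path. The path
    satisfies boundary, monotonicity and band invariants, and re-summing
    the pointwise distances along it reproduces the distance.
    """
    zu, zv = _znorm_pair(u, v)
    m = _resolve_band(zu.size, zv.size, maxsamp)
    D = _dp_matrix(zu, zv, m)
    dist = float(D[-1, -1])
    if not np.isfinite(dist):
        raise BandInfeasibleError("no path reaches the final cell within the band")
    return DtwResult(distance=dist, path=_traceback(D))


def dtw_distance(
    u: Sequence[float],
    v: Sequence[float],
    maxsamp: Union[int, float, None] = 20,
) -> float:
    """DTW distance only (no traceback); same contract as :func:`dtw`."""
    zu, zv = _znorm_pair(u, v)
    m = _resolve_band(zu.size, zv.size, maxsamp)
    dist = float(_dp_matrix(zu, zv, m)[-1, -1])
    if not np.isfinite(dist):
        raise BandInfeasibleError("no path reaches the final cell within the band")
    return dist


def _dtw_distance_prenormed(zu: np.ndarray, zv: np.ndarray, maxsamp: int) -> float:
    """Hot-loop variant: inputs already z-normalised, band already feasible."""
    return float(_dp_matrix(zu, zv, maxsamp)[-1, -1])


def dtw_bruteforce(
    u: Sequence[float],
    v: Sequence[float],
    maxsamp: Union[int, float, None] = None,
) -> float:
    """Exhaustive-enumeration DTW distance, for testing only.

    Recursively explores every boundary-anchored monotone unit-step path
    within the band, with no memoisation, so it is independent of the
    dynamic program it cross-checks. Limited to series of length <= 10.
    """
    zu, zv = _znorm_pair(u, v)
    nu, nv = zu.size, zv.size
    if nu > 10 or nv > 10:
        raise ValueError(f"brute force limited to lengths <= 10, got ({nu}, {nv})")
    m = _resolve_band(nu, nv, maxsamp)

    def rec(i: int, j: int) -> float:
        d = (zu[i] - zv[j]) ** 2
        if i == nu - 1 and j == nv - 1:
            return d
        best = math.inf
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < nu and nj < nv and abs(nj - ni) <= m:
                c = rec(ni, nj)
                if c < best:
                    best = c
        return d + best

    dist = rec(0, 0)
    if not math.isfinite(dist):
        raise BandInfeasibleError("no path reaches the final cell within the band")
    return float(dist)


def path_cost(u: Sequence[float], v: Sequence[float], path: WarpingPath) -> float:
    """Re-sum the z-normalised pointwise distances along a given path."""
    zu, zv = _znorm_pair(u, v)
    return float(sum((zu[i] - zv[j]) ** 2 for i, j in path.pairs))
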