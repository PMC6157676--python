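"""Trend and changepoint inference on composite curves.

Millennial trend is tested with Spearman's rank correlation between the
composite and calendar time (time = -age, so increasing burning toward the
present gives rho > 0, the sign convention used throughout).  Changes in
mean level are found by exact penalized segmentation: the objective is

    sum over segments of SSE(segment) / sigma2_hat  +  penalty * (#changepoints)

with sigma2_hat estimated from first differences of the series, so the
manual penalty is dimensionless.  The optimum is computed by dynamic
programming; a brute-force enumeration oracle over all admissible boundary
sets is provided for verification at small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .composite import CompositeCurve
from .errors import EstimationError, RefusalError, ValidationError


@dataclass
class TrendResult:
    """Spearman rank trend: rho in [-1, 1], two-sided p, n ages used."""

    rho: float
    p: float
    n: int


@dataclass
class ChangepointResult:
    """Mean-shift segmentation: boundary ages (oldest first) and segment means.

    ``segment_means`` are ordered oldest segment first, so
    ``segment_means[i]`` and ``segment_means[i+1]`` flank
    ``change_ages[i]``.  ``objective`` is the minimized penalized cost.
    """

    change_ages: np.ndarray
    segment_means: np.ndarray
    penalty: float
    objective: float


def _curve_series(curve: CompositeCurve) -> tuple[np.ndarray, np.ndarray]:
    mask = curve.defined
    return curve.ages[mask], curve.mean_z[mask]


def spearman_trend(curve: CompositeCurve) -> TrendResult:
    """Rank correlation of the composite with calendar time (= -age)."""
    ages, z = _curve_series(curve)
    if ages.size < 3:
        raise EstimationError("need >= 3 defined composite ages for a trend test")
    rho, p = stats.spearmanr(-ages, z)
    return TrendResult(rho=float(rho), p=float(p), n=int(ages.size))


def _as_series(curve_or_series, ages=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve_or_series, CompositeCurve):
        return _curve_series(curve_or_series)
    x = np.asarray(curve_or_series, dtype=float)
    a = np.arange(x.size, dtype=float) if ages is None else np.asarray(ages, float)
    return a, x


def _diff_variance(x: np.ndarray) -> float:
    """Noise variance estimate from lag-1 differences: mean(diff^2)/2."""
    d = np.diff(x)
    return float(np.mean(d * d) / 2.0)


def _segment_cost_arrays(x: np.ndarray):
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    return c1, c2


def _sse(c1: np.ndarray, c2: np.ndarray, i, j):
    """SSE of x[i:j] around its mean, vectorized over i or j."""
    n = j - i
    s = c1[j] - c1[i]
    return (c2[j] - c2[i]) - s * s / n


def _objective(x: np.ndarray, boundaries, penalty: float, sigma2: float) -> float:
    c1, c2 = _segment_cost_arrays(x)
    edges = [0, *boundaries, x.size]
    sse = sum(_sse(c1, c2, i, j) for i, j in zip(edges[:-1], edges[1:]))
    return sse / sigma2 + penalty * len(boundaries)


def _dp_segment(
    x: np.ndarray, penalty: float, min_seg: int, max_cp: int | None
) -> tuple[list[int], float]:
    """Exact layered DP over (#changepoints, right endpoint)."""
    n = x.size
    sigma2 = _diff_variance(x)
    if sigma2 == 0.0:
        return [], 0.0
    c1, c2 = _segment_cost_arrays(x)
    kmax = n // min_seg - 1
    if max_cp is not None:
        kmax = min(kmax, max_cp)
    kmax = max(kmax, 0)
    idx = np.arange(n + 1)
    # best[k][j]: min unpenalized cost of x[0:j] split into k+1 segments
    best = np.full((kmax + 1, n + 1), np.inf)
    argp = np.zeros((kmax + 1, n + 1), dtype=int)
    valid0 = idx >= min_seg
    best[0, valid0] = _sse(c1, c2, 0, idx[valid0])
    for k in range(1, kmax + 1):
        # previous boundary i: k segments over x[0:i], new segment x[i:j]
        for j in range(min_seg * (k + 1), n + 1):
            i_lo, i_hi = min_seg * k, j - min_seg
            if i_hi < i_lo:
                continue
            ii = np.arange(i_lo, i_hi + 1)
            cand = best[k - 1, ii] + _sse(c1, c2, ii, j)
            b = int(np.argmin(cand))
            best[k, j] = cand[b]
            argp[k, j] = ii[b]
    totals = best[:, n] / sigma2 + penalty * np.arange(kmax + 1)
    k_best = int(np.argmin(totals))
    # backtrack
    bounds: list[int] = []
    j = n
    for k in range(k_best, 0, -1):
        i = int(argp[k, j])
        bounds.append(i)
        j = i
    bounds.reverse()
    return bounds, float(totals[k_best])


def _result_from_bounds(
    ages: np.ndarray, x: np.ndarray, bounds: list[int], penalty: float, objective: float
) -> ChangepointResult:
    edges = [0, *bounds, x.size]
    means_young_first = [float(x[i:j].mean()) for i, j in zip(edges[:-1], edges[1:])]
    # boundary age = midpoint between flanking bin centers (= shared bin edge
    # on a regular grid), reported oldest first
    change_ages = np.array(
        [(ages[b - 1] + ages[b]) / 2.0 for b in bounds], dtype=float
    )[::-1]
    return ChangepointResult(
        change_ages=change_ages,
        segment_means=np.array(means_young_first[::-1]),
        penalty=penalty,
        objective=objective,
    )


def detect_changepoints(
    curve_or_series,
    penalty: float = 5.0,
    min_seg: int = 5,
    max_cp: int | None = None,
    ages=None,
) -> ChangepointResult:
    """Optimal penalized mean-shift segmentation of a composite (or series).

    Accepts a :class:`CompositeCurve` (its defined ages, young to old) or a
    plain series with optional ``ages``.  ``min_seg`` is the minimum
    segment length in bins; ``max_cp`` caps the number of changepoints.
    """
    a, x = _as_series(curve_or_series, ages)
    if penalty < 0:
        raise ValidationError("penalty must be >= 0")
    if x.size < 2 * min_seg:
        raise EstimationError(
            f"series of length {x.size} too short for min_seg={min_seg}"
        )
    bounds, obj = _dp_segment(x, penalty, min_seg, max_cp)
    return _result_from_bounds(a, x, bounds, penalty, obj)


def exhaustive_changepoint_oracle(
    series,
    penalty: float,
    min_seg: int = 5,
    max_cp: int = 3,
    ages=None,
    max_enumeration: int = 200_000,
) -> ChangepointResult:
    """Brute-force global optimum over all admissible boundary sets.

    Verification oracle for :func:`detect_changepoints`; refuses series
    long enough to make enumeration explode.
    """
    a, x = _as_series(series, ages)
    n = x.size
    if n < 2 * min_seg:
        raise EstimationError("series too short")
    total = sum(comb(n, k) for k in range(max_cp + 1))
    if n > 16 and total > max_enumeration:
        raise RefusalError(
            f"enumeration bound exceeded (n={n}, max_cp={max_cp})"
        )
    sigma2 = _diff_variance(x)
    if sigma2 == 0.0:
        return _result_from_bounds(a, x, [], penalty, 0.0)
    positions = range(min_seg, n - min_seg + 1)
    best_bounds: list[int] = []
    best_obj = _objective(x, [], penalty, sigma2)
    for k in range(1, max_cp + 1):
        for combo in combinations(positions, k):
            if any(b2 - b1 < min_seg for b1, b2 in zip(combo, combo[1:])):
                continue
            obj = _objective(x, list(combo), penalty, sigma2)
            if obj < best_obj:
                best_obj = obj
                best_bounds = list(combo)
    return _result_from_bounds(a, x, best_bounds, penalty, best_obj)
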