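"""Nonparametric statistics for paleontological time series and group tests.

The battery consists of:

* generalized differencing — OLS detrending against bin midpoints followed by
  quasi-differencing with the residual lag-1 autocorrelation, removing trend
  and first-order autocorrelation before correlation testing;
* Spearman's rho and Kendall's tau-b rank correlations with two-tailed
  p-values (t approximation and tie-corrected normal approximation
  respectively);
* the Mann-Whitney U test on midranks, with the exact two-tailed p obtained
  by full enumeration of group assignments for small samples
  (n1 + n2 <= 20) and a tie-corrected, continuity-corrected normal
  approximation otherwise.

All p-values are reported uncorrected for multiple testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedStatisticError

#: Sample-size bound up to which the exact Mann-Whitney null is enumerated.
EXACT_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class CorrelationResult:
    statistic: float
    p_value: float
    n: int
    method: str  # "spearman" | "kendall"


@dataclass(frozen=True)
class GroupComparisonResult:
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal"


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("input vectors must be aligned")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def generalized_difference(series: Sequence[float], times: Sequence[float]) -> np.ndarray:
    """Detrend *series* against *times* and quasi-difference by lag-1 rho.

    Steps: (i) OLS of the series on time gives trend residuals ``r_t``;
    (ii) ``rho`` is the lag-1 Pearson autocorrelation of those residuals;
    (iii) the output is ``d_t = r_t - rho * r_{t-1}`` for t >= 2, with the
    first element kept as the plain trend residual ``r_1`` so the output
    stays aligned with the input for pairwise correlation.

    A constant (or exactly linear) series has no information left after
    detrending: a zero vector is returned with a warning.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("series and times must be aligned")
    if np.isnan(y).any() or np.isnan(t).any():
        raise ValueError("generalized_difference requires complete series; drop missing bins first")
    if y.size < 4:
        raise InsufficientDataError(f"generalized differencing needs >=4 points, got {y.size}")
    if np.ptp(t) == 0:
        raise ValueError("times are all identical")

    fit = sps.linregress(t, y)
    r = y - (fit.intercept + fit.slope * t)
    if np.allclose(r, 0.0):
        warnings.warn(
            "series is exactly linear in time; generalized difference is a zero vector",
            stacklevel=2,
        )
        return np.zeros_like(r)
    denom = np.std(r[:-1]) * np.std(r[1:])
    rho = 0.0 if denom == 0 else float(np.corrcoef(r[:-1], r[1:])[0, 1])
    out = np.empty_like(r)
    out[0] = r[0]
    out[1:] = r[1:] - rho * r[:-1]
    return out


def _rank_checks(x: np.ndarray, y: np.ndarray, method: str) -> None:
    if x.size < 3:
        raise InsufficientDataError(f"{method} needs >=3 complete pairs, got {x.size}")
    if np.ptp(sps.rankdata(x)) == 0 or np.ptp(sps.rankdata(y)) == 0:
        raise UndefinedStatisticError(f"{method} undefined: zero variance in ranks")


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rho on midranks with a two-tailed t-approximation p."""
    xc, yc = _complete_pairs(x, y)
    _rank_checks(xc, yc, "spearman")
    rho, p = sps.spearmanr(xc, yc)
    return CorrelationResult(float(rho), float(p), int(xc.size), "spearman")


def kendall(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Kendall's tau-b (tie-corrected) with a two-tailed normal-approximation p."""
    xc, yc = _complete_pairs(x, y)
    _rank_checks(xc, yc, "kendall")
    tau, p = sps.kendalltau(xc, yc, variant="b", method="asymptotic")
    return CorrelationResult(float(tau), float(p), int(xc.size), "kendall")


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(U_a, U_b, combined midranks); U_a + U_b == n1 * n2."""
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = ranks[:n1].sum()
    u_a = r_a - n1 * (n1 + 1) / 2.0
    return float(u_a), float(n1 * n2 - u_a), ranks


def _exact_two_tailed_p(ranks: np.ndarray, n1: int, u_min_obs: float) -> float:
    """P(min(U, n1*n2 - U) <= observed min U) by full enumeration.

    Enumerates every assignment of n1 of the combined midranks to the first
    group; valid for tied data since midranks are enumerated directly.
    """
    n = ranks.size
    n1n2 = n1 * (n - n1)
    offset = n1 * (n1 + 1) / 2.0
    hits = 0
    tol = 1e-9
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if min(u, n1n2 - u) <= u_min_obs + tol:
            hits += 1
    return hits / comb(n, n1)


def mann_whitney(
    a: Sequence[float], b: Sequence[float], method: str = "auto"
) -> GroupComparisonResult:
    """Two-tailed Mann-Whitney U test; U = min(U_a, U_b) on midranks.

    ``method`` may force ``"exact"`` (full enumeration) or ``"normal"``
    (tie-corrected normal approximation with continuity correction);
    ``"auto"`` enumerates when n1 + n2 <= EXACT_ENUMERATION_LIMIT.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("mann_whitney requires complete data")
    n1, n2 = int(a.size), int(b.size)
    u_a, u_b, ranks = _u_statistics(a, b)
    u_min = min(u_a, u_b)

    if method == "auto":
        method = "exact" if n1 + n2 <= EXACT_ENUMERATION_LIMIT else "normal"
    if method == "exact":
        p = _exact_two_tailed_p(ranks, n1, u_min)
    elif method == "normal":
        p = float(
            sps.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    else:
        raise ValueError(f"unknown method {method!r}; use 'auto', 'exact' or 'normal'")
    return GroupComparisonResult(u_min, p, n1, n2, method)


def gd_correlate(
    x: Sequence[float],
    y: Sequence[float],
    times: Sequence[float],
    method: str = "spearman",
    gd: bool = True,
) -> CorrelationResult:
    """Correlate two aligned bin series, optionally after generalized differencing.

    Bins missing either value are dropped pairwise first; with ``gd=True``
    both remaining sub-series are generalized-differenced against the
    corresponding bin midpoints before the rank correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(times, dtype=float)
    if not (x.shape == y.shape == t.shape):
        raise ValueError("x, y and times must be aligned")
    mask = ~(np.isnan(x) | np.isnan(y))
    xc, yc, tc = x[mask], y[mask], t[mask]
    if gd:
        xc = generalized_difference(xc, tc)
        yc = generalized_difference(yc, tc)
    func = {"spearman": spearman, "kendall": kendall}.get(method)
    if func is None:
        raise ValueError(f"unknown correlation method {method!r}")
    return func(xc, yc)
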