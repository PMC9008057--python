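"""Small shared statistics: block jackknife, 2x2 chi-squares, homogeneity."""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np
from scipy import stats as sps


class UndefinedResult(ValueError):
    """A statistic is undefined for the given data (e.g. zero denominator)."""


def block_jackknife_ratio(
    num: np.ndarray, den: np.ndarray, block_size: int
) -> Tuple[float, float, int, np.ndarray]:
    """Delete-one block jackknife for a ratio-of-sums statistic.

    The markers are cut into contiguous blocks of ``block_size`` (the last
    block may be shorter).  Returns (estimate, jackknife SE, number of
    blocks, per-block leave-one-out estimates).
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    if num.shape != den.shape:
        raise ValueError("numerator and denominator must have equal length")
    n = num.size
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    total_num = num.sum()
    total_den = den.sum()
    if total_den == 0:
        raise UndefinedResult("ratio undefined: zero denominator over all markers")
    estimate = total_num / total_den

    n_blocks = math.ceil(n / block_size)
    if n_blocks < 2:
        raise UndefinedResult(
            f"need at least 2 jackknife blocks, got {n_blocks} "
            f"({n} markers at block size {block_size})"
        )
    edges = np.arange(1, n_blocks + 1) * block_size
    edges[-1] = n
    block_num = np.add.reduceat(num, np.r_[0, edges[:-1]])
    block_den = np.add.reduceat(den, np.r_[0, edges[:-1]])
    loo_den = total_den - block_den
    if np.any(loo_den == 0):
        raise UndefinedResult("a leave-one-out block has zero denominator")
    loo = (total_num - block_num) / loo_den
    se = math.sqrt((n_blocks - 1) / n_blocks * np.sum((loo - loo.mean()) ** 2))
    return float(estimate), float(se), int(n_blocks), loo


def yates_chi2(a: float, b: float, c: float, d: float) -> Tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on [[a, b], [c, d]].

    chi2 = N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)); the correction
    term is floored at zero so chi2 >= 0.  Returns (chi2, p) with 1 df;
    p is NaN when a margin is zero.
    """
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return float("nan"), float("nan")
    adj = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = n * adj**2 / margins
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def chi2_2x2(a: float, b: float, c: float, d: float) -> Tuple[float, float]:
    """Plain (uncorrected) Pearson chi-square on [[a, b], [c, d]], 1 df."""
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return float("nan"), float("nan")
    chi2 = n * (a * d - b * c) ** 2 / margins
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def chi2_homogeneity(
    row1: np.ndarray, row2: np.ndarray, min_expected: float = 5.0
) -> float:
    """Chi-square homogeneity p for a 2 x K table, pooling sparse columns.

    Consecutive columns are pooled until every expected count in a pooled
    column reaches ``min_expected``; a trailing remainder is merged into
    the previous pooled column.  Returns NaN when fewer than two pooled
    columns remain or a row total is zero.
    """
    row1 = np.asarray(row1, dtype=float)
    row2 = np.asarray(row2, dtype=float)
    t1, t2 = row1.sum(), row2.sum()
    total = t1 + t2
    if total == 0 or t1 == 0 or t2 == 0:
        return float("nan")
    pooled1, pooled2 = [], []
    acc1 = acc2 = 0.0
    for x1, x2 in zip(row1, row2):
        acc1 += x1
        acc2 += x2
        col = acc1 + acc2
        if col * t1 / total >= min_expected and col * t2 / total >= min_expected:
            pooled1.append(acc1)
            pooled2.append(acc2)
            acc1 = acc2 = 0.0
    if acc1 or acc2:
        if pooled1:
            pooled1[-1] += acc1
            pooled2[-1] += acc2
        else:
            return float("nan")
    if len(pooled1) < 2:
        return float("nan")
    _, p, _, _ = sps.chi2_contingency(np.array([pooled1, pooled2]))
    return float(p)
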