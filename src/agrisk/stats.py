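"""Nonparametric two-sample tests, rank correlation, and FDR adjustment.

Thin, contract-checked wrappers around scipy with the conventions used
throughout the comparison pipeline: exact small-sample null distributions
where feasible, tie-corrected normal approximations otherwise, and
Benjamini–Hochberg step-up adjustment within a declared test family.
"""

from __future__ import annotations

import math
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "mann_whitney_u",
    "ks_two_sample",
    "spearman",
    "chi_square_frequencies",
    "normality_check",
    "fdr_adjust",
]

_TAILS = {"two": "two-sided", "one_greater": "greater", "one_less": "less"}

#: Below this smaller-sample size the exact U null distribution is used
#: (when the pooled data are tie-free); otherwise the tie-corrected normal
#: approximation.
EXACT_N_MAX = 8


def _check_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sample")
    return arr


def mann_whitney_u(
    sample_a, sample_b, tail: str = "two"
) -> tuple[float, float]:
    """Mann–Whitney U test; returns (U of sample_a, p).

    ``tail``: ``"two"``, ``"one_greater"`` (alternative: a stochastically
    larger), or ``"one_less"``.  Exact enumeration of the U null for
    min(n) <= 8 without ties; tie-corrected normal approximation with
    continuity correction otherwise.
    """
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {sorted(_TAILS)}, got {tail!r}")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        # Degenerate: every pooled value tied; no evidence either way.
        return a.size * b.size / 2.0, 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_N_MAX and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=_TAILS[tail], method=method)
    return float(res.statistic), float(res.pvalue)


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test: maximum ECDF gap D with the
    asymptotic p-value."""
    a = _check_sample(sample_a, "sample_a")
    b = _check_sample(sample_b, "sample_b")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties).

    p-value by exhaustive permutation of the pairing for n <= exact_max_n
    (two-sided on |r|), and by the t approximation otherwise.
    """
    xa = _check_sample(x, "x")
    ya = _check_sample(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    r_obs = _spearman_r(xa, ya)
    if math.isnan(r_obs):
        return r_obs, float("nan")
    if n <= exact_max_n:
        ry = sps.rankdata(ya)
        hits = 0
        total = 0
        for perm in permutations(range(n)):
            r = _spearman_r(xa, ry[list(perm)])
            total += 1
            if abs(r) >= abs(r_obs) - 1e-12:
                hits += 1
        return r_obs, hits / total
    res = sps.spearmanr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def chi_square_frequencies(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2-way count table
    (no continuity correction), with (r-1)(c-1) degrees of freedom."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be a 2-way count table (>= 2x2)")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero marginal (expected count of 0)")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def normality_check(sample, min_n: int = 20) -> tuple[float, float]:
    """D'Agostino–Pearson omnibus (skew + kurtosis) normality test.

    Used to justify rank-based comparisons in reports; requires n >= 20
    for the component statistics to be trustworthy.
    """
    x = _check_sample(sample, "sample")
    if x.size < min_n:
        raise ValueError(f"normality check requires n >= {min_n}, got {x.size}")
    res = sps.normaltest(x)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, scale by m/rank, enforce monotonicity from the largest
    down, cap at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return np.asarray(sps.false_discovery_control(p, method="bh"))
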