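"""Rank statistics: Wilcoxon–Mann–Whitney, Spearman correlation, median/range.

The Mann–Whitney implementation exposes two p-value routes: a continuity-
corrected normal approximation (the default, matching common spreadsheet
practice for small clinical samples) and exact enumeration of all
``C(n1+n2, n1)`` group labelings for small n.  A paired signed-rank
alternative is available via :func:`wilcoxon_signed_rank`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "spearman",
    "median_range",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test: statistic, two-sided p and method used."""

    statistic: float  # U for the rank-sum test, rho for correlation
    p_value: float
    method: str  # normal_cc | exact_enumeration | t_approx
    n1: int
    n2: int | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n1": self.n1,
            "n2": self.n2,
        }


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x from midrank rank sums over the pooled data."""
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks for ties
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], method: str = "normal_cc"
) -> TestResult:
    """Two-sided Wilcoxon–Mann–Whitney test for two independent samples.

    ``method="normal_cc"`` uses the normal approximation with continuity
    correction ``z = (|U - n1*n2/2| - 0.5) / sigma_U`` with the standard tie
    correction in ``sigma_U``.  ``method="exact_enumeration"`` enumerates all
    labelings (requires ``n1 + n2 <= 20``) and counts labelings whose U
    deviates from the null mean at least as much as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if method == "normal_cc":
        pooled = np.concatenate([x, y])
        n = n1 + n2
        tie = _tie_term(pooled)
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if sigma2 <= 0:  # all observations tied
            return TestResult(u, 1.0, method, n1, n2)
        z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(sigma2)
        p = 2.0 * sps.norm.sf(z)
        return TestResult(u, min(p, 1.0), method, n1, n2)

    if method == "exact_enumeration":
        n = n1 + n2
        if n > 20:
            raise ValueError(f"exact enumeration requires n1 + n2 <= 20, got {n}")
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        obs_dev = abs(u - mu)
        offset = n1 * (n1 + 1) / 2.0
        hits = total = 0
        for idx in combinations(range(n), n1):
            u_perm = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                hits += 1
        return TestResult(u, hits / total, method, n1, n2)

    raise ValueError(f"unknown method {method!r}")


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired two-sided signed-rank alternative (not the default route)."""
    res = sps.wilcoxon(np.asarray(x, float), np.asarray(y, float))
    return TestResult(float(res.statistic), float(res.pvalue), "signed_rank", len(x), len(y))


def spearman(pairs: Sequence[tuple[float, float]]) -> TestResult:
    """Spearman rank correlation with a t-approximation p-value.

    rho is computed on midranks (equivalent to ``1 - 6*sum(d^2)/(n(n^2-1))``
    when there are no ties); p is two-sided from
    ``t = rho * sqrt((n-2)/(1-rho^2))`` with ``n - 2`` degrees of freedom.
    """
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    n = a.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise ValueError("constant input: zero rank variance")
    rho = float(np.corrcoef(ra, rb)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return TestResult(rho, p, "t_approx", n)


def median_range(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, min, max) with the midpoint convention for even n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return float(np.median(v)), float(v.min()), float(v.max())
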