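"""Statistical primitives shared by the pipeline stages.

Small wrappers around scipy with the exact-vs-approximate switchovers,
sidedness conventions and degenerate-input behaviour pinned down, since
conventions differ between implementations:

* Fisher's exact test: two-sided by summing hypergeometric probabilities of
  tables as or less probable than the observed one.
* Mann-Whitney U: exact null enumeration when ``min(n, m) <= EXACT_MW_MAX``
  and there are no ties; tie-corrected normal approximation with continuity
  correction otherwise.
* Variance comparison: two-sided variance-ratio (F) test.
* Poisson / binomial upper tails P(X >= k) for the enrichment test.

Every result carries its method label and sidedness into the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import ZeroVarianceError

__all__ = [
    "TestResult",
    "EXACT_MW_MAX",
    "pearson_r",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "variance_ratio_test",
    "count_tail",
]

#: Largest min(n, m) for which Mann-Whitney uses exact enumeration.
EXACT_MW_MAX = 8


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    sidedness: str  # "one" or "two"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def pearson_r(x, y) -> float:
    """Product-moment correlation; raises ZeroVarianceError when undefined.

    Callers decide how to map the degenerate case (linearity maps it to 0
    and flags the assay; reproducibility reports "na").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("pearson_r requires finite values")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0.0:
        raise ZeroVarianceError("zero variance in at least one vector")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        return TestResult(np.nan, 1.0, "fisher_exact", "two")
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(float(odds), min(float(p), 1.0), "fisher_exact", "two")


def _all_distinct(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) == len(pooled)


def mann_whitney_u(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney_u needs non-empty samples")
    exact = min(len(x), len(y)) <= EXACT_MW_MAX and _all_distinct(x, y)
    if len(x) == len(y) and np.array_equal(np.sort(x), np.sort(y)):
        # identical multisets carry no evidence against equal locations
        return TestResult(len(x) * len(y) / 2.0, 1.0, "mann_whitney_degenerate", "two")
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return TestResult(len(x) * len(y) / 2.0, 1.0, "mann_whitney_degenerate", "two")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    method = "mann_whitney_exact" if exact else "mann_whitney_normal_approx"
    return TestResult(float(res.statistic), min(float(res.pvalue), 1.0), method, "two")


def variance_ratio_test(x, y) -> TestResult:
    """Two-sided F test of equal variances, F = s2_x / s2_y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("variance_ratio_test needs n >= 2 per sample")
    s2x = x.var(ddof=1)
    s2y = y.var(ddof=1)
    if s2y == 0.0:
        raise ZeroVarianceError("zero variance in denominator sample")
    f = s2x / s2y
    dist = sps.f(len(x) - 1, len(y) - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return TestResult(float(f), min(max(float(p), np.nextafter(0, 1)), 1.0),
                      "variance_ratio_f", "two")


def count_tail(k: int, mode: str = "poisson", *, lam: float | None = None,
               n: int | None = None, p: float | None = None) -> float:
    """Upper-tail probability P(X >= k) of a count under the null.

    mode="poisson" uses X ~ Poisson(lam); mode="binomial" uses
    X ~ Binomial(n, p).  ``k = 0`` always yields 1.0.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if mode == "poisson":
        if lam is None or lam < 0:
            raise ValueError("poisson mode needs lam >= 0")
        return float(sps.poisson.sf(k - 1, lam))
    if mode == "binomial":
        if n is None or p is None or not (0.0 <= p <= 1.0) or n < 0:
            raise ValueError("binomial mode needs n >= 0 and p in [0, 1]")
        return float(sps.binom.sf(k - 1, n, p))
    raise ValueError(f"unknown mode {mode!r}")
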