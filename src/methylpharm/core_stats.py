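"""Correlation statistics and false-discovery-rate adjustment.

Every association in the pipeline is a rank (Spearman) or product-moment
(Pearson) correlation whose two-sided p-value comes from the t approximation

    t = rho * sqrt((n - 2) / (1 - rho**2)),   df = n - 2.

This single convention is used for probe-level, region-level, expression and
copy-number correlations alike, so that a reported (rho, n) pair always
reproduces its own p-value.  Missing data are handled by pairwise-complete
deletion and the number of complete pairs is recorded on every result.

Degenerate inputs (fewer than 3 complete pairs, or a constant rank vector)
yield ``None`` — an *undefined result* that callers must log and exclude from
FDR families rather than silently convert to a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "AdjustedPValues",
    "SMALLEST_P",
    "MIN_COMPLETE_PAIRS",
    "spearman",
    "pearson",
    "spearman_p_from_rho",
    "critical_rho",
    "bh_adjust",
]

#: Smallest representable positive double; p-values are floored here so that
#: a perfect correlation never produces p == 0 and -log10(p) stays finite.
SMALLEST_P: float = math.ulp(0.0)

#: Hard floor on complete pairs for a defined correlation coefficient.
MIN_COMPLETE_PAIRS: int = 3


@dataclass(frozen=True)
class CorrelationResult:
    """One correlation test: coefficient, two-sided p, and pairs used.

    ``coefficient`` houses Spearman's rho or Pearson's r depending on
    ``method``; ``p_value`` is the two-sided p from the t approximation.
    ``low_n`` flags results computed on fewer than 80% of the nominal
    sample set (set by callers that know the sample universe).
    """

    coefficient: float
    p_value: float
    n_used: int
    method: str
    low_n: bool = False

    def __post_init__(self) -> None:
        if not (abs(self.coefficient) <= 1 + 1e-12):
            raise ValueError(f"|coefficient| > 1: {self.coefficient}")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value outside (0, 1]: {self.p_value}")
        if self.n_used < MIN_COMPLETE_PAIRS:
            raise ValueError(f"n_used < {MIN_COMPLETE_PAIRS}: {self.n_used}")


@dataclass(frozen=True)
class AdjustedPValues:
    """Benjamini-Hochberg step-up adjusted p-values for one test family."""

    raw: np.ndarray
    adjusted: np.ndarray
    family_size: int


def _two_sided_p(rho: float, n: int) -> float:
    """Two-sided p for a correlation of magnitude |rho| at n complete pairs."""
    r = abs(float(rho))
    if r >= 1.0:
        return SMALLEST_P
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(t, n - 2)
    return max(min(float(p), 1.0), SMALLEST_P)


def _snap(r: float, tol: float = 1e-12) -> float:
    """Clamp to [-1, 1] and snap floating-point 1-epsilon to exactly +/-1."""
    if r >= 1.0 - tol:
        return 1.0
    if r <= -1.0 + tol:
        return -1.0
    return r


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y) -> CorrelationResult | None:
    """Spearman rank correlation with pairwise-complete deletion.

    Ties receive average ranks; the coefficient is the Pearson correlation
    of the two rank vectors.  Returns ``None`` (undefined result) when fewer
    than :data:`MIN_COMPLETE_PAIRS` complete pairs remain or either rank
    vector is constant.
    """
    xc, yc = _complete_pairs(x, y)
    n = xc.size
    if n < MIN_COMPLETE_PAIRS:
        return None
    rx = stats.rankdata(xc, method="average")
    ry = stats.rankdata(yc, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return None
    rho = _snap(float(np.corrcoef(rx, ry)[0, 1]))
    return CorrelationResult(rho, _two_sided_p(rho, n), n, "spearman")


def pearson(x, y) -> CorrelationResult | None:
    """Pearson product-moment correlation with pairwise-complete deletion.

    Returns ``None`` for fewer than 3 complete pairs or a constant vector.
    """
    xc, yc = _complete_pairs(x, y)
    n = xc.size
    if n < MIN_COMPLETE_PAIRS:
        return None
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        return None
    r = _snap(float(np.corrcoef(xc, yc)[0, 1]))
    return CorrelationResult(r, _two_sided_p(r, n), n, "pearson")


def spearman_p_from_rho(rho: float, n: int) -> float:
    """Two-sided p-value of a Spearman rho at n samples (t approximation).

    This is the convention under which reported (rho, n, p) triples are
    self-consistent.  |rho| >= 1 returns :data:`SMALLEST_P` rather than 0.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    return _two_sided_p(rho, n)


def critical_rho(n: int, alpha: float, tol: float = 1e-6) -> float:
    """Smallest |rho| whose two-sided p-value is below ``alpha`` at size n.

    Found by bisection on the strictly decreasing map rho -> p(rho, n).
    ``alpha >= 1`` returns 0 (any nonzero rho has p < 1).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if alpha >= 1.0:
        return 0.0
    lo, hi = 0.0, 1.0 - 1e-15
    if _two_sided_p(hi, n) >= alpha:  # alpha below the p-floor
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _two_sided_p(mid, n) < alpha:
            hi = mid
        else:
            lo = mid
    return hi


def bh_adjust(p) -> AdjustedPValues:
    """Benjamini-Hochberg step-up FDR adjustment over one test family.

    Input p-values must lie in (0, 1]; undefined-result placeholders must be
    removed by the caller before adjustment so they never inflate the family.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return AdjustedPValues(p.copy(), p.copy(), 0)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1] with no missing entries")
    adjusted = multipletests(p, method="fdr_bh")[1]
    adjusted = np.minimum(np.maximum(adjusted, p), 1.0)
    return AdjustedPValues(p.copy(), adjusted, int(p.size))
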