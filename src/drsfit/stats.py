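"""Statistical toolbox used by the breach-detection study.

Non-normal, min/max-bounded physiological parameters call for the
nonparametric workflow implemented here: Jarque-Bera normality screening,
Wilcoxon rank-sum comparisons (exact enumeration for small samples,
tie-corrected normal approximation otherwise), OLS R^2 for trend reporting,
and the min/max range of per-measurement confidence-interval half-widths as
a signal-quality summary.  Significance level defaults to alpha = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .fit import FitResult

__all__ = [
    "TestResult",
    "jarque_bera",
    "wilcoxon_rank_sum",
    "linear_r2",
    "ci_range_summary",
    "DEFAULT_ALPHA",
]

DEFAULT_ALPHA = 0.01

#: largest pooled sample size for which the rank-sum test enumerates exactly
EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_x: int
    n_y: int | None
    alpha: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must be in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def jarque_bera(sample: Sequence[float], alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Moment-based normality test: JB = n/6 (S^2 + K^2/4) ~ chi^2(2).

    S is the (biased, moment-estimator) sample skewness and K the excess
    kurtosis, as in the classical definition.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError("Jarque-Bera requires n >= 8")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        raise ValueError("constant sample: moments undefined")
    s = np.mean((x - m) ** 3) / m2**1.5
    k = np.mean((x - m) ** 4) / m2**2 - 3.0
    jb = x.size / 6.0 * (s**2 + k**2 / 4.0)
    p = float(sps.chi2.sf(jb, df=2))
    return TestResult(float(jb), p, int(x.size), None, alpha, "jarque_bera")


def _ranksum_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Midranks handle ties; the p-value is the null fraction of assignments
    whose rank sum deviates from its mean at least as much as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, nx = pooled.size, x.size
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), nx):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            count += 1
    return float(w_obs), count / total


def _ranksum_normal(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, nx, ny = pooled.size, x.size, y.size
    w = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(w), 1.0
    diff = w - mu
    # continuity correction shrinks the deviation toward zero by 1/2
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return float(w), p


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alpha: float = DEFAULT_ALPHA
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two groups.

    Exact enumeration over all C(n, n_x) rank assignments when the pooled
    size is <= 12, tie-corrected continuity-corrected normal approximation
    otherwise.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both groups must be non-empty")
    if xa.size < 3 or ya.size < 3:
        raise ValueError("both groups need n >= 3")
    if xa.size + ya.size <= EXACT_ENUMERATION_MAX_N:
        w, p = _ranksum_exact(xa, ya)
        method = "ranksum_exact"
    else:
        w, p = _ranksum_normal(xa, ya)
        method = "ranksum_normal"
    return TestResult(w, p, int(xa.size), int(ya.size), alpha, method)


def linear_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination of the OLS line y ~ x (squared Pearson r)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need n >= 3")
    if np.var(xa) == 0:
        raise ValueError("zero variance in x")
    r = sps.pearsonr(xa, ya).statistic
    return float(r * r)


def ci_range_summary(fits: Sequence[FitResult], parameter: str = "fat_fraction_pct") -> tuple[float, float]:
    """(min, max) of the 95% CI half-widths of one parameter across fits.

    The range is the study's signal-quality summary: narrow half-widths mean
    the parameter is reliably determined from each individual spectrum.
    All fits must have converged.
    """
    if not fits:
        raise ValueError("need at least one fit")
    if any(not f.converged for f in fits):
        raise ValueError("ci_range_summary requires converged fits")
    widths = [float(f.ci95[parameter]) for f in fits]
    return (min(widths), max(widths))
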