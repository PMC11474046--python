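"""Statistical primitives: rank tests, ECDF distance, Spearman, bootstrap CI.

Thin, explicitly parameterised wrappers around the scipy.stats machinery so
that every choice (exact vs asymptotic null, tie handling, CI type) is
fixed and documented rather than left to library defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "bootstrap_ci_mean",
    "ks_two_sample",
    "mann_whitney_u",
    "spearman",
]

#: largest pooled sample size for which the exact Mann-Whitney null is enumerated
EXACT_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str          # "exact" | "asymptotic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _validate(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return x, y


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The exact null distribution is enumerated when the pooled sample has at
    most 12 observations and no ties; otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    x, y = _validate(x, y)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    exact = no_ties and (len(x) + len(y)) <= EXACT_LIMIT
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=len(x),
        n2=len(y),
        method="exact" if exact else "asymptotic",
    )


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_x - ECDF_y|, asymptotic p."""
    x, y = _validate(x, y)
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=len(x),
        n2=len(y),
        method="asymptotic",
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant sample")
    return float(sps.spearmanr(x, y).statistic)


def bootstrap_ci_mean(
    sample: Sequence[float],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean: returns ``(mean, lo, hi)``.

    Resamples the observations with replacement ``n_boot`` times and takes
    the (alpha/2, 1 - alpha/2) percentiles of the resampled means;
    deterministic under ``seed``.
    """
    a = np.asarray(sample, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    means = a[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(a.mean()), float(lo), float(hi)
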