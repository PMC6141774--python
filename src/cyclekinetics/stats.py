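"""Uncertainty and group-comparison machinery.

Matches the study's reporting conventions: point estimates with 95%
intervals (replicate-level percentile bootstrap over embryos, or Wilson
for single-replicate proportions) and Mann-Whitney tests for two-group
comparisons (exact for small n, asymptotic otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError
from .types import EstimateWithCI

__all__ = [
    "BootstrapSpec",
    "bootstrap_samples",
    "bootstrap_ci",
    "MannWhitneyReport",
    "compare_two_groups",
    "wilson_interval",
]


@dataclass(frozen=True)
class BootstrapSpec:
    """Nonparametric bootstrap settings.

    The default resampling unit is the replicate (embryo), matching the
    study's n = embryos; ``unit="cell"`` is available for single-replicate
    designs where only cell-level resampling is possible.
    """

    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    unit: str = "replicate"

    def __post_init__(self):
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.unit not in ("replicate", "cell"):
            raise ValueError("unit must be 'replicate' or 'cell'")


def resample_indices(n: int, spec: BootstrapSpec) -> np.ndarray:
    """The bootstrap index stream: shape ``(n_boot, n)``.

    Defined as ``default_rng(seed).integers(0, n, size=(n_boot, n))`` so an
    independent implementation with the same seed reproduces it exactly.
    """
    rng = np.random.default_rng(spec.seed)
    return rng.integers(0, n, size=(spec.n_boot, n))


def bootstrap_samples(
    rows: Sequence,
    statistic: Callable[[Sequence], float],
    spec: BootstrapSpec,
) -> np.ndarray:
    """Statistic evaluated on ``n_boot`` resamples of the rows."""
    rows = list(rows)
    n = len(rows)
    if n < 3:
        raise InsufficientDataError(
            f"bootstrap requires >= 3 resampling units, got {n}"
        )
    idx = resample_indices(n, spec)
    return np.array(
        [statistic([rows[i] for i in draw]) for draw in idx], dtype=float
    )


def percentile_interval(samples: np.ndarray, ci_level: float) -> tuple[float, float]:
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(samples, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def bootstrap_ci(
    rows: Sequence,
    statistic: Callable[[Sequence], float],
    spec: BootstrapSpec,
    units: str = "",
) -> EstimateWithCI:
    """Replicate-level percentile bootstrap interval for ``statistic``.

    The point estimate is the statistic on the full data; the interval is
    the percentile interval over ``spec.n_boot`` resamples (deterministic
    for a fixed ``spec.seed``).
    """
    rows = list(rows)
    value = float(statistic(rows))
    samples = bootstrap_samples(rows, statistic, spec)
    lo, hi = percentile_interval(samples, spec.ci_level)
    # percentile intervals can, on degenerate resamples, narrowly miss the
    # full-data point estimate; widen so the invariant lo <= value <= hi holds
    lo, hi = min(lo, value), max(hi, value)
    return EstimateWithCI(
        value, lo, hi, ci_level=spec.ci_level,
        method=f"bootstrap-percentile(B={spec.n_boot})",
        n_replicates=len(rows), units=units,
    )


def wilson_interval(count: int, nobs: int, ci_level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (delegated)."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(count, nobs, alpha=1 - ci_level, method="wilson")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


@dataclass(frozen=True)
class MannWhitneyReport:
    """Two-sided Mann-Whitney U comparison of two replicate groups."""

    u_statistic: float
    p_value: float
    significant: bool
    method: str
    n_a: int
    n_b: int
    alpha: float = 0.05
    warning: str | None = None

    def as_dict(self) -> dict:
        return {
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "method": self.method,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "alpha": self.alpha,
            "warning": self.warning,
        }


def compare_two_groups(a: Sequence[float], b: Sequence[float],
                       alpha: float = 0.05) -> MannWhitneyReport:
    """Two-sided Mann-Whitney U test (exact for n <= 8 per group).

    Delegated to :func:`scipy.stats.mannwhitneyu`; the exact null
    distribution is used when both groups have at most 8 observations and
    the data are tie-free, the normal approximation (with tie correction)
    otherwise.  Degenerate all-tied data report p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("each group needs >= 3 replicates")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        msg = "all observations identical; Mann-Whitney is undefined, reporting p = 1"
        warnings.warn(msg)
        return MannWhitneyReport(
            u_statistic=len(a) * len(b) / 2.0, p_value=1.0, significant=False,
            method="degenerate-ties", n_a=len(a), n_b=len(b), alpha=alpha,
            warning=msg,
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return MannWhitneyReport(
        u_statistic=float(res.statistic), p_value=p,
        significant=p < alpha, method=method,
        n_a=len(a), n_b=len(b), alpha=alpha,
    )
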