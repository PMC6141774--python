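"""Ten-bin laminar distribution analysis of marker-positive neurons.

Cortical depth is normalised to [0, 1] with 0 at the pial (superficial)
surface and 1 at the ventricular (deep) surface; the wall is divided into
ten equal bins, bin 1 most superficial, bin 10 deepest.  A cell at depth
``d`` falls in bin ``floor(10 d) + 1``, with ``d = 1.0`` assigned to
bin 10.  Group comparison follows the study's convention: two-way ANOVA
(group x bin) with Sidak-adjusted per-bin comparisons at alpha = 0.05,
delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

__all__ = [
    "N_BINS",
    "LaminarSample",
    "BinDistribution",
    "assign_bins",
    "bin_indices",
    "compare_distributions",
    "LaminarComparison",
    "read_depth_csv",
    "write_bin_csv",
]

N_BINS = 10


@dataclass(frozen=True)
class LaminarSample:
    """Normalised depths of marker-positive cells in one replicate section."""

    normalized_depths: tuple[float, ...]
    marker: str = ""
    replicate_id: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "normalized_depths",
            tuple(float(d) for d in self.normalized_depths),
        )
        for d in self.normalized_depths:
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"depth {d} outside [0, 1]")


@dataclass(frozen=True)
class BinDistribution:
    """Proportions across the ten laminar bins (bin 1 superficial)."""

    proportions: tuple[float, ...]
    n_cells: int

    def __post_init__(self):
        props = tuple(float(p) for p in self.proportions)
        object.__setattr__(self, "proportions", props)
        if len(props) != N_BINS:
            raise ValueError(f"expected {N_BINS} proportions, got {len(props)}")
        if any(not 0.0 <= p <= 1.0 for p in props):
            raise ValueError("proportions must lie in [0, 1]")
        if self.n_cells > 0 and abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions)


def bin_indices(depths: Sequence[float]) -> np.ndarray:
    """1-based bin index per depth: floor(10 d) + 1, with 1.0 -> bin 10."""
    d = np.asarray(depths, dtype=float)
    if d.size and (d.min() < 0 or d.max() > 1):
        raise ValueError("depths must lie in [0, 1]")
    return np.minimum(np.floor(d * N_BINS).astype(int), N_BINS - 1) + 1


def assign_bins(sample: LaminarSample) -> BinDistribution:
    """Per-bin proportions of a replicate's marker-positive cells."""
    n = len(sample.normalized_depths)
    if n == 0:
        return BinDistribution((0.0,) * N_BINS, 0)
    idx = bin_indices(sample.normalized_depths)
    counts = np.bincount(idx - 1, minlength=N_BINS)
    return BinDistribution(tuple(counts / n), n)


@dataclass
class LaminarComparison:
    """Per-bin comparison of two replicate groups."""

    table: pd.DataFrame  # per-bin means, CI half-widths, adjusted p-values
    flagged_bins: list[int]
    anova: pd.DataFrame
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "flagged_bins": self.flagged_bins,
            "bins": self.table.reset_index().to_dict("records"),
        }


def compare_distributions(
    group_a: Sequence[BinDistribution],
    group_b: Sequence[BinDistribution],
    alpha: float = 0.05,
) -> LaminarComparison:
    """Two-way ANOVA (group x bin) with Sidak-adjusted per-bin comparisons.

    Requires >= 3 replicates per group.  Per-bin group means are compared
    with t statistics using the ANOVA's pooled residual mean square
    (Prism-style multiple-comparisons after two-way ANOVA); raw p-values
    are Sidak-adjusted for the ten bins and flagged below ``alpha``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    na, nb = len(group_a), len(group_b)
    if na < 3 or nb < 3:
        raise InsufficientDataError("need >= 3 replicates per group")
    a = np.vstack([g.as_array() for g in group_a])
    b = np.vstack([g.as_array() for g in group_b])

    long = pd.DataFrame({
        "proportion": np.concatenate([a.ravel(), b.ravel()]),
        "bin": np.concatenate([
            np.tile(np.arange(1, N_BINS + 1), na),
            np.tile(np.arange(1, N_BINS + 1), nb),
        ]),
        "group": ["A"] * (na * N_BINS) + ["B"] * (nb * N_BINS),
    })
    fit = smf.ols("proportion ~ C(group) * C(bin)", data=long).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    mse = float(fit.mse_resid)
    dof = int(fit.df_resid)

    from scipy import stats as sps

    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    diff = mean_b - mean_a
    se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
    if se > 0:
        tvals = diff / se
        p_raw = 2.0 * sps.t.sf(np.abs(tvals), dof)
    else:
        tvals = np.zeros(N_BINS)
        p_raw = np.where(diff == 0, 1.0, 0.0)
    p_sidak = 1.0 - (1.0 - p_raw) ** N_BINS
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, dof) if dof > 0 else np.nan
    ci_half = tcrit * np.sqrt(mse) / np.sqrt([na] * N_BINS)

    table = pd.DataFrame({
        "mean_a": mean_a,
        "mean_b": mean_b,
        "diff": diff,
        "ci95_half_width": ci_half,
        "t": tvals,
        "p_raw": p_raw,
        "p_sidak": np.clip(p_sidak, 0.0, 1.0),
    }, index=pd.Index(range(1, N_BINS + 1), name="bin"))
    table["significant"] = table["p_sidak"] < alpha
    flagged = [int(i) for i in table.index[table["significant"]]]
    return LaminarComparison(table, flagged, anova, alpha)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_depth_csv(path) -> list[LaminarSample]:
    """Read per-cell depths: columns replicate, marker, normalized_depth."""
    df = pd.read_csv(path, comment="#")
    required = {"replicate", "marker", "normalized_depth"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out = []
    for (rep, marker), grp in df.groupby(["replicate", "marker"], sort=True):
        out.append(LaminarSample(
            tuple(grp["normalized_depth"]), marker=str(marker),
            replicate_id=str(rep),
        ))
    return out


def write_bin_csv(path, samples_and_bins: Sequence[tuple[LaminarSample, BinDistribution]]) -> None:
    rows = []
    for sample, dist in samples_and_bins:
        row = {"replicate": sample.replicate_id, "marker": sample.marker,
               "n_cells": dist.n_cells}
        row.update({f"bin_{i + 1}": p for i, p in enumerate(dist.proportions)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
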