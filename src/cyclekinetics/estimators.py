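"""Cell-cycle phase-length estimators from immunolabelling counts.

The arithmetic of the dual thymidine-analogue paradigm:

* ``T_S  = T_i * S / L``  — S-cells (BrdU+) over leaving cells (IdU+BrdU-),
  scaled by the inter-injection interval T_i;
* ``T_C  = T_S * P / S``  — the cycling pool (PCNA+) over the S cohort;
* ``T_G2``                — time after a BrdU pulse at which 50% of pHH3+
  mitotic figures are BrdU+, by piecewise-linear interpolation;
* ``T_M  = T_C * pHH3+/PCNA+`` — mitotic index times cycle length;
* ``T_G1 = T_C - T_S - T_G2 - T_M``;
* ``Q    = BrdU+PCNA- / BrdU+`` after a 24 h chase — the quit fraction.

Each estimator accepts a single replicate or a sequence of replicates;
with >= 3 replicates the CI is a replicate-level percentile bootstrap,
single-replicate proportions get Wilson intervals, anything else reports
a degenerate interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    InconsistentEstimatesError,
    NoCrossingError,
    UndefinedEstimateError,
)
from .stats import BootstrapSpec, bootstrap_samples, percentile_interval, wilson_interval
from .types import CountTable, EstimateWithCI

__all__ = [
    "DualPulseCounts",
    "TimeCoursePoint",
    "QuitCounts",
    "estimate_ts",
    "estimate_tc",
    "estimate_tg2",
    "estimate_tm",
    "estimate_tg1",
    "quit_fraction",
    "double_label_proportion",
    "dual_pulse_rows_from_table",
    "timecourse_series_from_table",
    "quit_rows_from_table",
]

logger = logging.getLogger(__name__)

HOURS = "hours"


# ---------------------------------------------------------------------------
# Input records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DualPulseCounts:
    """One replicate of the IdU/BrdU dual-pulse experiment.

    ``n_idu_only`` are the leaving cells (IdU+BrdU-, "L-cells"),
    ``n_s_cells`` the S cohort (BrdU+, "S-cells"), ``n_cycling`` the PCNA+
    pool, and ``t_i`` the inter-injection interval in hours.
    """

    n_idu_only: int
    n_s_cells: int
    n_cycling: int
    t_i: float

    def __post_init__(self):
        if min(self.n_idu_only, self.n_s_cells, self.n_cycling) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_s_cells > self.n_cycling:
            raise ValueError("S-cells cannot exceed the cycling pool")
        if self.t_i <= 0:
            raise ValueError("t_i must be > 0")


@dataclass(frozen=True)
class TimeCoursePoint:
    """One time point of the BrdU -> pHH3 time course."""

    t: float  # hours since the BrdU injection
    n_phh3: int
    n_phh3_brdu: int

    def __post_init__(self):
        if self.n_phh3 <= 0:
            raise ValueError("n_phh3 must be > 0")
        if not 0 <= self.n_phh3_brdu <= self.n_phh3:
            raise ValueError("n_phh3_brdu must lie in [0, n_phh3]")

    @property
    def proportion(self) -> float:
        return self.n_phh3_brdu / self.n_phh3


@dataclass(frozen=True)
class QuitCounts:
    """One replicate of the 24 h pulse-chase cell-cycle-exit experiment."""

    n_brdu: int
    n_brdu_pcna_neg: int

    def __post_init__(self):
        if self.n_brdu <= 0:
            raise ValueError("n_brdu must be > 0")
        if not 0 <= self.n_brdu_pcna_neg <= self.n_brdu:
            raise ValueError("n_brdu_pcna_neg must lie in [0, n_brdu]")


def _as_rows(data, cls) -> list:
    if isinstance(data, cls):
        return [data]
    rows = list(data)
    if not rows:
        raise ValueError("no replicate rows supplied")
    if not all(isinstance(r, cls) for r in rows):
        raise TypeError(f"expected {cls.__name__} rows")
    return rows


def _estimate(rows, point_fn, bootstrap: BootstrapSpec | None,
              units: str = HOURS) -> EstimateWithCI:
    """Point estimate on pooled rows; replicate bootstrap CI when possible."""
    value = float(point_fn(rows))
    if bootstrap is not None and len(rows) >= 3:
        samples = bootstrap_samples(rows, point_fn, bootstrap)
        samples = samples[np.isfinite(samples)]
        lo, hi = percentile_interval(samples, bootstrap.ci_level)
        lo, hi = min(lo, value), max(hi, value)
        return EstimateWithCI(
            value, lo, hi, ci_level=bootstrap.ci_level,
            method=f"bootstrap-percentile(B={bootstrap.n_boot})",
            n_replicates=len(rows), units=units,
        )
    return EstimateWithCI.degenerate(
        value, method="formula", units=units, n_replicates=len(rows)
    )


# ---------------------------------------------------------------------------
# T_S and T_C (dual pulse)
# ---------------------------------------------------------------------------

def _pool_dual(rows: Sequence[DualPulseCounts]):
    t_i = rows[0].t_i
    if any(abs(r.t_i - t_i) > 1e-9 for r in rows):
        raise ValueError("all replicates must share the same t_i")
    L = sum(r.n_idu_only for r in rows)
    S = sum(r.n_s_cells for r in rows)
    P = sum(r.n_cycling for r in rows)
    return t_i, L, S, P


def _ts_point(rows: Sequence[DualPulseCounts]) -> float:
    t_i, L, S, _ = _pool_dual(rows)
    if L == 0:
        raise UndefinedEstimateError(
            "no IdU-only cells: T_S is unbounded below by the data"
        )
    return t_i * S / L


def estimate_ts(data, bootstrap: BootstrapSpec | None = None) -> EstimateWithCI:
    """S-phase duration T_S = T_i * S-cells / L-cells (hours)."""
    rows = _as_rows(data, DualPulseCounts)
    return _estimate(rows, _ts_point, bootstrap)


def _tc_point_factory(ts: float | None):
    def point(rows: Sequence[DualPulseCounts]) -> float:
        t_i, L, S, P = _pool_dual(rows)
        if S == 0:
            raise UndefinedEstimateError(
                "no S-cells: T_C is undefined for these counts"
            )
        ts_val = ts if ts is not None else _ts_point(rows)
        return ts_val * P / S
    return point


def estimate_tc(ts, data, bootstrap: BootstrapSpec | None = None) -> EstimateWithCI:
    """Total cycle length T_C = T_S * PCNA+ / S-cells (hours).

    ``ts=None`` re-derives T_S from the same rows inside every bootstrap
    resample, which propagates the shared sampling error of the two
    estimates; passing a number holds T_S fixed.
    """
    rows = _as_rows(data, DualPulseCounts)
    ts_val = ts.value if isinstance(ts, EstimateWithCI) else ts
    return _estimate(rows, _tc_point_factory(ts_val), bootstrap)


# ---------------------------------------------------------------------------
# T_G2 (50% crossing of the BrdU+/pHH3+ time course)
# ---------------------------------------------------------------------------

def crossing_time(ts: Sequence[float], ps: Sequence[float]) -> float:
    """Earliest time at which the piecewise-linear p(t) reaches 0.5."""
    ts = list(ts)
    ps = list(ps)
    if len(ts) < 2:
        raise ValueError("need at least two time points")
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("time points must be strictly increasing")
    if any(b < a for a, b in zip(ps, ps[1:])):
        logger.info("non-monotone BrdU+/pHH3+ sequence: %s", ps)
    if ps[0] >= 0.5:
        if ps[0] == 0.5:
            return ts[0]
        raise NoCrossingError(
            f"proportion already above 50% at the first time point; "
            f"the data only bound T_G2 < {ts[0]} h",
            bound="below", t_bound_hours=ts[0],
        )
    for (t0, p0), (t1, p1) in zip(zip(ts, ps), zip(ts[1:], ps[1:])):
        if p1 == 0.5:
            return t1
        if p0 < 0.5 < p1:
            return t0 + (t1 - t0) * (0.5 - p0) / (p1 - p0)
    raise NoCrossingError(
        f"proportion never reaches 50%; the data only bound T_G2 > {ts[-1]} h",
        bound="above", t_bound_hours=ts[-1],
    )


def _tg2_point(series: Sequence[Sequence[TimeCoursePoint]]) -> float:
    """Crossing time of the replicate-pooled time course."""
    pooled: dict[float, list[int]] = {}
    for rep in series:
        for pt in rep:
            acc = pooled.setdefault(pt.t, [0, 0])
            acc[0] += pt.n_phh3
            acc[1] += pt.n_phh3_brdu
    ts = sorted(pooled)
    ps = [pooled[t][1] / pooled[t][0] for t in ts]
    return crossing_time(ts, ps)


def estimate_tg2(points, bootstrap: BootstrapSpec | None = None) -> EstimateWithCI:
    """G2 duration: earliest 50% crossing of the BrdU+/pHH3+ proportion.

    ``points`` is a single replicate's list of :class:`TimeCoursePoint`
    (strictly increasing ``t``) or a list of such lists, one per replicate.
    """
    if points and isinstance(points[0], TimeCoursePoint):
        series = [list(points)]
    else:
        series = [list(rep) for rep in points]
    if not series or not all(series):
        raise ValueError("no time-course points supplied")
    for rep in series:
        times = [pt.t for pt in rep]
        if len(times) < 2:
            raise ValueError("each replicate needs at least two time points")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time points must be strictly increasing")
    value = _tg2_point(series)
    if bootstrap is not None and len(series) >= 3:
        def stat(reps):
            try:
                return _tg2_point(reps)
            except NoCrossingError:
                return np.nan
        samples = bootstrap_samples(series, stat, bootstrap)
        n_bad = int(np.sum(~np.isfinite(samples)))
        if n_bad:
            logger.warning("%d bootstrap resamples had no 50%% crossing", n_bad)
        samples = samples[np.isfinite(samples)]
        lo, hi = percentile_interval(samples, bootstrap.ci_level)
        lo, hi = min(lo, value), max(hi, value)
        return EstimateWithCI(
            value, lo, hi, ci_level=bootstrap.ci_level,
            method=f"bootstrap-percentile(B={bootstrap.n_boot})",
            n_replicates=len(series), units=HOURS,
        )
    return EstimateWithCI.degenerate(
        value, method="piecewise-linear-crossing", units=HOURS,
        n_replicates=len(series),
    )


# ---------------------------------------------------------------------------
# T_M, T_G1
# ---------------------------------------------------------------------------

def estimate_tm(n_phh3: int, n_cycling: int, tc: float) -> EstimateWithCI:
    """M-phase duration T_M = T_C * pHH3+ / PCNA+ (hours)."""
    if n_cycling <= 0:
        raise UndefinedEstimateError("n_cycling must be > 0")
    if not 0 <= n_phh3 <= n_cycling:
        raise ValueError("n_phh3 must lie in [0, n_cycling]")
    tc_val = tc.value if isinstance(tc, EstimateWithCI) else float(tc)
    return EstimateWithCI.degenerate(
        tc_val * n_phh3 / n_cycling, method="formula", units=HOURS
    )


def estimate_tg1(tc, ts, tg2, tm) -> EstimateWithCI:
    """G1 duration by subtraction: T_G1 = T_C - T_S - T_G2 - T_M.

    A negative result raises :class:`InconsistentEstimatesError` carrying
    the four inputs — inconsistency is diagnostic information, never
    silently clamped.
    """
    vals = [
        x.value if isinstance(x, EstimateWithCI) else float(x)
        for x in (tc, ts, tg2, tm)
    ]
    tc_v, ts_v, tg2_v, tm_v = vals
    tg1 = tc_v - ts_v - tg2_v - tm_v
    if tg1 < 0:
        raise InconsistentEstimatesError(tc_v, ts_v, tg2_v, tm_v)
    return EstimateWithCI.degenerate(tg1, method="subtraction", units=HOURS)


# ---------------------------------------------------------------------------
# Quit fraction and double-label proportions
# ---------------------------------------------------------------------------

def _quit_point(rows: Sequence[QuitCounts]) -> float:
    num = sum(r.n_brdu_pcna_neg for r in rows)
    den = sum(r.n_brdu for r in rows)
    return num / den


def quit_fraction(data, bootstrap: BootstrapSpec | None = None) -> EstimateWithCI:
    """Cell-cycle exit fraction Q = BrdU+PCNA- / BrdU+ after the chase."""
    rows = _as_rows(data, QuitCounts)
    est = _estimate(rows, _quit_point, bootstrap, units="fraction")
    if len(rows) == 1 and (bootstrap is None or len(rows) < 3):
        lo, hi = wilson_interval(rows[0].n_brdu_pcna_neg, rows[0].n_brdu)
        return EstimateWithCI(
            est.value, min(lo, est.value), max(hi, est.value),
            method="wilson", n_replicates=1, units="fraction",
        )
    return est


def double_label_proportion(
    n_double,
    n_reference,
    bootstrap: BootstrapSpec | None = None,
) -> EstimateWithCI:
    """Proportion of double-labelled cells among a reference class.

    Scalars give a single-replicate Wilson interval; paired sequences
    (one entry per replicate) give a replicate-bootstrap interval of the
    pooled proportion.
    """
    if np.isscalar(n_double):
        n_double, n_reference = int(n_double), int(n_reference)
        if n_reference <= 0:
            raise UndefinedEstimateError("n_reference must be > 0")
        if n_double > n_reference:
            raise ValueError("n_double cannot exceed n_reference")
        p = n_double / n_reference
        lo, hi = wilson_interval(n_double, n_reference)
        return EstimateWithCI(
            p, min(lo, p), max(hi, p), method="wilson",
            n_replicates=1, units="fraction",
        )
    pairs = list(zip(n_double, n_reference))
    if any(d > r for d, r in pairs):
        raise ValueError("n_double cannot exceed n_reference")
    if sum(r for _, r in pairs) <= 0:
        raise UndefinedEstimateError("n_reference must be > 0")

    def point(rows):
        num = sum(d for d, _ in rows)
        den = sum(r for _, r in rows)
        return num / den

    return _estimate(pairs, point, bootstrap, units="fraction")


# ---------------------------------------------------------------------------
# CountTable adapters
# ---------------------------------------------------------------------------

def dual_pulse_rows_from_table(
    table: CountTable, s_cell_convention: str = "at-sacrifice"
) -> list[DualPulseCounts]:
    """Extract per-replicate dual-pulse counts from a simulator table.

    ``s_cell_convention`` selects which cells count as the S cohort:
    ``"at-sacrifice"`` (default) uses all BrdU+ cells at sacrifice;
    ``"at-injection"`` uses cells in S at the BrdU injection instant
    (available only in simulated tables, via the ``S_at_BrdU`` overlay).
    """
    meta_protocol = table.metadata.get("protocol", {})
    injections = meta_protocol.get("injections", [])
    if len(injections) == 2:
        t_i = injections[1][1] - injections[0][1]
    else:
        t_i = table.metadata.get("t_i")
    if not t_i:
        raise ValueError("table metadata does not define the inter-injection interval")
    if s_cell_convention == "at-sacrifice":
        s_col = "BrdU_pos"
    elif s_cell_convention == "at-injection":
        s_col = "S_at_BrdU"
    else:
        raise ValueError(f"unknown s_cell_convention {s_cell_convention!r}")
    if s_col not in table.data.columns:
        raise ValueError(f"table lacks the {s_col!r} column needed for "
                         f"convention {s_cell_convention!r}")
    rows = []
    for rec in table.rows():
        rows.append(DualPulseCounts(
            n_idu_only=int(rec["IdU_only"]),
            n_s_cells=int(rec[s_col]),
            n_cycling=int(max(rec["PCNA_pos"], rec[s_col])),
            t_i=float(t_i),
        ))
    return rows


def timecourse_series_from_table(table: CountTable) -> list[list[TimeCoursePoint]]:
    """Per-replicate time-course series from a g2-timecourse table."""
    series = []
    for rep, grp in table.data.groupby("replicate"):
        pts = [
            TimeCoursePoint(
                t=float(rec["sacrifice_time"]),
                n_phh3=int(rec["pHH3_pos"]),
                n_phh3_brdu=int(rec["pHH3_BrdU_pos"]),
            )
            for rec in grp.sort_values("sacrifice_time").to_dict("records")
        ]
        series.append(pts)
    return series


def quit_rows_from_table(table: CountTable) -> list[QuitCounts]:
    return [
        QuitCounts(
            n_brdu=int(rec["BrdU_pos"]),
            n_brdu_pcna_neg=int(rec["BrdU_PCNA_neg"]),
        )
        for rec in table.rows()
    ]
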