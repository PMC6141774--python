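"""statsmodels-style front end: a model built from count tables whose
``fit()`` returns a results object with estimates, CIs and a summary table.

The model bundles the study's four kinetic experiments — dual pulse
(T_S, T_C), BrdU->pHH3 time course (T_G2), mitotic index (T_M) and,
optionally, the 24 h pulse-chase (quit fraction) — and propagates their
replicate-level bootstrap uncertainty through the derived quantities
T_M = mitotic index x T_C and T_G1 = T_C - T_S - T_G2 - T_M.  Replicates
of the same experiment are resampled jointly (T_S and T_C share embryos);
different experiments are resampled independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import estimators as est
from .errors import InsufficientDataError, NoCrossingError
from .stats import BootstrapSpec, percentile_interval, resample_indices, wilson_interval
from .types import CountTable, EstimateWithCI, PhaseDurations

__all__ = ["CellCycleModel", "CellCycleResults"]


class CellCycleModel:
    """Cell-cycle kinetics model over a set of labelling experiments.

    Parameters
    ----------
    dual_pulse, g2_timecourse, mitotic_index, quit
        CountTables produced by the matching experiment designs (or read
        from their CSV dialect).  ``dual_pulse`` is required; the other
        panels are optional and simply restrict which parameters ``fit``
        can report.
    s_cell_convention
        How the S cohort of the dual pulse is counted; see
        :func:`cyclekinetics.estimators.dual_pulse_rows_from_table`.
    """

    def __init__(
        self,
        dual_pulse: CountTable | None = None,
        g2_timecourse: CountTable | None = None,
        mitotic_index: CountTable | None = None,
        quit: CountTable | None = None,
        s_cell_convention: str = "at-sacrifice",
    ):
        self.dual_pulse = dual_pulse
        self.g2_timecourse = g2_timecourse
        self.mitotic_index = mitotic_index
        self.quit = quit
        self.s_cell_convention = s_cell_convention

    @classmethod
    def from_tables(cls, tables, s_cell_convention: str = "at-sacrifice"
                    ) -> "CellCycleModel":
        """Build from a list of CountTables, dispatching on design name."""
        slots = {"dual-pulse": "dual_pulse", "g2-timecourse": "g2_timecourse",
                 "mitotic-index": "mitotic_index", "quit-24h": "quit",
                 "quit": "quit"}
        kw: dict = {}
        for t in tables:
            slot = slots.get(t.design)
            if slot is None:
                raise ValueError(f"no model slot for design {t.design!r}")
            kw[slot] = t
        return cls(**kw, s_cell_convention=s_cell_convention)

    # -- fitting -------------------------------------------------------
    def fit(self, bootstrap: BootstrapSpec | None = BootstrapSpec()
            ) -> "CellCycleResults":
        """Estimate every phase the supplied panels support.

        ``bootstrap=None`` skips CI computation (point estimates only).
        """
        estimates: dict[str, EstimateWithCI] = {}
        boot: dict[str, np.ndarray] = {}

        dp_rows = mi_counts = None
        if self.dual_pulse is not None:
            dp_rows = est.dual_pulse_rows_from_table(
                self.dual_pulse, self.s_cell_convention
            )
            estimates["t_s"] = est.estimate_ts(dp_rows)
            estimates["t_c"] = est.estimate_tc(None, dp_rows)
        if self.g2_timecourse is not None:
            series = est.timecourse_series_from_table(self.g2_timecourse)
            estimates["t_g2"] = est.estimate_tg2(series)
        if self.mitotic_index is not None:
            mi_counts = self.mitotic_index.pooled()
            n_phh3 = mi_counts["pHH3_pos"]
            n_cyc = mi_counts["PCNA_pos"]
            if "t_c" in estimates:
                estimates["t_m"] = est.estimate_tm(
                    n_phh3, n_cyc, estimates["t_c"].value
                )
            mi = n_phh3 / n_cyc
            lo, hi = wilson_interval(n_phh3, n_cyc)
            estimates["mitotic_index"] = EstimateWithCI(
                mi, min(lo, mi), max(hi, mi), method="wilson",
                n_replicates=self.mitotic_index.n_replicates, units="fraction",
            )
        if {"t_c", "t_s", "t_g2", "t_m"} <= estimates.keys():
            estimates["t_g1"] = est.estimate_tg1(
                estimates["t_c"], estimates["t_s"],
                estimates["t_g2"], estimates["t_m"],
            )
        if self.quit is not None:
            q_rows = est.quit_rows_from_table(self.quit)
            estimates["quit_fraction"] = est.quit_fraction(q_rows, bootstrap)

        if bootstrap is not None:
            self._bootstrap(estimates, boot, bootstrap)

        return CellCycleResults(self, estimates, boot)

    def _bootstrap(self, estimates, boot, spec: BootstrapSpec) -> None:
        """Joint replicate-level bootstrap across the kinetic panels."""
        B = spec.n_boot

        def resample(table, sub_seed):
            rows_by_rep = None
            reps = sorted(table.data["replicate"].unique())
            if len(reps) < 3:
                return None
            idx = resample_indices(len(reps), BootstrapSpec(
                n_boot=B, ci_level=spec.ci_level, seed=sub_seed, unit=spec.unit))
            return reps, idx

        # independent, deterministic sub-seeds per experiment
        ss = np.random.SeedSequence(spec.seed).spawn(3)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

        ts_b = tc_b = tg2_b = mi_b = None
        if self.dual_pulse is not None:
            dp_rows = est.dual_pulse_rows_from_table(
                self.dual_pulse, self.s_cell_convention)
            r = resample(self.dual_pulse, seeds[0])
            if r is not None:
                reps, idx = r
                ts_b = np.empty(B)
                tc_b = np.empty(B)
                for b in range(B):
                    rows = [dp_rows[i] for i in idx[b]]
                    ts_b[b] = est._ts_point(rows)
                    tc_b[b] = est._tc_point_factory(None)(rows)
                boot["t_s"], boot["t_c"] = ts_b, tc_b
        if self.g2_timecourse is not None:
            series = est.timecourse_series_from_table(self.g2_timecourse)
            if len(series) >= 3:
                idx = resample_indices(len(series), BootstrapSpec(
                    n_boot=B, ci_level=spec.ci_level, seed=seeds[1]))
                tg2_b = np.empty(B)
                for b in range(B):
                    try:
                        tg2_b[b] = est._tg2_point([series[i] for i in idx[b]])
                    except NoCrossingError:
                        tg2_b[b] = np.nan
                boot["t_g2"] = tg2_b
        if self.mitotic_index is not None:
            rows = [
                (int(rec["pHH3_pos"]), int(rec["PCNA_pos"]))
                for rec in self.mitotic_index.rows()
            ]
            if len(rows) >= 3:
                idx = resample_indices(len(rows), BootstrapSpec(
                    n_boot=B, ci_level=spec.ci_level, seed=seeds[2]))
                mi_b = np.empty(B)
                for b in range(B):
                    sel = [rows[i] for i in idx[b]]
                    mi_b[b] = sum(x for x, _ in sel) / sum(y for _, y in sel)
                boot["mitotic_index"] = mi_b

        if mi_b is not None and tc_b is not None:
            boot["t_m"] = mi_b * tc_b
        if all(k in boot for k in ("t_c", "t_s", "t_g2", "t_m")):
            boot["t_g1"] = boot["t_c"] - boot["t_s"] - boot["t_g2"] - boot["t_m"]

        for name, samples in boot.items():
            if name not in estimates:
                continue
            point = estimates[name]
            good = samples[np.isfinite(samples)]
            if good.size == 0:
                continue
            lo, hi = percentile_interval(good, spec.ci_level)
            lo, hi = min(lo, point.value), max(hi, point.value)
            estimates[name] = EstimateWithCI(
                point.value, lo, hi, ci_level=spec.ci_level,
                method=f"bootstrap-percentile(B={spec.n_boot})",
                n_replicates=point.n_replicates, units=point.units,
            )


@dataclass
class CellCycleResults:
    """Fitted cell-cycle kinetics with uncertainty.

    ``estimates`` maps parameter names (``t_s``, ``t_c``, ``t_g2``,
    ``t_m``, ``t_g1``, ``mitotic_index``, ``quit_fraction``) to
    :class:`EstimateWithCI`; ``bootstrap_samples`` keeps the raw bootstrap
    draws for diagnostics.
    """

    model: CellCycleModel
    estimates: dict[str, EstimateWithCI]
    bootstrap_samples: dict[str, np.ndarray] = field(default_factory=dict)

    _LABELS = {
        "t_c": "T_C (total cycle)",
        "t_g1": "T_G1",
        "t_s": "T_S",
        "t_g2": "T_G2",
        "t_m": "T_M",
        "mitotic_index": "mitotic index",
        "quit_fraction": "quit fraction",
    }

    def __getitem__(self, name: str) -> EstimateWithCI:
        return self.estimates[name]

    @property
    def phases(self) -> PhaseDurations:
        """Point estimates as a PhaseDurations (requires all four phases)."""
        need = ("t_g1", "t_s", "t_g2", "t_m")
        if not all(k in self.estimates for k in need):
            raise InsufficientDataError(
                "not all four phases were estimable from the supplied panels"
            )
        return PhaseDurations(*(self.estimates[k].value for k in need))

    def to_frame(self):
        import pandas as pd

        recs = []
        for name, e in self.estimates.items():
            recs.append({
                "parameter": name, "value": e.value, "ci_low": e.ci_low,
                "ci_high": e.ci_high, "ci_level": e.ci_level,
                "method": e.method, "n_replicates": e.n_replicates,
                "units": e.units,
            })
        return pd.DataFrame(recs).set_index("parameter")

    def to_records(self, design: str = "") -> list[dict]:
        """Flat JSON-ready records, one per parameter."""
        return [
            {"design": design, "parameter": name, **e.as_dict()}
            for name, e in self.estimates.items()
        ]

    def summary(self) -> str:
        order = ["t_c", "t_g1", "t_s", "t_g2", "t_m",
                 "mitotic_index", "quit_fraction"]
        lines = [
            "          Cell-cycle kinetics estimates",
            "=" * 66,
            f"{'parameter':<22}{'estimate':>9}{'ci_low':>9}{'ci_high':>9}"
            f"{'n':>4}  method",
            "-" * 66,
        ]
        for name in order:
            if name not in self.estimates:
                continue
            e = self.estimates[name]
            lines.append(
                f"{self._LABELS.get(name, name):<22}{e.value:>9.3f}"
                f"{e.ci_low:>9.3f}{e.ci_high:>9.3f}{e.n_replicates:>4}  "
                f"{e.method}"
            )
        lines.append("=" * 66)
        lines.append(f"CIs at {next(iter(self.estimates.values())).ci_level:.0%}; "
                     "durations in hours.")
        return "\n".join(lines)

    def plot_phase_composition(self, ax=None):
        """Pie chart of the estimated cycle composition (G1/S/G2/M)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        phases = self.phases
        if ax is None:
            _, ax = plt.subplots()
        vals = [phases.t_g1, phases.t_s, phases.t_g2, phases.t_m]
        ax.pie(vals, labels=["G1", "S", "G2", "M"],
               autopct=lambda p: f"{p * phases.t_c / 100:.1f} h")
        ax.set_title(f"T_C = {phases.t_c:.1f} h")
        return ax
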