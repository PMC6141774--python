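"""Core domain types: phase durations, labelling protocols, count tables.

Time is in hours throughout the package; parsers accept minutes and convert.
The cycle-position convention is position 0 = birth (start of G1), phases
ordered G1 -> S -> G2 -> M, all interval logic half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ProtocolError

__all__ = [
    "PhaseDurations",
    "Injection",
    "LabelingProtocol",
    "PopulationConfig",
    "CountTable",
    "EstimateWithCI",
]


@dataclass(frozen=True)
class PhaseDurations:
    """Durations of the four cell-cycle phases, in hours.

    The total cycle length ``t_c`` is always the exact sum
    ``t_g1 + t_s + t_g2 + t_m``.
    """

    t_g1: float
    t_s: float
    t_g2: float
    t_m: float

    def __post_init__(self):
        for name in ("t_g1", "t_s", "t_g2", "t_m"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def t_c(self) -> float:
        return self.t_g1 + self.t_s + self.t_g2 + self.t_m

    # Cycle-position landmarks (hours from birth), half-open intervals.
    @property
    def s_start(self) -> float:
        return self.t_g1

    @property
    def s_end(self) -> float:
        return self.t_g1 + self.t_s

    @property
    def g2_end(self) -> float:
        return self.t_g1 + self.t_s + self.t_g2

    def phh3_start(self, phh3_g2_fraction: float) -> float:
        """Position at which pHH3 immunoreactivity begins.

        pHH3 marks the terminal ``phh3_g2_fraction`` of G2 plus all of M.
        """
        return self.g2_end - phh3_g2_fraction * self.t_g2

    def as_dict(self) -> dict[str, float]:
        return {
            "t_g1": self.t_g1,
            "t_s": self.t_s,
            "t_g2": self.t_g2,
            "t_m": self.t_m,
            "t_c": self.t_c,
        }


@dataclass(frozen=True)
class Injection:
    """A single analogue injection (e.g. IdU or BrdU) at ``time`` hours."""

    analogue: str
    time: float


@dataclass(frozen=True)
class LabelingProtocol:
    """Injection schedule and sacrifice time(s) of a labelling experiment.

    Parameters
    ----------
    injections
        Ordered ``(analogue, time)`` pairs; times in hours from protocol
        start, non-negative and strictly increasing.
    sacrifice_times
        Hours from protocol start; strictly after the last injection when
        any injections are present.
    availability
        ``"persistent"`` (default): an injected analogue labels any cell
        that spends time in S between injection and sacrifice.
        ``"windowed"``: the analogue is only incorporable for
        ``window_hours`` after injection.
    detection_threshold
        Minimum labelled S-phase residence (hours) for a cell to score
        positive. 0 means any S-phase contact with available analogue,
        including an instantaneous one.
    """

    injections: tuple[Injection, ...]
    sacrifice_times: tuple[float, ...]
    availability: str = "persistent"
    window_hours: float | None = None
    detection_threshold: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self,
            "injections",
            tuple(
                inj if isinstance(inj, Injection) else Injection(*inj)
                for inj in self.injections
            ),
        )
        object.__setattr__(self, "sacrifice_times", tuple(float(t) for t in self.sacrifice_times))
        times = [inj.time for inj in self.injections]
        if any(t < 0 for t in times):
            raise ProtocolError("injection times must be non-negative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ProtocolError("injection times must be strictly increasing")
        if not self.sacrifice_times:
            raise ProtocolError("at least one sacrifice time is required")
        if any(b <= a for a, b in zip(self.sacrifice_times, self.sacrifice_times[1:])):
            raise ProtocolError("sacrifice times must be strictly increasing")
        if times and min(self.sacrifice_times) <= max(times):
            raise ProtocolError(
                "every sacrifice time must fall strictly after the last injection"
            )
        if self.availability not in ("persistent", "windowed"):
            raise ProtocolError(f"unknown availability model {self.availability!r}")
        if self.availability == "windowed":
            if self.window_hours is None or self.window_hours <= 0:
                raise ProtocolError("windowed availability requires window_hours > 0")
        if self.detection_threshold < 0:
            raise ProtocolError("detection_threshold must be >= 0")

    @property
    def analogues(self) -> tuple[str, ...]:
        return tuple(inj.analogue for inj in self.injections)

    def injection_time(self, analogue: str) -> float:
        for inj in self.injections:
            if inj.analogue == analogue:
                return inj.time
        raise KeyError(analogue)

    def availability_window(self, analogue: str, sacrifice_time: float) -> tuple[float, float]:
        """Closed time window during which ``analogue`` can label S-phase cells."""
        t0 = self.injection_time(analogue)
        if self.availability == "persistent":
            return t0, sacrifice_time
        return t0, min(sacrifice_time, t0 + float(self.window_hours))

    @property
    def inter_injection_interval(self) -> float | None:
        """T_i of a dual-pulse design (hours), or None if not a two-injection protocol."""
        if len(self.injections) != 2:
            return None
        return self.injections[1].time - self.injections[0].time

    def as_dict(self) -> dict:
        return {
            "injections": [[inj.analogue, inj.time] for inj in self.injections],
            "sacrifice_times": list(self.sacrifice_times),
            "availability": self.availability,
            "window_hours": self.window_hours,
            "detection_threshold": self.detection_threshold,
        }


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of the simulated progenitor population."""

    n_cells: int = 10_000
    age_distribution: str = "uniform"  # or "exponential_growth"
    quit_probability: float = 0.0
    phase_cv: float = 0.0
    phh3_g2_fraction: float = 0.3
    seed: int | None = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.quit_probability <= 1.0:
            raise ValueError("quit_probability must lie in [0, 1]")
        if not 0.0 <= self.phh3_g2_fraction <= 1.0:
            raise ValueError("phh3_g2_fraction must lie in [0, 1]")
        if self.phase_cv < 0:
            raise ValueError("phase_cv must be >= 0")
        if self.age_distribution not in ("uniform", "exponential_growth"):
            raise ValueError(f"unknown age_distribution {self.age_distribution!r}")

    def replace(self, **kw) -> "PopulationConfig":
        return dataclasses.replace(self, **kw)


class CountTable:
    """Integer cell counts per label/marker class, one row per replicate.

    Thin wrapper around a :class:`pandas.DataFrame` whose non-index columns
    are ``replicate``, ``sacrifice_time`` and one column per class label.
    ``metadata`` records the design name and the protocol that produced the
    counts, and survives the CSV round trip.
    """

    INDEX_COLUMNS = ("replicate", "sacrifice_time")

    def __init__(self, design: str, data: pd.DataFrame, metadata: Mapping | None = None):
        self.design = design
        data = data.reset_index(drop=True).copy()
        if "replicate" not in data.columns:
            data.insert(0, "replicate", range(len(data)))
        if "sacrifice_time" not in data.columns:
            data.insert(1, "sacrifice_time", float("nan"))
        self.data = data
        self.metadata = dict(metadata or {})
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_rows(
        cls,
        design: str,
        rows: Sequence[Mapping[str, int]],
        metadata: Mapping | None = None,
    ) -> "CountTable":
        return cls(design, pd.DataFrame(list(rows)), metadata=metadata)

    # -- basic accessors ----------------------------------------------
    @property
    def class_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.INDEX_COLUMNS]

    @property
    def n_replicates(self) -> int:
        return int(self.data["replicate"].nunique())

    def rows(self) -> list[dict]:
        return self.data.to_dict("records")

    def pooled(self, sacrifice_time: float | None = None) -> dict[str, int]:
        """Class counts summed over replicates (optionally at one time point)."""
        df = self.data
        if sacrifice_time is not None:
            df = df[np.isclose(df["sacrifice_time"].astype(float), sacrifice_time)]
        return {c: int(df[c].sum()) for c in self.class_columns}

    def subset_replicates(self, replicate_ids: Iterable) -> "CountTable":
        """Rows for the given replicate ids, with repetition (bootstrap resampling)."""
        parts = [self.data[self.data["replicate"] == r] for r in replicate_ids]
        out = CountTable.__new__(CountTable)
        out.design = self.design
        out.data = pd.concat(parts, ignore_index=True)
        out.metadata = dict(self.metadata)
        return out

    # -- validation ----------------------------------------------------
    #: containment relations checked when both columns are present
    SUBCLASS_RELATIONS = (
        ("pHH3_BrdU_pos", "pHH3_pos"),
        ("BrdU_PCNA_neg", "BrdU_pos"),
        ("BrdU_PCNA_pos", "BrdU_pos"),
        ("IdU_BrdU", "BrdU_pos"),
        ("IdU_BrdU", "IdU_pos"),
        ("IdU_only", "IdU_pos"),
        ("pHH3_pos", "PCNA_pos"),
    )

    def validate(self) -> None:
        for c in self.class_columns:
            col = self.data[c]
            if not np.issubdtype(col.dtype, np.number):
                raise ValueError(f"class column {c!r} is not numeric")
            vals = col.to_numpy()
            if np.any(vals < 0):
                raise ValueError(f"negative count in class {c!r}")
            if not np.allclose(vals, np.round(vals)):
                raise ValueError(f"non-integer count in class {c!r}")
        present = set(self.class_columns)
        for sub, sup in self.SUBCLASS_RELATIONS:
            if sub in present and sup in present:
                if np.any(self.data[sub].to_numpy() > self.data[sup].to_numpy()):
                    raise ValueError(f"subclass {sub!r} exceeds enclosing class {sup!r}")

    # -- I/O (CSV with '#'-prefixed metadata header) -------------------
    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("# cyclekinetics-counttable v1\n")
            fh.write(f"# design: {self.design}\n")
            fh.write(f"# metadata: {json.dumps(self.metadata, sort_keys=True)}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        design = None
        metadata: dict = {}
        n_header = 0
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                n_header += 1
                body = line[1:].strip()
                if body.startswith("design:"):
                    design = body.split(":", 1)[1].strip()
                elif body.startswith("metadata:"):
                    metadata = json.loads(body.split(":", 1)[1])
        if design is None:
            raise ValueError(f"{path}: not a cyclekinetics count table (no '# design:' line)")
        data = pd.read_csv(path, skiprows=n_header)
        return cls(design, data, metadata=metadata)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CountTable(design={self.design!r}, n_rows={len(self.data)}, "
            f"classes={self.class_columns})"
        )


@dataclass(frozen=True)
class EstimateWithCI:
    """A point estimate with its uncertainty interval.

    ``method`` records how the interval was obtained (closed formula,
    Wilson, or replicate bootstrap); a degenerate interval (ci_low ==
    ci_high == value) marks estimates whose data cannot support a CI.
    """

    value: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    method: str = "formula"
    n_replicates: int = 1
    units: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError(
                f"CI must contain the point estimate: "
                f"[{self.ci_low}, {self.ci_high}] vs {self.value}"
            )
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def degenerate(cls, value: float, method: str = "formula", units: str = "",
                   n_replicates: int = 1) -> "EstimateWithCI":
        return cls(value, value, value, method=method, units=units,
                   n_replicates=n_replicates)
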