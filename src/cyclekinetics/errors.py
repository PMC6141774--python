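"""Exception hierarchy for cell-cycle kinetics estimation."""

from __future__ import annotations


class CellCycleError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedConfigurationError(CellCycleError):
    """The closed-form oracle was asked about a non-steady-state configuration."""


class ProtocolError(CellCycleError):
    """A labelling protocol is internally inconsistent (ordering, timing)."""


class UndefinedEstimateError(CellCycleError):
    """An estimator's denominator is zero; the quantity is unbounded by the data."""


class NoCrossingError(CellCycleError):
    """The pHH3/BrdU time course never brackets the 50% level.

    Carries the one-sided bound the data do support.
    """

    def __init__(self, message: str, bound: str, t_bound_hours: float):
        super().__init__(message)
        self.bound = bound  # "below" -> T_G2 < t_bound, "above" -> T_G2 > t_bound
        self.t_bound_hours = t_bound_hours


class InconsistentEstimatesError(CellCycleError):
    """T_C - T_S - T_G2 - T_M came out negative; reported, never clamped."""

    def __init__(self, t_c: float, t_s: float, t_g2: float, t_m: float):
        self.t_c, self.t_s, self.t_g2, self.t_m = t_c, t_s, t_g2, t_m
        super().__init__(
            f"phase estimates are inconsistent: T_C - T_S - T_G2 - T_M = "
            f"{t_c - t_s - t_g2 - t_m:.4g} h < 0 "
            f"(T_C={t_c:.4g}, T_S={t_s:.4g}, T_G2={t_g2:.4g}, T_M={t_m:.4g})"
        )


class InsufficientDataError(CellCycleError):
    """Too few replicates / resampling units for the requested procedure."""


class SchemaError(CellCycleError):
    """A configuration or data file failed validation."""
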