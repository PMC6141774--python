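"""Closed-form steady-state oracle for expected label-class fractions.

For a deterministic-phase population with no cell-cycle exit, every cell
alive at sacrifice descends from exactly one founder, and all descendants
of a founder with initial cycle position ``a`` share the same position and
label status (both daughters inherit the label set).  Expected class
fractions at sacrifice time ``T`` therefore reduce to one-dimensional
integrals over ``a`` in ``[0, t_c)``:

    E[fraction in class C] =
        \\int g(a) w(a) [lineage(a) in C] da / \\int g(a) w(a) da

where ``g`` is the initial age density (uniform, or the exponential
steady-state density proportional to 2^(1 - a/t_c)) and
``w(a) = 2^floor((a + T)/t_c)`` counts the founder's descendants.

Every indicator involved is piecewise constant in ``a`` with breakpoints
known in closed form, so the integrals are evaluated exactly on the
elementary partition generated by those breakpoints — no quadrature.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .errors import UnsupportedConfigurationError
from .panels import PANELS, classify
from .types import LabelingProtocol, PhaseDurations, PopulationConfig

__all__ = [
    "expected_class_fractions",
    "expected_panel_fractions",
    "effective_sample_size",
]

_LN2 = math.log(2.0)
_EPS = 1e-12


def _check_supported(config: PopulationConfig) -> None:
    if config.quit_probability != 0:
        raise UnsupportedConfigurationError(
            "the oracle requires quit_probability = 0 (steady-state cycling pool)"
        )
    if config.phase_cv != 0:
        raise UnsupportedConfigurationError(
            "the oracle requires deterministic phase durations (phase_cv = 0)"
        )


def _exposure(a: float, w0: float, w1: float, s0: float, s1: float, t_c: float) -> float:
    """Labelled S-phase residence (hours) of the lineage with initial position a.

    The lineage is in S during times t with (a + t) mod t_c in [s0, s1);
    returns the Lebesgue measure of those t intersected with [w0, w1].
    """
    if w1 <= w0:
        return 0.0
    k_min = math.floor((w0 - (s1 - a)) / t_c) - 1
    k_max = math.floor((w1 - (s0 - a)) / t_c) + 1
    total = 0.0
    for k in range(k_min, k_max + 1):
        lo = s0 - a + k * t_c
        hi = s1 - a + k * t_c
        total += max(0.0, min(hi, w1) - max(lo, w0))
    return total


def _in_s_at(a: float, t: float, s0: float, s1: float, t_c: float) -> bool:
    return s0 <= (a + t) % t_c < s1


def _position_flag_breaks(x0: float, x1: float, t_obs: float, t_c: float) -> list[float]:
    """Breakpoints in a of the indicator (a + t_obs) mod t_c in [x0, x1)."""
    return [(x0 - t_obs) % t_c, (x1 - t_obs) % t_c]


def _segments(phases: PhaseDurations, protocol: LabelingProtocol,
              sacrifice_time: float, phh3_g2_fraction: float):
    """Elementary partition of [0, t_c) on which every flag is constant."""
    t_c = phases.t_c
    s0, s1 = phases.s_start, phases.s_end
    m0 = phases.phh3_start(phh3_g2_fraction)
    T = sacrifice_time

    breaks: list[float] = [0.0]
    breaks.append((-T) % t_c)  # descendant-count (weight) step
    breaks += _position_flag_breaks(s0, s1, T, t_c)       # in S at sacrifice
    breaks += _position_flag_breaks(m0, t_c, T, t_c)      # pHH3 at sacrifice
    windows: dict[str, tuple[float, float]] = {}
    for inj in protocol.injections:
        if inj.time > T:
            continue  # not yet injected at this sacrifice
        w0, w1 = protocol.availability_window(inj.analogue, T)
        windows[inj.analogue] = (w0, w1)
        for w in (w0, w1):
            breaks.append((s0 - w) % t_c)
            breaks.append((s1 - w) % t_c)
        breaks += _position_flag_breaks(s0, s1, inj.time, t_c)  # in S at injection
    breaks = sorted({b % t_c for b in breaks} | {0.0})
    grid = [b for b in breaks if b < t_c - _EPS] + [t_c]
    # merge near-duplicates
    merged = [grid[0]]
    for b in grid[1:]:
        if b - merged[-1] > _EPS * max(1.0, t_c):
            merged.append(b)
    merged[-1] = t_c

    theta = protocol.detection_threshold
    if theta > 0:
        # exposure is piecewise linear on the partition; insert theta-crossings
        refined = [merged[0]]
        for u, v in zip(merged, merged[1:]):
            for name, (w0, w1) in windows.items():
                eu = _exposure(u, w0, w1, s0, s1, t_c)
                ev = _exposure(v, w0, w1, s0, s1, t_c)
                if (eu - theta) * (ev - theta) < 0:
                    frac = (theta - eu) / (ev - eu)
                    refined.append(u + frac * (v - u))
            refined.append(v)
        merged = sorted(set(refined))
    return merged, windows


def _interval_measure(u: float, v: float, t_c: float, age_distribution: str) -> float:
    """Integral of the (unnormalised) initial age density over [u, v)."""
    if age_distribution == "uniform":
        return v - u
    # exponential steady state: density proportional to 2^(-a/t_c)
    return (t_c / _LN2) * (2.0 ** (-u / t_c) - 2.0 ** (-v / t_c))


def _lineage_flags(a: float, phases: PhaseDurations, protocol: LabelingProtocol,
                   sacrifice_time: float, phh3_g2_fraction: float,
                   windows: Mapping[str, tuple[float, float]]) -> dict[str, bool]:
    t_c = phases.t_c
    s0, s1 = phases.s_start, phases.s_end
    T = sacrifice_time
    pos = (a + T) % t_c
    theta = protocol.detection_threshold
    flags: dict[str, bool] = {
        "cycling": True,
        "in_s": s0 <= pos < s1,
        "phh3": pos >= phases.phh3_start(phh3_g2_fraction),
        "in_s_at_brdu": False,
    }
    for inj in protocol.injections:
        name = inj.analogue
        if name not in windows:
            flags[name] = False
            continue
        w0, w1 = windows[name]
        exp = _exposure(a, w0, w1, s0, s1, t_c)
        if theta > 0:
            positive = exp > theta
        else:
            # any S-phase contact with available analogue, incl. the closed
            # window endpoints (covers the instantaneous-labelling limit)
            positive = (
                exp > _EPS
                or _in_s_at(a, w0, s0, s1, t_c)
                or _in_s_at(a, w1, s0, s1, t_c)
            )
        flags[name] = positive
        if name == "BrdU":
            flags["in_s_at_brdu"] = _in_s_at(a, inj.time, s0, s1, t_c)
    for name in ("IdU", "BrdU"):
        flags.setdefault(name, False)
    # numpy bools so the shared panel predicates' ~ operator negates correctly
    return {k: np.bool_(v) for k, v in flags.items()}


def _weight(a: float, T: float, t_c: float) -> float:
    return 2.0 ** math.floor((a + T) / t_c)


def expected_class_fractions(
    phases: PhaseDurations,
    protocol: LabelingProtocol,
    config: PopulationConfig,
    panel: str | None = None,
) -> dict[float, dict[str, float]]:
    """Exact expected class fractions at each sacrifice time.

    With ``panel=None`` the classes are the atomic label-combination
    partition of the cycling pool (e.g. ``"IdU+BrdU-"``, ``"unlabeled"``);
    with a panel name, the classes are that panel's exclusive, derived and
    overlay classes, expressed as fractions of the whole population.

    Only steady-state configurations are supported: deterministic phases
    (``phase_cv = 0``) and no cell-cycle exit (``quit_probability = 0``).
    Both ``uniform`` and ``exponential_growth`` age densities are handled
    in closed form.
    """
    _check_supported(config)
    t_c = phases.t_c
    out: dict[float, dict[str, float]] = {}
    pdef = classify(panel) if panel is not None else None

    for T in protocol.sacrifice_times:
        grid, windows = _segments(phases, protocol, T, config.phh3_g2_fraction)
        masses: dict[str, float] = {}
        total = 0.0
        for u, v in zip(grid, grid[1:]):
            mid = 0.5 * (u + v)
            w = _weight(mid, T, t_c)
            mass = w * _interval_measure(u, v, t_c, config.age_distribution)
            total += mass
            flags = _lineage_flags(mid, phases, protocol, T,
                                   config.phh3_g2_fraction, windows)
            if pdef is None:
                label = "".join(
                    f"{name}{'+' if flags.get(name) else '-'}"
                    for name in protocol.analogues
                ) or "unlabeled"
                masses[label] = masses.get(label, 0.0) + mass
            else:
                for cname, pred in pdef.exclusive.items():
                    if pred(flags):
                        masses[cname] = masses.get(cname, 0.0) + mass
                for oname, pred in pdef.overlays.items():
                    if pred(flags):
                        masses[oname] = masses.get(oname, 0.0) + mass
        fracs = {k: m / total for k, m in masses.items()}
        if pdef is not None:
            for cname in pdef.exclusive:
                fracs.setdefault(cname, 0.0)
            for dname, parts in pdef.derived.items():
                fracs[dname] = sum(fracs[p] for p in parts)
            for oname in pdef.overlays:
                fracs.setdefault(oname, 0.0)
        out[T] = fracs
    return out


def expected_panel_fractions(
    phases: PhaseDurations,
    protocol: LabelingProtocol,
    config: PopulationConfig,
    panel: str,
) -> dict[float, dict[str, float]]:
    """Panel-specific expected fractions; see :func:`expected_class_fractions`."""
    return expected_class_fractions(phases, protocol, config, panel=panel)


def effective_sample_size(
    phases: PhaseDurations,
    config: PopulationConfig,
    sacrifice_time: float,
    n_cells: int,
) -> float:
    """Design-effect-corrected sample size of a simulated snapshot.

    Descendants of one founder share their class deterministically, so the
    snapshot behaves like a weighted sample of the founders with weights
    ``w(a) = 2^floor((a + T)/t_c)``.  The variance of a class fraction is
    ``f (1 - f) / n_eff`` with ``n_eff = n * E[w]^2 / E[w^2]``.
    """
    _check_supported(config)
    t_c = phases.t_c
    T = sacrifice_time
    breaks = sorted({0.0, (-T) % t_c, t_c} | {
        (k * t_c - T) % t_c for k in range(int(T // t_c) + 2)
    })
    breaks = [b for b in breaks if b < t_c - _EPS] + [t_c]
    ew = eww = norm = 0.0
    for u, v in zip(breaks, breaks[1:]):
        mid = 0.5 * (u + v)
        w = _weight(mid, T, t_c)
        g = _interval_measure(u, v, t_c, config.age_distribution)
        norm += g
        ew += w * g
        eww += w * w * g
    ew /= norm
    eww /= norm
    return n_cells * ew * ew / eww
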