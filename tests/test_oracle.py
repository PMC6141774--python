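"""Tests of the closed-form steady-state labelling oracle.

The independent check is a brute-force Monte-Carlo over founder cycle
positions: descendants of a founder share its class, so classes are
weighted fractions over uniformly drawn founder positions with weight
2^floor((a+T)/t_c).  The Monte-Carlo code below shares nothing with the
oracle's interval arithmetic.
"""

import numpy as np
import pytest

from cyclekinetics import (
    LabelingProtocol,
    PhaseDurations,
    PopulationConfig,
    UnsupportedConfigurationError,
    expected_class_fractions,
    expected_panel_fractions,
)


def _mc_dual_pulse(phases, n=1_000_000, seed=42):
    """Brute-force fractions for IdU@0, BrdU@1.5, sacrifice 2.0."""
    t_c = phases.t_c
    s0, s1 = phases.t_g1, phases.t_g1 + phases.t_s
    T = 2.0
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, t_c, n)
    w = 2.0 ** np.floor((a + T) / t_c)

    def labelled(w0, w1):
        # in S at some instant of [w0, w1]: sample nothing — check interval
        # overlap of {t : (a+t) mod t_c in [s0, s1)} with [w0, w1]
        hit = np.zeros(n, dtype=bool)
        kmax = int(np.ceil((w1 + t_c) / t_c)) + 1
        for k in range(-kmax, kmax + 1):
            lo = s0 - a + k * t_c
            hi = s1 - a + k * t_c
            hit |= (np.minimum(hi, w1) > np.maximum(lo, w0)) | (
                (lo <= w0) & (w0 < hi)) | ((lo <= w1) & (w1 < hi))
        return hit

    idu = labelled(0.0, T)
    brdu = labelled(1.5, T)

    def frac(mask):
        f = float(np.sum(w * mask) / np.sum(w))
        # MC standard error of the weighted ratio estimator
        se = float(np.sqrt(np.sum((w * (mask - f)) ** 2)) / np.sum(w))
        return f, se

    return {"IdU_only": frac(idu & ~brdu), "BrdU_pos": frac(brdu)}


def test_instantaneous_labelling_index_equals_s_occupancy():
    # single persistent pulse, sacrifice immediately after: BrdU+ = t_s/t_c
    phases = PhaseDurations(4, 4, 1.5, 0.5)
    proto = LabelingProtocol((("BrdU", 0.0),), (1e-9,))
    fr = expected_class_fractions(phases, proto, PopulationConfig(seed=0))
    assert fr[1e-9]["BrdU+"] == pytest.approx(0.4, abs=1e-6)


def test_no_injections_means_no_label():
    phases = PhaseDurations(5, 4, 1.5, 0.5)
    proto = LabelingProtocol((), (3.0,))
    fr = expected_class_fractions(phases, proto, PopulationConfig(seed=0))
    assert fr[3.0] == {"unlabeled": pytest.approx(1.0)}


def test_dual_pulse_fractions_match_brute_force_monte_carlo(phases):
    proto = LabelingProtocol((("IdU", 0.0), ("BrdU", 1.5)), (2.0,))
    fr = expected_panel_fractions(
        phases, proto, PopulationConfig(seed=0), "dual-pulse"
    )[2.0]
    mc = _mc_dual_pulse(phases)
    for cls in ("IdU_only", "BrdU_pos"):
        f_mc, se = mc[cls]
        assert abs(fr[cls] - f_mc) < 3 * se


@pytest.mark.parametrize("panel", [
    "dual-pulse", "g2-timecourse", "mitotic-index", "quit", "double-marker",
])
def test_exclusive_class_fractions_sum_to_one(phases, panel):
    proto = LabelingProtocol((("IdU", 0.0), ("BrdU", 1.5)), (2.0,))
    from cyclekinetics.panels import PANELS

    fr = expected_panel_fractions(
        phases, proto, PopulationConfig(seed=0), panel
    )[2.0]
    total = sum(fr[c] for c in PANELS[panel].exclusive)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_s_occupancy_strictly_increases_with_t_s():
    proto = LabelingProtocol((("BrdU", 0.0),), (1e-9,))
    prev = 0.0
    for t_s in (2.0, 3.0, 4.0, 5.0):
        phases = PhaseDurations(5.0, t_s, 1.5, 0.5)
        fr = expected_class_fractions(phases, proto, PopulationConfig(seed=0))
        cur = fr[1e-9]["BrdU+"]
        assert cur > prev
        assert cur == pytest.approx(t_s / phases.t_c, abs=1e-9)
        prev = cur


def test_windowed_availability_labels_fewer_cells_than_persistent(phases):
    persistent = LabelingProtocol((("BrdU", 0.0),), (3.0,))
    windowed = LabelingProtocol((("BrdU", 0.0),), (3.0,),
                                availability="windowed", window_hours=0.5)
    cfg = PopulationConfig(seed=0)
    f_p = expected_class_fractions(phases, persistent, cfg)[3.0]["BrdU+"]
    f_w = expected_class_fractions(phases, windowed, cfg)[3.0]["BrdU+"]
    assert f_w < f_p


def test_detection_threshold_reduces_positive_fraction(phases):
    cfg = PopulationConfig(seed=0)
    lax = LabelingProtocol((("BrdU", 0.0),), (1.0,))
    strict = LabelingProtocol((("BrdU", 0.0),), (1.0,),
                              detection_threshold=0.5)
    f_lax = expected_class_fractions(phases, lax, cfg)[1.0]["BrdU+"]
    f_strict = expected_class_fractions(phases, strict, cfg)[1.0]["BrdU+"]
    assert f_strict < f_lax


def test_non_steady_state_configurations_are_rejected(phases):
    proto = LabelingProtocol((("BrdU", 0.0),), (1.0,))
    with pytest.raises(UnsupportedConfigurationError):
        expected_class_fractions(
            phases, proto, PopulationConfig(quit_probability=0.2, seed=0)
        )
    with pytest.raises(UnsupportedConfigurationError):
        expected_class_fractions(
            phases, proto, PopulationConfig(phase_cv=0.1, seed=0)
        )


def test_exponential_growth_density_shifts_fractions(phases):
    # a growing population is enriched for young (early-G1) cells, so the
    # instantaneous S-phase occupancy drops below t_s/t_c
    proto = LabelingProtocol((("BrdU", 0.0),), (1e-9,))
    uni = expected_class_fractions(
        phases, proto, PopulationConfig(seed=0))[1e-9]["BrdU+"]
    exp = expected_class_fractions(
        phases, proto,
        PopulationConfig(age_distribution="exponential_growth", seed=0),
    )[1e-9]["BrdU+"]
    assert uni == pytest.approx(phases.t_s / phases.t_c, abs=1e-9)
    assert exp < uni
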