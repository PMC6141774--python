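import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclekinetics import (
    DualPulseCounts,
    InconsistentEstimatesError,
    NoCrossingError,
    QuitCounts,
    TimeCoursePoint,
    UndefinedEstimateError,
    double_label_proportion,
    estimate_tc,
    estimate_tg1,
    estimate_tg2,
    estimate_tm,
    estimate_ts,
    quit_fraction,
)


# ---------------------------------------------------------------------------
# dual pulse: T_S and T_C
# ---------------------------------------------------------------------------

def test_ts_formula_with_study_interval():
    d = DualPulseCounts(n_idu_only=300, n_s_cells=800, n_cycling=2000, t_i=1.5)
    assert estimate_ts(d).value == pytest.approx(4.0)


def test_ts_equals_interval_when_cohorts_match():
    d = DualPulseCounts(n_idu_only=500, n_s_cells=500, n_cycling=800, t_i=1.5)
    assert estimate_ts(d).value == pytest.approx(1.5)


def test_ts_undefined_without_leaving_cells():
    d = DualPulseCounts(n_idu_only=0, n_s_cells=100, n_cycling=200, t_i=1.5)
    with pytest.raises(UndefinedEstimateError):
        estimate_ts(d)


def test_tc_formula():
    d = DualPulseCounts(n_idu_only=300, n_s_cells=800, n_cycling=2000, t_i=1.5)
    assert estimate_tc(4.0, d).value == pytest.approx(10.0)


def test_tc_equals_ts_when_all_cycling_cells_in_s():
    d = DualPulseCounts(n_idu_only=100, n_s_cells=900, n_cycling=900, t_i=1.5)
    ts = estimate_ts(d)
    assert estimate_tc(ts, d).value == pytest.approx(ts.value)


def test_tc_never_below_ts():
    d = DualPulseCounts(n_idu_only=250, n_s_cells=700, n_cycling=1900, t_i=1.5)
    ts = estimate_ts(d)
    assert estimate_tc(ts, d).value >= ts.value


def test_tc_undefined_without_s_cells():
    d = DualPulseCounts(n_idu_only=10, n_s_cells=0, n_cycling=100, t_i=1.5)
    with pytest.raises(UndefinedEstimateError):
        estimate_tc(4.0, d)


@given(st.integers(2, 20))
@settings(deadline=None, max_examples=20)
def test_point_estimates_are_scale_equivariant(k):
    base = DualPulseCounts(n_idu_only=300, n_s_cells=800, n_cycling=2000, t_i=1.5)
    scaled = DualPulseCounts(300 * k, 800 * k, 2000 * k, 1.5)
    assert estimate_ts(scaled).value == pytest.approx(estimate_ts(base).value)
    assert estimate_tc(None, scaled).value == pytest.approx(
        estimate_tc(None, base).value)
    q = QuitCounts(500, 150)
    qk = QuitCounts(500 * k, 150 * k)
    assert quit_fraction(qk).value == pytest.approx(quit_fraction(q).value)


# ---------------------------------------------------------------------------
# T_G2 crossing
# ---------------------------------------------------------------------------

def test_tg2_linear_interpolation_between_points():
    pts = [TimeCoursePoint(1.0, 100, 30), TimeCoursePoint(1.5, 100, 55)]
    # p: 0.30 -> 0.55, crossing at 60 + 24 = 84 min
    assert estimate_tg2(pts).value == pytest.approx(1.4)


def test_tg2_exact_half_hit_returns_that_time():
    pts = [TimeCoursePoint(1.0, 100, 20), TimeCoursePoint(1.5, 100, 50),
           TimeCoursePoint(2.0, 100, 90)]
    assert estimate_tg2(pts).value == pytest.approx(1.5)


def test_tg2_requires_bracketing_of_the_half_level():
    low = [TimeCoursePoint(1.0, 100, 10), TimeCoursePoint(1.5, 100, 30)]
    with pytest.raises(NoCrossingError) as ei:
        estimate_tg2(low)
    assert ei.value.bound == "above"
    high = [TimeCoursePoint(1.0, 100, 70), TimeCoursePoint(1.5, 100, 90)]
    with pytest.raises(NoCrossingError) as ei:
        estimate_tg2(high)
    assert ei.value.bound == "below"


def test_tg2_needs_increasing_times():
    pts = [TimeCoursePoint(1.5, 100, 30), TimeCoursePoint(1.0, 100, 55)]
    with pytest.raises(ValueError):
        estimate_tg2(pts)


# ---------------------------------------------------------------------------
# T_M, T_G1, quit fraction, proportions
# ---------------------------------------------------------------------------

def test_tm_is_mitotic_index_times_cycle_length():
    assert estimate_tm(100, 2000, 10.0).value == pytest.approx(0.5)
    assert estimate_tm(0, 2000, 10.0).value == 0.0
    with pytest.raises(UndefinedEstimateError):
        estimate_tm(5, 0, 10.0)


def test_tg1_by_subtraction_and_boundary():
    assert estimate_tg1(10.0, 4.0, 1.5, 0.5).value == pytest.approx(4.0)
    assert estimate_tg1(6.0, 4.0, 1.5, 0.5).value == 0.0


def test_negative_tg1_raises_with_diagnostics():
    with pytest.raises(InconsistentEstimatesError) as ei:
        estimate_tg1(5.0, 4.0, 1.5, 0.5)
    err = ei.value
    assert (err.t_c, err.t_s, err.t_g2, err.t_m) == (5.0, 4.0, 1.5, 0.5)


def test_quit_fraction_ratio():
    q = QuitCounts(n_brdu=500, n_brdu_pcna_neg=150)
    est = quit_fraction(q)
    assert est.value == pytest.approx(0.30)
    assert 0 <= est.ci_low <= est.value <= est.ci_high <= 1


def _wilson_reference(k, n, z=1.959963984540054):
    # independent closed-form Wilson interval
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return centre - half, centre + half


def test_double_label_wilson_interval_matches_closed_form():
    est = double_label_proportion(50, 100)
    lo, hi = _wilson_reference(50, 100)
    assert est.value == pytest.approx(0.5)
    assert est.ci_low == pytest.approx(lo, abs=1e-10)
    assert est.ci_high == pytest.approx(hi, abs=1e-10)


def test_double_label_boundary_proportions():
    z = double_label_proportion(0, 40)
    assert z.value == 0.0 and z.ci_low == 0.0
    o = double_label_proportion(40, 40)
    assert o.value == 1.0 and o.ci_high == 1.0


def test_double_label_rejects_count_inversion():
    with pytest.raises(ValueError):
        double_label_proportion(11, 10)
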