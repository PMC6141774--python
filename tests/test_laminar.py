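import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclekinetics import (
    BinDistribution,
    DESIGNS,
    InsufficientDataError,
    LaminarSample,
    PopulationConfig,
    assign_bins,
    compare_distributions,
    simulate,
)
from cyclekinetics.laminar import bin_indices, read_depth_csv, write_bin_csv


def test_binning_rule_with_boundary_depths():
    dist = assign_bins(LaminarSample((0.05, 0.95, 0.95, 1.0)))
    assert dist.n_cells == 4
    assert dist.proportions[0] == pytest.approx(0.25)   # bin 1, superficial
    assert dist.proportions[9] == pytest.approx(0.75)   # bin 10, deepest
    assert sum(dist.proportions) == pytest.approx(1.0)


def test_bin_boundaries_are_half_open_except_the_deep_edge():
    # depth k/10 falls into bin k+1; depth 1.0 into bin 10
    assert list(bin_indices([0.0, 0.1, 0.999, 1.0])) == [1, 2, 10, 10]


def test_empty_sample_gives_zero_distribution():
    dist = assign_bins(LaminarSample(()))
    assert dist.n_cells == 0
    assert all(p == 0 for p in dist.proportions)


def test_depths_outside_unit_interval_are_rejected():
    with pytest.raises(ValueError):
        LaminarSample((0.5, 1.2))
    with pytest.raises(ValueError):
        bin_indices([-0.1])


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=80),
       st.randoms(use_true_random=False))
@settings(deadline=None, max_examples=40)
def test_cell_order_never_changes_the_distribution(depths, rnd):
    shuffled = list(depths)
    rnd.shuffle(shuffled)
    d1 = assign_bins(LaminarSample(tuple(depths)))
    d2 = assign_bins(LaminarSample(tuple(shuffled)))
    assert d1 == d2


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200))
@settings(deadline=None, max_examples=40)
def test_pairwise_bin_merging_conserves_mass_exactly(depths):
    props = np.array(assign_bins(LaminarSample(tuple(depths))).proportions)
    merged = props.reshape(5, 2).sum(axis=1)
    assert merged.sum() == pytest.approx(props.sum())
    assert props.sum() == pytest.approx(1.0)


def _multinomial_group(rng, p, n_reps=4, n_cells=800):
    out = []
    for _ in range(n_reps):
        counts = rng.multinomial(n_cells, p)
        out.append(BinDistribution(tuple(counts / n_cells), n_cells))
    return out


def test_identical_groups_flag_no_bin():
    rng = np.random.default_rng(7)
    p = np.full(10, 0.1)
    a = _multinomial_group(rng, p)
    b = _multinomial_group(rng, p)
    cmp = compare_distributions(a, b)
    assert cmp.flagged_bins == []


def test_large_shift_in_deepest_bin_is_flagged():
    rng = np.random.default_rng(11)
    p_a = np.full(10, 0.1)
    shift = 0.15
    p_b = p_a.copy()
    p_b[:9] -= shift / 9
    p_b[9] += shift
    a = _multinomial_group(rng, p_a)
    b = _multinomial_group(rng, p_b)
    cmp = compare_distributions(a, b)
    assert 10 in cmp.flagged_bins
    row = cmp.table.loc[10]
    assert row["diff"] == pytest.approx(shift, abs=0.05)


def test_single_replicate_groups_are_rejected():
    rng = np.random.default_rng(3)
    p = np.full(10, 0.1)
    with pytest.raises(InsufficientDataError):
        compare_distributions(_multinomial_group(rng, p, n_reps=1),
                              _multinomial_group(rng, p, n_reps=4))


def test_birthdating_simulation_concentrates_early_cohort_in_deep_bins(phases):
    """Depth binning agrees with a direct count of simulator assignments."""
    cfg = PopulationConfig(n_cells=3000, quit_probability=0.4, seed=23)
    snap = simulate(phases, DESIGNS["birthdating"].protocol, cfg)[0]
    post = snap.data[snap.data["fate"] == "postmitotic"]
    early = post[post["birth_time"] <= post["birth_time"].quantile(0.3)]
    dist = assign_bins(LaminarSample(tuple(early["normalized_depth"])))
    # early-born neurons sit deep: mass concentrated in high-index bins
    assert sum(dist.proportions[7:]) > 0.9
    # cross-check one bin against a direct count
    direct = int(((early["normalized_depth"] >= 0.9)).sum())
    expected_bin10 = direct / len(early)
    assert dist.proportions[9] == pytest.approx(expected_bin10, abs=1e-12)


def test_depth_csv_roundtrip(tmp_path):
    path = tmp_path / "depths.csv"
    path.write_text(
        "replicate,marker,normalized_depth\n"
        "e1,Tbr1,0.91\ne1,Tbr1,0.95\ne1,Ctip2,0.55\ne2,Tbr1,0.88\n"
    )
    samples = read_depth_csv(path)
    keys = {(s.replicate_id, s.marker) for s in samples}
    assert keys == {("e1", "Tbr1"), ("e1", "Ctip2"), ("e2", "Tbr1")}
    out = tmp_path / "bins.csv"
    write_bin_csv(out, [(s, assign_bins(s)) for s in samples])
    text = out.read_text()
    assert "bin_10" in text and "n_cells" in text
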