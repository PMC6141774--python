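import numpy as np
import pandas as pd
import pytest

from cyclekinetics import (
    DESIGNS,
    LabelingProtocol,
    PhaseDurations,
    PopulationConfig,
    ProtocolError,
    effective_sample_size,
    expected_panel_fractions,
    generate_experiment,
    simulate,
    tabulate,
)
from cyclekinetics.popsim import PopulationSnapshot


def test_nobody_exits_when_quit_probability_is_zero(phases):
    proto = LabelingProtocol((), (1.0, 5.0, 12.0))
    cfg = PopulationConfig(n_cells=2000, seed=11)
    for snap in simulate(phases, proto, cfg):
        assert snap.data["pcna"].all()


def test_mitotic_fraction_matches_binomial_oracle(phases):
    # with pHH3 restricted to M (phh3_g2_fraction=0), fraction = t_m/t_c
    proto = LabelingProtocol((), (0.0,))
    n = 100_000
    cfg = PopulationConfig(n_cells=n, phh3_g2_fraction=0.0, seed=21)
    snap = simulate(phases, proto, cfg)[0]
    f = phases.t_m / phases.t_c
    se = np.sqrt(f * (1 - f) / n)
    assert abs(snap.fraction("phh3") - f) < 3 * se


def test_saturating_label_after_a_full_cycle(phases):
    # persistent BrdU for 24 h > t_c: every cycling cell has traversed S
    proto = DESIGNS["quit-24h"].protocol
    cfg = PopulationConfig(n_cells=3000, seed=31)
    snap = simulate(phases, proto, cfg)[0]
    cycling = snap.data[snap.data["pcna"]]
    assert cycling["label_BrdU"].all()


def test_counts_are_deterministic_for_fixed_seed(phases):
    cfg = PopulationConfig(n_cells=2000, seed=77)
    t1 = generate_experiment("dual-pulse", phases, cfg, 4, seed=5)
    t2 = generate_experiment("dual-pulse", phases, cfg, 4, seed=5)
    pd.testing.assert_frame_equal(t1.data, t2.data)
    t3 = generate_experiment("dual-pulse", phases, cfg, 4, seed=6)
    assert not t1.data.equals(t3.data)


def test_quit_one_extinguishes_cycling_pool_within_one_cycle(phases):
    proto = LabelingProtocol((), (phases.t_c + 0.01, 24.0))
    cfg = PopulationConfig(n_cells=500, quit_probability=1.0, seed=9)
    snaps = simulate(phases, proto, cfg)
    for snap in snaps:
        assert int(snap.data["pcna"].sum()) == 0
        # conservation: every founder's two daughters persist postmitotically
        assert snap.n_cells == 1000


def test_sacrifice_before_first_injection_is_a_protocol_error(phases):
    with pytest.raises(ProtocolError):
        LabelingProtocol((("BrdU", 2.0),), (1.0,))


def _toy_snapshot():
    """3 cycling BrdU+ cells, 1 postmitotic BrdU+, 1 unlabeled cycling."""
    data = pd.DataFrame({
        "birth_time": [0.0] * 5,
        "fate": ["cycling"] * 3 + ["postmitotic", "cycling"],
        "position": [1.0, 2.0, 3.0, np.nan, 1.0],
        "t_g1": [5.0] * 5, "t_s": [4.0] * 5, "t_g2": [1.5] * 5,
        "t_m": [0.5] * 5,
        "in_s": [False] * 5,
        "phh3": [False] * 5,
        "pcna": [True, True, True, False, True],
        "normalized_depth": [np.nan] * 3 + [0.5, np.nan],
        "label_BrdU": [True, True, True, True, False],
    })
    return PopulationSnapshot(24.0, data, ("BrdU",))


def test_tabulate_quit_panel_counts_directly():
    tab = tabulate(_toy_snapshot(), "quit")
    row = tab.data.iloc[0]
    assert row["BrdU_pos"] == 4
    assert row["BrdU_PCNA_neg"] == 1
    assert row["total"] == 5


def test_tabulate_empty_snapshot_gives_all_zero_counts():
    empty = PopulationSnapshot(1.0, pd.DataFrame(), ())
    tab = tabulate(empty, "quit")
    assert (tab.data[tab.class_columns].iloc[0] == 0).all()


def test_tabulate_rejects_unknown_panel():
    with pytest.raises(KeyError):
        tabulate(_toy_snapshot(), "no-such-panel")


@pytest.mark.parametrize("design", ["dual-pulse", "g2-timecourse",
                                    "mitotic-index", "quit"])
def test_simulated_fractions_match_oracle_per_panel(phases, design):
    """Simulator vs closed-form oracle, per panel, 3 effective-n binomial SE."""
    key = design if design != "quit" else "quit-24h"
    d = DESIGNS[key]
    n = 20_000
    cfg = PopulationConfig(n_cells=n, seed=sum(design.encode()))
    expected = expected_panel_fractions(phases, d.protocol, cfg, d.panel)
    snaps = simulate(phases, d.protocol, cfg)
    for snap in snaps:
        tab = tabulate(snap, d.panel)
        total = snap.n_cells
        n_eff = effective_sample_size(phases, cfg, snap.sacrifice_time, n)
        for cls, f in expected[snap.sacrifice_time].items():
            obs = tab.data[cls].iloc[0] / total
            if f in (0.0, 1.0):
                assert obs == f
            else:
                se = np.sqrt(f * (1 - f) / n_eff)
                assert abs(obs - f) < 3 * se, (cls, obs, f)


def test_generate_experiment_schema_and_replicates(phases):
    cfg = PopulationConfig(n_cells=500, seed=3)
    tab = generate_experiment("g2-timecourse", phases, cfg, 3, seed=8)
    assert {"pHH3_pos", "pHH3_BrdU_pos"} <= set(tab.class_columns)
    assert tab.n_replicates == 3
    assert sorted(tab.data["sacrifice_time"].unique()) == [1.0, 1.5, 2.0]
    with pytest.raises(KeyError):
        generate_experiment("no-such-design", phases, cfg, 2, seed=1)


def test_quit_design_reports_zero_exit_without_quitting(phases):
    cfg = PopulationConfig(n_cells=1000, seed=13)
    tab = generate_experiment("quit-24h", phases, cfg, 3, seed=2)
    assert (tab.data["BrdU_PCNA_neg"] == 0).all()
    assert (tab.data["BrdU_pos"] > 0).all()


def test_earlier_born_neurons_settle_deeper(phases):
    cfg = PopulationConfig(n_cells=2000, quit_probability=0.4, seed=17)
    snap = simulate(phases, DESIGNS["birthdating"].protocol, cfg)[0]
    post = snap.data[snap.data["fate"] == "postmitotic"]
    assert len(post) > 100
    depths = post["normalized_depth"].to_numpy()
    births = post["birth_time"].to_numpy()
    assert depths.min() >= 0 and depths.max() <= 1
    # birth order and depth rank agree (ties in birth time broken arbitrarily)
    early = depths[births <= np.quantile(births, 0.25)]
    late = depths[births >= np.quantile(births, 0.75)]
    assert early.mean() > late.mean() + 0.3
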