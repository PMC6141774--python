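"""Staining-panel definitions shared by the simulator and the oracle.

A panel mirrors one immunofluorescence experiment: a set of mutually
exclusive, exhaustive classes (they always sum to the whole population)
plus derived convenience classes that are sums of exclusive ones, and
"overlay" classes that cut across the partition (counted independently).

Class predicates operate on a mapping of boolean flags and work unchanged
on scalars (oracle, one cycle-position stratum at a time) and on numpy
arrays (simulator snapshots):

``IdU``/``BrdU``  analogue positivity at sacrifice
``cycling``       PCNA+ (actively proliferating)
``in_s``          in S phase at sacrifice
``phh3``          pHH3+ (terminal G2 or M)
``in_s_at_brdu``  in S phase at the instant of the BrdU injection
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = ["PanelDef", "PANELS", "classify", "panel_names"]

Flags = Mapping[str, object]


@dataclass(frozen=True)
class PanelDef:
    name: str
    #: name -> predicate over flags; mutually exclusive and exhaustive
    exclusive: dict[str, Callable[[Flags], object]]
    #: name -> list of exclusive class names whose counts are summed
    derived: dict[str, list[str]] = field(default_factory=dict)
    #: name -> predicate counted independently of the partition
    overlays: dict[str, Callable[[Flags], object]] = field(default_factory=dict)

    def counts(self, flags: Mapping[str, np.ndarray], n: int) -> dict[str, int]:
        """Tabulate a snapshot's boolean flag arrays into class counts."""
        out: dict[str, int] = {}
        total = 0
        for cname, pred in self.exclusive.items():
            c = int(np.count_nonzero(pred(flags)))
            out[cname] = c
            total += c
        if total != n:
            raise AssertionError(
                f"panel {self.name!r}: exclusive classes sum to {total}, not {n}"
            )
        for dname, parts in self.derived.items():
            out[dname] = sum(out[p] for p in parts)
        for oname, pred in self.overlays.items():
            out[oname] = int(np.count_nonzero(pred(flags)))
        out["total"] = n
        return out


def _f(key: str):
    return lambda flags: flags[key]


PANELS: dict[str, PanelDef] = {
    # IdU/BrdU dual pulse (T_S and T_C): IdU at 0, BrdU T_i later.
    "dual-pulse": PanelDef(
        "dual-pulse",
        exclusive={
            "IdU_only": lambda f: f["IdU"] & ~f["BrdU"] & f["cycling"],
            "IdU_BrdU": lambda f: f["IdU"] & f["BrdU"] & f["cycling"],
            "BrdU_only": lambda f: ~f["IdU"] & f["BrdU"] & f["cycling"],
            "label_neg": lambda f: ~f["IdU"] & ~f["BrdU"] & f["cycling"],
            "PCNA_neg": lambda f: ~f["cycling"],
        },
        derived={
            "BrdU_pos": ["IdU_BrdU", "BrdU_only"],
            "IdU_pos": ["IdU_only", "IdU_BrdU"],
            "PCNA_pos": ["IdU_only", "IdU_BrdU", "BrdU_only", "label_neg"],
        },
        overlays={
            # cycling cells in S at the BrdU injection instant; supports the
            # "at-injection" S-cell counting convention.
            "S_at_BrdU": lambda f: f["in_s_at_brdu"] & f["cycling"],
        },
    ),
    # BrdU pulse followed by pHH3 staining at several delays (T_G2).
    "g2-timecourse": PanelDef(
        "g2-timecourse",
        exclusive={
            "pHH3_BrdU_pos": lambda f: f["phh3"] & f["BrdU"],
            "pHH3_BrdU_neg": lambda f: f["phh3"] & ~f["BrdU"],
            "pHH3_neg": lambda f: ~f["phh3"],
        },
        derived={"pHH3_pos": ["pHH3_BrdU_pos", "pHH3_BrdU_neg"]},
    ),
    # pHH3 vs PCNA (mitotic index, T_M).
    "mitotic-index": PanelDef(
        "mitotic-index",
        exclusive={
            "pHH3_pos": lambda f: f["phh3"],
            "PCNA_pHH3_neg": lambda f: f["cycling"] & ~f["phh3"],
            "PCNA_neg": lambda f: ~f["cycling"],
        },
        derived={"PCNA_pos": ["pHH3_pos", "PCNA_pHH3_neg"]},
    ),
    # BrdU pulse, 24 h chase, PCNA staining (cell-cycle exit fraction).
    "quit": PanelDef(
        "quit",
        exclusive={
            "BrdU_PCNA_pos": lambda f: f["BrdU"] & f["cycling"],
            "BrdU_PCNA_neg": lambda f: f["BrdU"] & ~f["cycling"],
            "BrdU_neg_PCNA_pos": lambda f: ~f["BrdU"] & f["cycling"],
            "BrdU_neg_PCNA_neg": lambda f: ~f["BrdU"] & ~f["cycling"],
        },
        derived={
            "BrdU_pos": ["BrdU_PCNA_pos", "BrdU_PCNA_neg"],
            "PCNA_pos": ["BrdU_PCNA_pos", "BrdU_neg_PCNA_pos"],
            "PCNA_neg": ["BrdU_PCNA_neg", "BrdU_neg_PCNA_neg"],
        },
    ),
    # Generic progenitor-vs-neuron double staining (e.g. Pax6/PCNA).
    "double-marker": PanelDef(
        "double-marker",
        exclusive={
            "PCNA_pos": lambda f: f["cycling"],
            "PCNA_neg": lambda f: ~f["cycling"],
        },
    ),
    # Birthdating: BrdU pulse, long chase, neurons scored for the label.
    "birthdating": PanelDef(
        "birthdating",
        exclusive={
            "neuron_BrdU_pos": lambda f: f["BrdU"] & ~f["cycling"],
            "neuron_BrdU_neg": lambda f: ~f["BrdU"] & ~f["cycling"],
            "progenitor": lambda f: f["cycling"],
        },
        derived={"neuron_total": ["neuron_BrdU_pos", "neuron_BrdU_neg"]},
    ),
}


def panel_names() -> list[str]:
    return list(PANELS)


def classify(panel: str) -> PanelDef:
    try:
        return PANELS[panel]
    except KeyError:
        raise KeyError(
            f"unknown panel {panel!r}; known panels: {', '.join(PANELS)}"
        ) from None
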