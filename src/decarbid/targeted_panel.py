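"""Targeted MRM amino-acid panel: the simple-system activity assay.

A triple-quadrupole transition list (19 amino acid analytes; the printed
panel contains no glycine entry and carries cystine rather than cysteine)
is quantified in vector-control vs enzyme samples by trapezoidal peak
integration with local baseline subtraction, and per-analyte depletion is
reported with the same ratio/pseudocount logic as the untargeted branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metabolites as _metab
from .differential import default_pseudocount, vector_enzyme_ratio
from .masscalc import PROTON_MASS, formula_mass
from .runs import MRMTrace

__all__ = [
    "Transition",
    "PanelResult",
    "BUILTIN_TRANSITIONS",
    "load_transitions",
    "integrate_trace",
    "panel_compare",
]


@dataclass(frozen=True)
class Transition:
    """One MRM transition: precursor (Q1), fragment (Q3), collision energy."""

    analyte: str
    q1: float
    q3: float
    collision_energy: float  # volts
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.q3 >= self.q1 + 0.1:
            raise ValueError(
                f"{self.analyte}: Q3 {self.q3} not below precursor Q1 {self.q1}"
            )


# The built-in amino acid transition panel (nominal masses as printed on
# the instrument method; these, not formula-derived values, drive matching).
_BUILTIN_ROWS: list[tuple[str, float, float, float]] = [
    ("alanine", 90.1, 44.2, 13.0),
    ("arginine", 175.02, 60.0, 16.0),
    ("asparagine", 133.1, 74.0, 19.0),
    ("aspartic acid", 134.0, 74.0, 17.0),
    ("cystine", 241.002, 74.0, 32.0),
    ("glutamic acid", 148.1, 84.1, 17.0),
    ("glutamine", 147.1, 84.1, 17.0),
    ("histidine", 156.1, 110.1, 14.0),
    ("isoleucine", 132.1, 86.0, 13.0),
    ("leucine", 132.1, 86.0, 13.0),
    ("lysine", 147.0, 67.0, 32.0),
    ("methionine", 150.1, 133.0, 12.0),
    ("phenylalanine", 166.1, 103.0, 30.0),
    ("proline", 116.1, 70.1, 13.0),
    ("serine", 106.0, 60.0, 15.0),
    ("threonine", 120.0, 74.0, 13.0),
    ("tryptophan", 205.0, 146.0, 18.0),
    ("tyrosine", 182.1, 77.0, 39.0),
    ("valine", 118.1, 55.2, 13.0),
]

BUILTIN_TRANSITIONS: list[Transition] = [
    Transition(name, q1, q3, ce) for name, q1, q3, ce in _BUILTIN_ROWS
]


def nominal_q1(formula: str) -> float:
    """Formula-derived nominal precursor: monoisotopic [M+H]+ to 1 decimal."""
    return round(formula_mass(formula) + PROTON_MASS, 1)


def load_transitions(
    source: str | Path | None = None, validate: bool = True
) -> list[Transition]:
    """The transition panel, from a CSV file or the built-in table.

    CSV columns: analyte, q1, q3, ce[, polarity]. With ``validate`` each
    Q1 is checked against the formula-derived nominal [M+H]+; a deviation
    above 0.25 raises a warning (printed instrument tables round
    inconsistently, so this is advisory, never an error).
    """
    if source is None:
        transitions = list(BUILTIN_TRANSITIONS)
    else:
        frame = pd.read_csv(source)
        transitions = [
            Transition(
                str(r["analyte"]),
                float(r["q1"]),
                float(r["q3"]),
                float(r["ce"]),
                str(r.get("polarity", "positive")),
            )
            for _, r in frame.iterrows()
        ]
    seen = set()
    for tr in transitions:
        key = (tr.analyte, tr.q1, tr.q3)
        if key in seen:
            raise ValueError(f"duplicate transition {key}")
        seen.add(key)
        if validate and tr.analyte in _metab.FORMULAS:
            expected = nominal_q1(_metab.FORMULAS[tr.analyte])
            if abs(tr.q1 - expected) > 0.25:
                warnings.warn(
                    f"{tr.analyte}: Q1 {tr.q1} deviates from formula-derived "
                    f"nominal {expected}",
                    stacklevel=2,
                )
    return transitions


def integrate_trace(
    trace: MRMTrace, rt_window: tuple[float, float]
) -> tuple[float, float, float]:
    """(area, height, rt_apex) over a window with local baseline removal.

    The baseline is the straight line between the window's endpoints; the
    baseline-subtracted signal is clamped at zero before trapezoidal
    integration, which makes the result invariant under any constant
    intensity offset. An empty window yields zeros.
    """
    lo, hi = rt_window
    mask = (trace.rt >= lo) & (trace.rt <= hi)
    if mask.sum() < 2:
        return 0.0, 0.0, 0.0
    t = trace.rt[mask]
    y = trace.intensity[mask]
    baseline = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
    sub = np.clip(y - baseline, 0.0, None)
    area = float(np.trapezoid(sub, t))
    apex = int(np.argmax(sub))
    return area, float(sub[apex]), float(t[apex])


@dataclass
class PanelResult:
    """Per-analyte group means, vector/enzyme ratios and depletion flags."""

    table: pd.DataFrame  # columns: analyte, mean_vector, mean_enzyme, ratio, depleted
    pseudocount: float
    fold_threshold: float

    @property
    def depleted(self) -> list[str]:
        return self.table.loc[self.table["depleted"], "analyte"].tolist()

    def ratio(self, analyte: str) -> float:
        sel = self.table.loc[self.table["analyte"] == analyte, "ratio"]
        if sel.empty:
            raise KeyError(analyte)
        return float(sel.iloc[0])


def panel_compare(
    traces: list[MRMTrace],
    transitions: list[Transition] | None = None,
    rt_map: dict[str, float] | None = None,
    rt_half_window: float = 0.5,
    fold_threshold: float = 2.0,
    pseudocount: float | None = None,
) -> PanelResult:
    """Integrate every analyte per group and flag depleted substrates.

    Integration windows default to the library retention time +- 0.5 min
    per analyte. Ratios use the same pseudocount convention as the
    untargeted branch and analytes with ratio >= ``fold_threshold`` are
    flagged depleted. The report is ordered by ratio descending.
    """
    transitions = transitions or load_transitions()
    rt_map = rt_map or _metab.RETENTION_TIMES
    by_analyte: dict[str, dict[str, list[float]]] = {}
    for tr in transitions:
        group_traces = [t for t in traces if t.analyte == tr.analyte]
        if not group_traces:
            continue
        groups = {t.group for t in group_traces}
        if not {"vector", "enzyme"} <= groups:
            raise ValueError(
                f"{tr.analyte}: traces missing for group "
                f"{sorted({'vector', 'enzyme'} - groups)}"
            )
        rt = rt_map.get(tr.analyte)
        areas: dict[str, list[float]] = {"vector": [], "enzyme": []}
        for t in group_traces:
            center = rt if rt is not None else float(t.rt[np.argmax(t.intensity)])
            area, _, _ = integrate_trace(
                t, (center - rt_half_window, center + rt_half_window)
            )
            areas[t.group].append(area)
        by_analyte[tr.analyte] = areas
    if not by_analyte:
        raise ValueError("no traces match any transition in the panel")
    all_areas = np.array(
        [a for d in by_analyte.values() for g in d.values() for a in g]
    )
    if pseudocount is None:
        pseudocount = default_pseudocount(all_areas)
    rows = []
    for analyte, areas in by_analyte.items():
        mv = float(np.mean(areas["vector"]))
        me = float(np.mean(areas["enzyme"]))
        ratio = vector_enzyme_ratio(mv, me, pseudocount)
        rows.append(
            {
                "analyte": analyte,
                "mean_vector": mv,
                "mean_enzyme": me,
                "ratio": ratio,
                "depleted": ratio >= fold_threshold,
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        "ratio", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return PanelResult(frame, pseudocount, fold_threshold)
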