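"""Cross-sample feature table construction.

Join alignment merges each run's features into a growing consensus using a
combined m/z + retention-time proximity score; gap filling recovers missing
cells directly from the raw scans; duplicate filtering collapses rows that
ended up within both tolerances of each other.

Defaults follow the untargeted workflow settings: RT tolerance 0.2 min,
unit weights for the m/z and RT score terms, gap-filling intensity
tolerance 1.0 with a one-point minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .feature_extraction import Feature, mz_tolerance
from .runs import Run

__all__ = [
    "AlignedFeature",
    "FeatureTable",
    "join_align",
    "gap_fill",
    "filter_duplicates",
]

_NEW_ROW_COST = 1e6
_FORBIDDEN = 1e9


@dataclass
class AlignedFeature:
    """One consensus row: member features plus filled/missing cells."""

    mz: float
    rt: float
    members: dict[str, Feature] = field(default_factory=dict)
    filled: dict[str, float] = field(default_factory=dict)

    def status(self, run_id: str) -> str:
        if run_id in self.members:
            return "detected"
        if self.filled.get(run_id, 0.0) > 0.0:
            return "gap_filled"
        return "missing"

    def value(self, run_id: str) -> float:
        if run_id in self.members:
            return self.members[run_id].area
        return self.filled.get(run_id, 0.0)

    def refresh_consensus(self) -> None:
        self.mz = float(np.mean([f.mz for f in self.members.values()]))
        self.rt = float(np.mean([f.rt_apex for f in self.members.values()]))


@dataclass
class FeatureTable:
    """Aligned features across runs with vector/enzyme group labels."""

    run_ids: list[str]
    groups: dict[str, str]  # run_id -> {"vector", "enzyme"}
    rows: list[AlignedFeature]
    polarity: str = "positive"

    def intensity_matrix(self) -> np.ndarray:
        return np.array(
            [[row.value(rid) for rid in self.run_ids] for row in self.rows]
        )

    def group_runs(self, label: str) -> list[str]:
        return [rid for rid in self.run_ids if self.groups.get(rid) == label]

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, list] = {
            "mz": [r.mz for r in self.rows],
            "rt": [r.rt for r in self.rows],
        }
        for rid in self.run_ids:
            data[rid] = [row.value(rid) for row in self.rows]
            data[f"{rid}_status"] = [row.status(rid) for row in self.rows]
        return pd.DataFrame(data)

    def __len__(self) -> int:
        return len(self.rows)


def _pair_score(
    feature: Feature,
    row: AlignedFeature,
    mz_tol_da: float,
    mz_tol_ppm: float,
    rt_tol: float,
    w_mz: float,
    w_rt: float,
) -> float:
    """Tolerance-normalized match score; +inf when out of tolerance."""
    tol = mz_tolerance(row.mz, mz_tol_da, mz_tol_ppm)
    dmz = abs(feature.mz - row.mz)
    drt = abs(feature.rt_apex - row.rt)
    if dmz > tol or drt > rt_tol:
        return np.inf
    return w_mz * dmz / tol + w_rt * drt / rt_tol


def join_align(
    per_run_features: dict[str, list[Feature]],
    groups: dict[str, str] | None = None,
    mz_tol_da: float = 0.002,
    mz_tol_ppm: float = 20.0,
    rt_tol: float = 0.2,
    w_mz: float = 1.0,
    w_rt: float = 1.0,
    polarity: str = "positive",
) -> FeatureTable:
    """Sequentially merge runs into a consensus feature table.

    Runs are processed in input order. For each run, its features are
    matched to consensus rows within both tolerances by minimizing the
    summed score ``w_mz * dmz/mz_tol + w_rt * drt/rt_tol`` over an optimal
    one-to-one assignment (so at most one feature per run joins a row);
    unmatched features start new rows. Matching as many features as
    possible takes precedence over the score sum.
    """
    if not per_run_features:
        raise ValueError("at least one run is required")
    run_ids = list(per_run_features)
    rows: list[AlignedFeature] = []
    for rid in run_ids:
        feats = per_run_features[rid]
        if not feats:
            continue
        if not rows:
            assignments: dict[int, int | None] = {i: None for i in range(len(feats))}
        else:
            cost = np.full((len(feats), len(rows) + len(feats)), _FORBIDDEN)
            for i, f in enumerate(feats):
                for j, row in enumerate(rows):
                    s = _pair_score(f, row, mz_tol_da, mz_tol_ppm, rt_tol, w_mz, w_rt)
                    if np.isfinite(s):
                        cost[i, j] = s
                cost[i, len(rows) + i] = _NEW_ROW_COST
            fi, cj = linear_sum_assignment(cost)
            assignments = {}
            for i, j in zip(fi, cj):
                assignments[i] = (
                    int(j) if j < len(rows) and cost[i, j] < _NEW_ROW_COST else None
                )
        for i, f in enumerate(feats):
            j = assignments[i]
            if j is None:
                rows.append(AlignedFeature(f.mz, f.rt_apex, members={rid: f}))
            else:
                rows[j].members[rid] = f
                rows[j].refresh_consensus()
    rows.sort(key=lambda r: (r.mz, r.rt))
    return FeatureTable(run_ids, dict(groups or {}), rows, polarity)


def gap_fill(
    table: FeatureTable,
    raw_runs: dict[str, Run],
    intensity_tolerance: float = 1.0,
    min_points: int = 1,
    mz_tol_da: float = 0.002,
    mz_tol_ppm: float = 20.0,
    rt_tol: float = 0.2,
) -> FeatureTable:
    """Fill missing cells by integrating raw signal around each row.

    For a missing cell, raw points within the row's m/z tolerance and
    RT +- ``rt_tol`` are collected (most intense point per scan). From the
    local apex the window extends outward while the intensity does not rise
    by more than ``(1 + intensity_tolerance)`` fold from one point to the
    next; at least ``min_points`` points are required for a filled value.
    Detected cells are never modified; cells with no signal stay missing
    with value 0.
    """
    for row in table.rows:
        tol = mz_tolerance(row.mz, mz_tol_da, mz_tol_ppm)
        for rid in table.run_ids:
            if rid in row.members or rid in row.filled:
                continue
            run = raw_runs.get(rid)
            if run is None:
                continue
            rts, ints = [], []
            for scan in run.scans:
                if not (row.rt - rt_tol <= scan.retention_time <= row.rt + rt_tol):
                    continue
                lo = np.searchsorted(scan.mz, row.mz - tol)
                hi = np.searchsorted(scan.mz, row.mz + tol, side="right")
                if hi > lo:
                    best = lo + int(np.argmax(scan.intensity[lo:hi]))
                    rts.append(scan.retention_time)
                    ints.append(float(scan.intensity[best]))
            if not rts:
                continue
            rts_arr = np.array(rts)
            ints_arr = np.array(ints)
            apex = int(np.argmax(ints_arr))
            first = apex
            while first > 0:
                if ints_arr[first] > 0 and ints_arr[first - 1] > (
                    1.0 + intensity_tolerance
                ) * ints_arr[first]:
                    break
                first -= 1
            last = apex
            while last < len(ints_arr) - 1:
                if ints_arr[last] > 0 and ints_arr[last + 1] > (
                    1.0 + intensity_tolerance
                ) * ints_arr[last]:
                    break
                last += 1
            n_pts = last - first + 1
            if n_pts < min_points:
                continue
            if n_pts == 1:
                # a single point integrates over one median scan interval
                times = run.scan_times
                dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
                area = float(ints_arr[apex]) * dt
            else:
                area = float(
                    np.trapezoid(ints_arr[first: last + 1], rts_arr[first: last + 1])
                )
            if area > 0:
                row.filled[rid] = area
    return table


def filter_duplicates(
    table: FeatureTable,
    mz_tol_da: float = 0.002,
    mz_tol_ppm: float = 20.0,
    rt_tol: float = 0.2,
) -> FeatureTable:
    """Collapse rows lying within both tolerances of one another.

    The row with the greater total intensity wins; ties resolve to the
    lower m/z. Idempotent: after filtering no two rows remain within both
    tolerances.
    """
    totals = [sum(row.value(rid) for rid in table.run_ids) for row in table.rows]
    order = sorted(
        range(len(table.rows)),
        key=lambda i: (-totals[i], table.rows[i].mz, table.rows[i].rt),
    )
    kept: list[int] = []
    for i in order:
        row = table.rows[i]
        duplicate = False
        for j in kept:
            other = table.rows[j]
            tol = mz_tolerance(other.mz, mz_tol_da, mz_tol_ppm)
            if abs(row.mz - other.mz) <= tol and abs(row.rt - other.rt) <= rt_tol:
                duplicate = True
                break
        if not duplicate:
            kept.append(i)
    rows = [table.rows[i] for i in sorted(kept)]
    rows.sort(key=lambda r: (r.mz, r.rt))
    return FeatureTable(table.run_ids, table.groups, rows, table.polarity)
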