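"""Vector/enzyme ratio ranking and candidate calling.

The core inference of the workflow: for every aligned feature, the mean
signal in the empty-vector control is divided by the mean signal in the
enzyme reaction. Metabolites with high ratios were consumed by the enzyme
(candidate substrates); metabolites with low ratios appeared in the enzyme
arm (candidate products). A pseudocount keeps ratios finite when a product
is entirely absent from the vector group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import FeatureTable

__all__ = [
    "RatioRecord",
    "CandidateCall",
    "default_pseudocount",
    "vector_enzyme_ratio",
    "rank_ratios",
    "call_candidates",
    "permutation_pvalues",
    "ranked_to_dataframe",
]


@dataclass
class RatioRecord:
    """One row's vector/enzyme ratio and its low-to-high rank."""

    row_index: int
    mz: float
    rt: float
    mean_vector: float
    mean_enzyme: float
    ratio: float
    rank: int = 0


@dataclass
class CandidateCall:
    """A depleted (substrate) or accumulated (product) candidate."""

    row_index: int
    mz: float
    rt: float
    polarity: str
    direction: str  # "depleted" | "accumulated"
    fold: float
    ratio: float
    rank: int


def default_pseudocount(values: np.ndarray) -> float:
    """Half the smallest nonzero intensity in the table (1.0 if none)."""
    nonzero = values[values > 0]
    return float(nonzero.min()) / 2.0 if nonzero.size else 1.0


def vector_enzyme_ratio(
    mean_vector: float, mean_enzyme: float, pseudocount: float
) -> float:
    """Pseudocount-adjusted control/enzyme signal ratio."""
    return (mean_vector + pseudocount) / (mean_enzyme + pseudocount)


def rank_ratios(
    table: FeatureTable,
    pseudocount: float | None = None,
    summary: str = "mean",
) -> list[RatioRecord]:
    """Per-row group summaries and low-to-high ratio ranking.

    Group summary is the arithmetic mean of the gap-filled intensities by
    default (``summary="median"`` is available). Records are sorted by
    ascending ratio, ties broken by ascending m/z; rank 1 is the lowest
    ratio (strongest accumulation).
    """
    vec_runs = table.group_runs("vector")
    enz_runs = table.group_runs("enzyme")
    if not vec_runs or not enz_runs:
        raise ValueError("table must contain at least one run per group")
    if summary not in ("mean", "median"):
        raise ValueError(f"unknown summary {summary!r}")
    agg = np.mean if summary == "mean" else np.median
    matrix = table.intensity_matrix()
    if pseudocount is None:
        pseudocount = default_pseudocount(matrix)
    vec_idx = [table.run_ids.index(r) for r in vec_runs]
    enz_idx = [table.run_ids.index(r) for r in enz_runs]
    records = []
    for i, row in enumerate(table.rows):
        mv = float(agg(matrix[i, vec_idx]))
        me = float(agg(matrix[i, enz_idx]))
        records.append(
            RatioRecord(
                i, row.mz, row.rt, mv, me, vector_enzyme_ratio(mv, me, pseudocount)
            )
        )
    records.sort(key=lambda r: (r.ratio, r.mz))
    for rank, rec in enumerate(records, start=1):
        rec.rank = rank
    return records


def call_candidates(
    ranked: list[RatioRecord],
    fold_threshold: float = 2.0,
    polarity: str = "positive",
) -> list[CandidateCall]:
    """Threshold the ranked ratios into depleted/accumulated candidates.

    Rows with ratio >= ``fold_threshold`` are called depleted (substrates);
    rows with ratio <= ``1/fold_threshold`` are called accumulated
    (products); boundaries are inclusive. Output is ordered by effect size
    descending within each direction, depleted first.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if not ranked:
        raise ValueError("ranked record list is empty")
    depleted, accumulated = [], []
    for rec in ranked:
        if rec.ratio >= fold_threshold:
            depleted.append(
                CandidateCall(
                    rec.row_index, rec.mz, rec.rt, polarity, "depleted",
                    rec.ratio, rec.ratio, rec.rank,
                )
            )
        elif rec.ratio <= 1.0 / fold_threshold:
            accumulated.append(
                CandidateCall(
                    rec.row_index, rec.mz, rec.rt, polarity, "accumulated",
                    1.0 / rec.ratio, rec.ratio, rec.rank,
                )
            )
    depleted.sort(key=lambda c: -c.fold)
    accumulated.sort(key=lambda c: -c.fold)
    return depleted + accumulated


def permutation_pvalues(
    table: FeatureTable,
    n_permutations: int = 999,
    seed: int = 0,
    pseudocount: float | None = None,
) -> np.ndarray:
    """Optional per-row permutation p-values for |log ratio|.

    Group labels are permuted over runs; the p-value is the fraction of
    permutations whose absolute log ratio meets or exceeds the observed
    one (with the +1 correction). This is an extra beyond the plain
    ranking procedure, for users who want a significance screen.
    """
    rng = np.random.default_rng(seed)
    matrix = table.intensity_matrix()
    if pseudocount is None:
        pseudocount = default_pseudocount(matrix)
    labels = np.array([table.groups[r] for r in table.run_ids])
    vec_mask = labels == "vector"
    if vec_mask.all() or not vec_mask.any():
        raise ValueError("both groups are required")

    def log_ratios(mask: np.ndarray) -> np.ndarray:
        mv = matrix[:, mask].mean(axis=1)
        me = matrix[:, ~mask].mean(axis=1)
        return np.abs(np.log((mv + pseudocount) / (me + pseudocount)))

    observed = log_ratios(vec_mask)
    exceed = np.zeros(len(observed))
    for _ in range(n_permutations):
        perm = rng.permutation(vec_mask)
        if perm.all() or not perm.any():
            continue
        exceed += log_ratios(perm) >= observed
    return (exceed + 1.0) / (n_permutations + 1.0)


def ranked_to_dataframe(
    ranked: list[RatioRecord], calls: list[CandidateCall] | None = None
) -> pd.DataFrame:
    """Ranked ratio table with an optional call column, one row per feature."""
    call_by_row = {c.row_index: c.direction for c in calls or []}
    return pd.DataFrame(
        {
            "mz": [r.mz for r in ranked],
            "rt": [r.rt for r in ranked],
            "mean_vector": [r.mean_vector for r in ranked],
            "mean_enzyme": [r.mean_enzyme for r in ranked],
            "ratio": [r.ratio for r in ranked],
            "rank": [r.rank for r in ranked],
            "call": [call_by_row.get(r.row_index, "") for r in ranked],
        }
    )
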