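"""Apply the SGS to single-cell matrices.

The score is computed per cell with the same ssGSEA engine as the bulk
path (average-tie ranks, so the many zeros of a sparse matrix tie
deterministically; global-range normalization within the cell matrix
being scored), using risk/protective direction labels transferred from a
bulk survival screen — per-cell survival does not exist, so directions
are never re-screened on cells.  Per-patient summaries are arithmetic
means of the patient's cell scores, and patients are split high/low at
the median of those means with the same rule as the bulk path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection
from .sgs import compute_sgs, stratify_median
from .ssgsea import score_all

logger = logging.getLogger(__name__)

__all__ = ["CellScoreTable", "score_cells", "aggregate_patients"]


@dataclass
class CellScoreTable:
    """Per-cell SGS with per-patient means and high/low patient grouping."""

    cells: pd.DataFrame     # index cell id; columns patient, sgs
    patients: pd.DataFrame  # index patient id; columns mean_sgs, group
    cutoff: float

    @property
    def patient_mean_sgs(self) -> pd.Series:
        return self.patients["mean_sgs"]

    @property
    def patient_group(self) -> pd.Series:
        return self.patients["group"]


def score_cells(
    x: ExpressionMatrix,
    sets: GeneSetCollection,
    risk_sets: Sequence[str],
    protective_sets: Sequence[str] = (),
    alpha: float = 0.25,
) -> tuple[pd.Series, list[str]]:
    """Per-cell SGS.

    Cells with all-zero expression have undefined ranks and are excluded
    with a warning; returns (scores for retained cells, excluded cell ids).
    """
    totals = np.abs(x.values).sum(axis=0)
    excluded = [c for c, t in zip(x.sample_ids, totals) if t == 0]
    if excluded:
        warnings.warn(f"{len(excluded)} all-zero cell(s) excluded from scoring")
        kept = [c for c in x.sample_ids if c not in set(excluded)]
        if not kept:
            raise ValueError("no cells left after excluding all-zero cells")
        x = ExpressionMatrix(x.data[kept])
    em = score_all(x, sets, alpha=alpha, norm="global_range")
    scores = compute_sgs(em, risk_sets, protective_sets)
    scores.name = "cell_sgs"
    return scores, excluded


def aggregate_patients(
    cell_scores: pd.Series,
    cell_to_patient: Mapping[str, str] | pd.Series,
) -> CellScoreTable:
    """Mean per-patient SGS and median split of the patient means."""
    mapping = (
        cell_to_patient
        if isinstance(cell_to_patient, pd.Series)
        else pd.Series(dict(cell_to_patient))
    )
    unmapped = [c for c in cell_scores.index if c not in mapping.index]
    if unmapped:
        raise ValueError(f"cells without a patient mapping: {unmapped[:5]}")
    patients_all = mapping.unique()
    cells = pd.DataFrame(
        {"patient": mapping.reindex(cell_scores.index), "sgs": cell_scores}
    )
    means = cells.groupby("patient")["sgs"].mean()
    empty = [p for p in patients_all if p not in means.index]
    if empty:
        raise ValueError(f"patient(s) with zero retained cells: {empty}")
    table = stratify_median(means.rename("mean_sgs"))
    patients = pd.DataFrame(
        {"mean_sgs": means, "group": table.group}
    )
    return CellScoreTable(cells, patients, table.cutoff)
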