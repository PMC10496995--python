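"""The stemness-risk gene score (SGS) and median stratification.

SGS(sample) = sum of NES over risk-direction sets minus sum over
protective-direction sets.  Samples are split into high/low groups at
the cohort median (ties at the cutoff go to low — a patient exactly at
the median is not called high-risk).  A fixed cutoff can be supplied
instead to apply a training-cohort threshold to a validation cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .ssgsea import EnrichmentMatrix

__all__ = ["ScoreTable", "compute_sgs", "stratify_median", "compare_groups"]


@dataclass
class ScoreTable:
    """Per-sample SGS with the high/low grouping and the cutoff used."""

    data: pd.DataFrame  # index sample ids; columns sgs, group
    cutoff: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sgs(self) -> pd.Series:
        return self.data["sgs"]

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    def samples_in(self, group: str) -> list[str]:
        return list(self.data.index[self.data["group"] == group])


def compute_sgs(
    nes: EnrichmentMatrix | pd.DataFrame,
    risk_sets: Sequence[str],
    protective_sets: Sequence[str] = (),
) -> pd.Series:
    """Signed NES sum per sample: sum over risk sets minus sum over protective."""
    nes_df = nes.nes if isinstance(nes, EnrichmentMatrix) else nes
    risk = list(risk_sets)
    prot = list(protective_sets)
    if not risk and not prot:
        raise ValueError("need at least one risk or protective set")
    overlap = set(risk) & set(prot)
    if overlap:
        raise ValueError(f"sets listed as both risk and protective: {sorted(overlap)}")
    unknown = [s for s in risk + prot if s not in nes_df.index]
    if unknown:
        raise KeyError(f"unknown set name(s): {unknown}")
    score = nes_df.loc[risk].sum(axis=0) - nes_df.loc[prot].sum(axis=0)
    score.name = "sgs"
    return score


def stratify_median(scores: pd.Series, cutoff: float | None = None) -> ScoreTable:
    """Split samples into high (score > cutoff) and low (score <= cutoff).

    The cutoff defaults to the cohort median (mean of the middle two for
    even n).  All-identical scores cannot be stratified and raise.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; no stratification possible")
    cut = float(np.median(scores.to_numpy())) if cutoff is None else float(cutoff)
    group = pd.Series(
        np.where(scores.to_numpy() > cut, "high", "low"),
        index=scores.index,
        name="group",
    )
    if (group == "high").sum() == 0 or (group == "low").sum() == 0:
        raise ValueError("cutoff leaves one group empty")
    return ScoreTable(pd.DataFrame({"sgs": scores, "group": group}), cut)


def compare_groups(
    values: pd.Series, groups: pd.Series | Sequence[str]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) between high and low.

    Normal approximation with tie correction and continuity correction;
    returns (U statistic of the high group, p).
    """
    groups = pd.Series(groups, index=values.index) if not isinstance(groups, pd.Series) else groups
    groups = groups.reindex(values.index)
    hi = values[groups == "high"].to_numpy()
    lo = values[groups == "low"].to_numpy()
    if hi.size == 0 or lo.size == 0:
        raise ValueError("both groups must be non-empty")
    res = mannwhitneyu(hi, lo, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)
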