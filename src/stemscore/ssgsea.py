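"""Single-sample gene-set enrichment (ssGSEA) scores and cohort NES.

For one sample, genes are ranked by expression (highest → rank N,
average ranks on ties) and walked in decreasing rank order.  The
enrichment score of a set S is the summed gap between two cumulative
distributions: the in-set CDF weighted by rank**alpha and the uniform
out-of-set CDF,

    ES(S) = sum_i [ CDF_in(i) - CDF_out(i) ],
    CDF_in(i) = sum_{g in S, pos(g) <= i} r_g**alpha / sum_{g in S} r_g**alpha,
    CDF_out(i) = #{g not in S, pos(g) <= i} / (N - |S|).

Because sum_i cumsum_i(v) = sum_g v_g * (N + 1 - pos(g)), the ES has a
closed form in the walk positions, which is what `score_all` vectorizes
across sets and samples with two matrix products.  Normalized scores
(NES) divide the whole ES grid by its global range (max - min across all
sets and samples), the convention of the ssGSEA implementations this
mirrors; ``norm="none"`` keeps raw ES for oracle comparisons.

Ties (ubiquitous in sparse single-cell matrices, where most genes tie at
zero) get average ranks, and the walk order among tied genes follows a
canonical lexicographic gene order, so scores never depend on the row
order of the input matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentMatrix",
    "rank_genes",
    "enrichment_score",
    "score_all",
    "infiltration_scores",
]


@dataclass
class EnrichmentMatrix:
    """Gene sets × samples grid of raw (es) and normalized (nes) scores."""

    es: pd.DataFrame
    nes: pd.DataFrame
    alpha: float
    norm_constant: float
    norm: str = "global_range"

    def __post_init__(self) -> None:
        if self.es.shape != self.nes.shape:
            raise ValueError("es and nes must have the same shape")
        if self.norm_constant <= 0:
            raise ValueError("norm_constant must be positive")

    @property
    def set_names(self) -> list[str]:
        return list(self.es.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.es.columns)


def rank_genes(
    x: ExpressionMatrix, sample: str, tie_rule: str = "average"
) -> pd.Series:
    """Per-gene ranks in 1..N for one sample; highest expression gets rank N."""
    if sample not in x.data.columns:
        raise KeyError(f"unknown sample id {sample!r}")
    if tie_rule not in ("average", "min"):
        raise ValueError(f"tie_rule must be 'average' or 'min', got {tie_rule!r}")
    vals = x.data[sample].to_numpy()
    return pd.Series(rankdata(vals, method=tie_rule), index=x.data.index, name=sample)


def _walk_positions(ranks: np.ndarray) -> np.ndarray:
    """1-based walk positions in decreasing-rank order (stable on ties).

    ``ranks`` rows must already be in canonical gene order so that tied
    genes are walked deterministically regardless of input row order.
    Works on a genes × samples array; returns the same shape.
    """
    order = np.argsort(-ranks, axis=0, kind="stable")
    pos = np.empty_like(ranks)
    np.put_along_axis(pos, order, np.arange(1, ranks.shape[0] + 1, dtype=float)[:, None], axis=0)
    return pos


def _es_closed_form(
    ranks: np.ndarray, member: np.ndarray, alpha: float
) -> np.ndarray:
    """ES for every (set, sample) pair from ranks (genes × samples, canonical
    order) and a boolean membership matrix (sets × genes)."""
    n = ranks.shape[0]
    pos = _walk_positions(ranks)
    tail = n + 1.0 - pos                         # genes × samples
    w = ranks ** alpha
    m = member.astype(float)                      # sets × genes
    sizes = m.sum(axis=1)
    r_s = m @ w                                   # sets × samples, sum of in-set weights
    if np.any(r_s == 0):
        raise ValueError("a gene set has zero total rank weight")
    in_term = (m @ (w * tail)) / r_s
    out_term = ((1.0 - m) @ tail) / (n - sizes)[:, None]
    return in_term - out_term


def enrichment_score(
    ranks: pd.Series, gene_set: Sequence[str], alpha: float = 0.25
) -> float:
    """ES of one gene set in one ranked sample.

    Genes absent from the ranked universe are dropped from the set first;
    an empty intersection or a set covering the whole universe is an error.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    ranks = ranks.sort_index()  # canonical gene order for tie walking
    genes = ranks.index
    present = [g for g in dict.fromkeys(gene_set) if g in genes]
    if not present:
        raise ValueError(f"gene set has no overlap with the expression matrix: {list(gene_set)[:5]}")
    if len(present) >= len(genes):
        raise ValueError("gene set covers the whole gene universe")
    member = genes.isin(present)[None, :]
    es = _es_closed_form(ranks.to_numpy()[:, None], member, alpha)
    return float(es[0, 0])


def score_all(
    x: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    norm: str = "global_range",
    tie_rule: str = "average",
    min_genes: int = 2,
) -> EnrichmentMatrix:
    """ES and NES for every gene set in every sample.

    Sets with fewer than ``min_genes`` genes in the matrix are dropped with
    a warning (they are too unstable to screen).  Under ``global_range``
    normalization, ``nes = es / (max(es) - min(es))`` over the whole grid.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if norm not in ("global_range", "none"):
        raise ValueError(f"norm must be 'global_range' or 'none', got {norm!r}")
    data = x.data.sort_index()
    genes = data.index
    n = len(genes)
    kept: list[str] = []
    rows: list[np.ndarray] = []
    for name, gene_list in sets.sets.items():
        mask = genes.isin(gene_list)
        k = int(mask.sum())
        if k == 0:
            warnings.warn(f"gene set {name!r} has no overlap with the matrix; dropped")
            continue
        if k < min_genes:
            warnings.warn(
                f"gene set {name!r} has only {k} gene(s) in the matrix "
                f"(< {min_genes}); dropped"
            )
            continue
        if k >= n:
            raise ValueError(f"gene set {name!r} covers the whole gene universe")
        kept.append(name)
        rows.append(mask)
    if not kept:
        raise ValueError("no gene set overlaps the expression matrix")
    member = np.vstack(rows)
    ranks = rankdata(data.to_numpy(), method=tie_rule, axis=0)
    es = _es_closed_form(ranks, member, alpha)
    es_df = pd.DataFrame(es, index=kept, columns=x.sample_ids)
    if norm == "global_range":
        rng = float(es.max() - es.min())
        if rng == 0:
            raise ValueError("all enrichment scores identical; range normalization undefined")
        nes_df = es_df / rng
        norm_constant = rng
    else:
        nes_df = es_df.copy()
        norm_constant = 1.0
    return EnrichmentMatrix(es_df, nes_df, alpha, norm_constant, norm)


def infiltration_scores(
    x: ExpressionMatrix,
    signatures: GeneSetCollection,
    alpha: float = 0.25,
    norm: str = "global_range",
) -> EnrichmentMatrix:
    """ssGSEA infiltration scores for stromal/immune cell signatures.

    Identical contract to :func:`score_all`; kept as a named entry point
    because microenvironment signatures are scored with the same engine as
    the stemness sets.
    """
    return score_all(x, signatures, alpha=alpha, norm=norm)


def write_enrichment(em: EnrichmentMatrix, path, params=None) -> None:
    from .io import _comment_header

    hdr = dict(params or {})
    hdr.setdefault("alpha", em.alpha)
    hdr.setdefault("norm", em.norm)
    hdr.setdefault("norm_constant", em.norm_constant)
    with open(path, "w") as fh:
        fh.write(_comment_header(hdr))
        em.nes.to_csv(fh, sep="\t", index_label="set")
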