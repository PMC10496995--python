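"""Tabular containers and readers/writers for the SGS pipeline.

The pipeline touches three kinds of files: a genes × samples expression
table (TSV/CSV, continuous values such as log2(TPM+1) or microarray
intensities), gene-set collections in GMT format, and a per-sample
survival table.  Everything is validated into small dataclasses wrapping
pandas objects so downstream modules can assume clean input.

All writers emit TSV with ``#``-prefixed comment lines recording the
package version and the parameters used; readers skip such lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "SurvivalTable",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_survival",
    "write_survival",
    "tpm_transform",
    "batch_center",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples continuous expression values.

    ``data`` is a DataFrame with unique gene ids as index and unique
    sample (or cell) ids as columns; no missing values are allowed after
    construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        if self.data.shape[0] < 2 or self.data.shape[1] < 1:
            raise ValueError(
                f"expression matrix needs >=2 genes and >=1 sample, got {self.data.shape}"
            )
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.data = self.data.astype(float)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GeneSetCollection:
    """Named gene sets (order-preserving) with a provenance label."""

    sets: dict[str, list[str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            deduped = list(dict.fromkeys(genes))
            if not deduped:
                raise ValueError(f"gene set {name!r} is empty after deduplication")
            cleaned[name] = deduped
        self.sets = cleaned

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names}, self.source_label)


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time, binary event flag, optional covariates.

    Time units are whatever the caller supplied (days, months, ...) and
    are never converted internally.
    """

    data: pd.DataFrame  # index: sample ids; columns: time, event [, batch, subtype]

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValueError("duplicate sample ids in survival table")
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if (df["time"].to_numpy(dtype=float) < 0).any():
            raise ValueError("negative follow-up times")
        ev = df["event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            bad = sorted(set(ev) - {0, 1})
            raise ValueError(f"event indicator must be 0/1, found {bad}")
        df = df.copy()
        df["time"] = df["time"].astype(float)
        df["event"] = df["event"].astype(int)
        df.index.name = None
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)])


def _comment_header(params: Mapping[str, object] | None) -> str:
    lines = [f"# stemscore {__version__}"]
    for key, val in (params or {}).items():
        lines.append(f"# {key}={val}")
    return "\n".join(lines) + "\n"


def read_expression(
    path: str | Path,
    delimiter: str = "\t",
    na_policy: str = "error",
) -> ExpressionMatrix:
    """Read a genes × samples table (first column gene ids, header sample ids).

    Duplicate gene rows are collapsed by the per-sample maximum (the usual
    keep-the-highest-probeset policy for array data).  ``na_policy`` is one
    of ``error`` (default), ``drop_gene`` or ``zero``.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"empty or missing expression file: {path}")
    # check duplicate sample ids before pandas auto-renames them
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split(delimiter)
                break
    if header is None:
        raise ValueError(f"expression file has no header: {path}")
    samples = header[1:]
    if len(samples) != len(set(samples)):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dup[:5]}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    if df.empty:
        raise ValueError(f"expression file has no data rows: {path}")
    if na_policy == "error":
        if df.isna().any().any():
            raise ValueError(f"missing values in {path} (na_policy=error)")
    elif na_policy == "drop_gene":
        df = df.dropna(axis=0)
    elif na_policy == "zero":
        df = df.fillna(0.0)
    else:
        raise ValueError(f"unknown na_policy {na_policy!r}")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by max", n_dup)
        df = df.groupby(level=0, sort=False).max()
    return ExpressionMatrix(df)


def write_expression(
    x: ExpressionMatrix, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        x.data.to_csv(fh, sep="\t", index_label="gene")


def read_gmt(path: str | Path, source_label: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: ``name<tab>description<tab>gene1<tab>gene2...`` per line."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return GeneSetCollection(sets, source_label or str(path))


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.sets.items():
            fh.write("\t".join([name, sets.source_label or "na", *genes]) + "\n")


def read_survival(path: str | Path, delimiter: str = "\t") -> SurvivalTable:
    """Read a survival table with columns sample, time, event [, batch, subtype]."""
    df = pd.read_csv(path, sep=delimiter, comment="#")
    if "sample" not in df.columns:
        raise ValueError(f"survival table {path} missing 'sample' column")
    df = df.set_index("sample")
    keep = [c for c in ("time", "event", "batch", "subtype") if c in df.columns]
    return SurvivalTable(df[keep])


def write_survival(
    surv: SurvivalTable, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        surv.data.to_csv(fh, sep="\t", index_label="sample")


def tpm_transform(
    counts: ExpressionMatrix,
    gene_lengths: Mapping[str, float],
    log2: bool = False,
) -> ExpressionMatrix:
    """Convert read counts to TPM (optionally log2(TPM+1)).

    Per sample: ``rate_g = count_g / length_kb_g``; ``TPM_g = 1e6 * rate_g /
    sum(rates)``.  Columns of the output sum to 1e6 before log transform.
    """
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ValueError(f"missing gene lengths for: {missing[:10]}")
    lengths_kb = np.array([gene_lengths[g] for g in counts.gene_ids], dtype=float) / 1e3
    if (lengths_kb <= 0).any():
        raise ValueError("gene lengths must be positive")
    rates = counts.values / lengths_kb[:, None]
    totals = rates.sum(axis=0)
    zero_cols = [s for s, t in zip(counts.sample_ids, totals) if t == 0]
    if zero_cols:
        raise ValueError(f"all-zero samples: {zero_cols}")
    tpm = 1e6 * rates / totals[None, :]
    if log2:
        tpm = np.log2(tpm + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.gene_ids, columns=counts.sample_ids)
    )


def batch_center(x: ExpressionMatrix, batch: Sequence[str] | pd.Series) -> ExpressionMatrix:
    """Remove additive per-gene batch shifts by exact mean-centering.

    Per gene, each sample's batch mean is subtracted and the unweighted mean
    of the batch means is added back, so that after the operation every
    batch has the same per-gene mean while within-batch variation is
    untouched.  Intended for merging cohorts measured on log-scale values.
    """
    if isinstance(batch, pd.Series):
        batch = batch.reindex(x.sample_ids)
        if batch.isna().any():
            raise ValueError("every sample needs a batch label")
        labels = batch.to_numpy()
    else:
        labels = np.asarray(list(batch))
        if labels.shape[0] != x.n_samples:
            raise ValueError(
                f"{labels.shape[0]} batch labels for {x.n_samples} samples"
            )
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("batch centering needs >=2 batches")
    counts = np.bincount(inv)
    if (counts == 0).any():
        raise ValueError("batch with zero samples")
    vals = x.values
    # per-gene per-batch means: genes × batches
    sums = np.zeros((vals.shape[0], uniq.size))
    np.add.at(sums.T, inv, vals.T)
    means = sums / counts[None, :]
    grand = means.mean(axis=1)  # unweighted mean of batch means
    centered = vals - means[:, inv] + grand[:, None]
    return ExpressionMatrix(
        pd.DataFrame(centered, index=x.gene_ids, columns=x.sample_ids)
    )
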