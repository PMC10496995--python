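"""End-to-end orchestration: enrich → screen → score → stratify → survdiff.

`run_pipeline` drives the whole SGS construction from one config: ssGSEA
NES of every gene set in every sample, univariate Cox screening against
overall survival, the signed SGS combination over retained sets, the
median (or fixed-cutoff) split, and the Kaplan-Meier / log-rank
comparison of the two groups.  It writes nes.tsv, screen.tsv,
scores.tsv, km.tsv and a manifest.json with versions, parameters, input
checksums and the retained sets; any stage failure aborts with the stage
name and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .coxscreen import screen_gene_sets, screen_to_frame
from .io import (
    read_expression,
    read_gmt,
    read_survival,
    _comment_header,
)
from .sgs import compute_sgs, stratify_median
from .ssgsea import score_all, write_enrichment
from .survival import km_estimate, logrank_test, write_km_curves

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    expression: str
    gmt: str
    survival: str
    out_dir: str
    alpha: float = 0.25
    norm: str = "global_range"
    p_threshold: float = 0.05
    ties: str = "efron"
    cutoff: str | float = "median"   # "median" or a fixed numeric cutoff
    delimiter: str = "\t"
    na_policy: str = "error"
    seed: int = 0

    def validate(self) -> None:
        for name in ("expression", "gmt", "survival"):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"{name} path does not exist: {path}")
        if self.cutoff != "median" and not isinstance(self.cutoff, (int, float)):
            raise ValueError("cutoff must be 'median' or a number")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full SGS pipeline; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = _time.time()
    params = {
        "alpha": config.alpha,
        "norm": config.norm,
        "p_threshold": config.p_threshold,
        "ties": config.ties,
        "cutoff": config.cutoff,
        "seed": config.seed,
    }

    def _emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        stage = "load"
        expr = read_expression(config.expression, delimiter=config.delimiter,
                               na_policy=config.na_policy)
        sets = read_gmt(config.gmt)
        surv = read_survival(config.survival)
        missing = [s for s in surv.sample_ids if s not in set(expr.sample_ids)]
        if missing:
            logger.warning("%d survival samples absent from expression matrix: %s",
                           len(missing), missing[:5])

        stage = "enrich"
        em = score_all(expr, sets, alpha=config.alpha, norm=config.norm)
        write_enrichment(em, _emit(out / "nes.tsv"), params)

        stage = "screen"
        results = screen_gene_sets(em, surv, p_threshold=config.p_threshold,
                                   ties=config.ties)
        frame = screen_to_frame(results)
        with open(_emit(out / "screen.tsv"), "w") as fh:
            fh.write(_comment_header(params))
            frame.to_csv(fh, sep="\t")
        risk = [r.set_name for r in results if r.direction == "risk"]
        protective = [r.set_name for r in results if r.direction == "protective"]

        stage = "score"
        sgs = compute_sgs(em, risk, protective)
        cutoff = None if config.cutoff == "median" else float(config.cutoff)
        table = stratify_median(sgs, cutoff=cutoff)
        with open(_emit(out / "scores.tsv"), "w") as fh:
            fh.write(_comment_header({**params, "cutoff_value": table.cutoff}))
            table.data.to_csv(fh, sep="\t", index_label="sample")

        stage = "survdiff"
        shared = [s for s in table.sample_ids if s in set(surv.sample_ids)]
        sub = surv.subset(shared)
        groups = table.group.loc[shared]
        chi2, p = logrank_test(sub, groups)
        curves = []
        for name in ("high", "low"):
            ids = [s for s in shared if groups.loc[s] == name]
            curves.append(km_estimate(sub.subset(ids), label=name))
        write_km_curves(curves, _emit(out / "km.tsv"), params)

        stage = "manifest"
        manifest = {
            "stemscore_version": __version__,
            "parameters": params,
            "inputs": {
                name: {"path": str(getattr(config, name)),
                       "sha256": _sha256(getattr(config, name))}
                for name in ("expression", "gmt", "survival")
            },
            "n_genes": expr.n_genes,
            "n_samples": expr.n_samples,
            "n_sets_scored": len(em.set_names),
            "norm_constant": em.norm_constant,
            "risk_sets": risk,
            "protective_sets": protective,
            "cutoff": table.cutoff,
            "n_high": len(table.samples_in("high")),
            "n_low": len(table.samples_in("low")),
            "logrank_chi2": chi2,
            "logrank_p": p,
            "elapsed_s": round(_time.time() - t0, 3),
        }
        with open(_emit(out / "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        logger.info("pipeline finished in %.1fs; log-rank p = %.3g",
                    manifest["elapsed_s"], p)
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
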