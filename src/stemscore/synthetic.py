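"""Synthetic cohorts with planted gene-set activity driving survival.

The generator emulates the statistical structure the SGS pipeline
assumes, with full ground truth:

* each gene set k has a latent per-sample activity a_{k,s} ~ Normal(0,1);
* expression is x_{g,s} = mu_g + signal_strength * sum_{k: g in S_k} a_{k,s}
  + Normal(0, noise_sd), with baseline mu_g ~ Normal(6, 2) (a log2-like
  scale); overlapping sets contribute additively;
* survival follows a proportional-hazards exponential model,
  T_s ~ Exp(lambda0 * exp(sum_k beta_k a_{k,s})), so the Cox screen's
  model is exactly right by construction;
* censoring is an independent exponential whose rate is solved (1-D root
  find) so the expected censored fraction hits the target;
* single-cell mode draws per-patient activities (optionally shifted),
  adds per-cell noise and applies Bernoulli dropout.

Everything is driven by one integer seed through a single
``numpy.random.default_rng`` stream; no global state is touched, and the
same (parameters, seed) pair reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ExpressionMatrix, GeneSetCollection, SurvivalTable

__all__ = [
    "SyntheticTruth",
    "random_gene_sets",
    "generate_bulk",
    "generate_single_cell",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    set_effects: dict[str, float]          # true log-hazard coefficient per set
    activities: pd.DataFrame               # samples/patients × sets latent factors
    baseline_hazard: float
    censor_rate: float | None
    seed: int
    censor_hazard: float | None = None
    patient_shifts: dict[str, float] = field(default_factory=dict)


def random_gene_sets(
    gene_ids: Sequence[str],
    n_sets: int,
    set_size: int,
    seed: int = 0,
    prefix: str = "SET",
) -> GeneSetCollection:
    """Build ``n_sets`` sets of ``set_size`` genes over ``gene_ids``.

    When the sets fit disjointly they partition a shuffled gene list
    (cleanest for calibration studies); otherwise each set is an
    independent random draw and sets may overlap.
    """
    genes = list(gene_ids)
    rng = np.random.default_rng(seed)
    width = len(str(n_sets))
    if n_sets * set_size <= len(genes):
        shuffled = list(rng.permutation(genes))
        sets = {
            f"{prefix}{i + 1:0{width}d}": shuffled[i * set_size : (i + 1) * set_size]
            for i in range(n_sets)
        }
    else:
        sets = {
            f"{prefix}{i + 1:0{width}d}": list(rng.choice(genes, set_size, replace=False))
            for i in range(n_sets)
        }
    return GeneSetCollection(sets, source_label="synthetic")


def _membership(gene_ids: Sequence[str], sets: GeneSetCollection) -> np.ndarray:
    idx = {g: i for i, g in enumerate(gene_ids)}
    member = np.zeros((len(gene_ids), len(sets)), dtype=float)
    for j, (name, genes) in enumerate(sets.sets.items()):
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValueError(f"set {name!r} has genes outside the universe: {missing[:5]}")
        member[[idx[g] for g in genes], j] = 1.0
    return member


def _calibrate_censor_hazard(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate with expected censored fraction = target.

    P(censor | hazard lam, censor rate c) = c / (c + lam) for independent
    exponentials; the expectation over the cohort's hazards is monotone in
    c, so a bracketing root find is exact.
    """

    def frac(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - target

    lo = np.log(hazards.min()) - 25.0
    hi = np.log(hazards.max()) + 25.0
    return float(np.exp(brentq(frac, lo, hi, xtol=1e-12)))


def generate_bulk(
    n_samples: int = 200,
    n_genes: int = 1000,
    sets: GeneSetCollection | None = None,
    effects: Mapping[str, float] | None = None,
    signal_strength: float = 1.0,
    noise_sd: float = 1.0,
    censor_rate: float = 0.3,
    baseline_hazard: float = 0.1,
    seed: int = 0,
    n_sets: int = 36,
    set_size: int = 25,
) -> tuple[ExpressionMatrix, SurvivalTable, SyntheticTruth]:
    """Simulate a bulk cohort with planted set activities and survival.

    ``effects`` maps set names to true log-hazard coefficients (missing
    sets get 0, i.e. null).  When ``sets`` is omitted, ``n_sets`` disjoint
    sets of ``set_size`` genes are drawn from the same seed.
    """
    if not (0.0 < censor_rate < 1.0):
        raise ValueError("censor_rate must be strictly between 0 and 1")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    samples = [f"s{i + 1:05d}" for i in range(n_samples)]
    if sets is None:
        sets = random_gene_sets(genes, n_sets, set_size, seed=seed)
    member = _membership(genes, sets)  # genes × sets
    effects = dict(effects or {})
    unknown = [k for k in effects if k not in sets.sets]
    if unknown:
        raise KeyError(f"effects refer to unknown sets: {unknown}")
    beta = np.array([effects.get(name, 0.0) for name in sets.names])

    mu = rng.normal(6.0, 2.0, size=n_genes)
    activities = rng.standard_normal((len(sets), n_samples))  # sets × samples
    noise = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    expr = mu[:, None] + signal_strength * (member @ activities) + noise

    hazards = baseline_hazard * np.exp(beta @ activities)
    death = rng.exponential(1.0 / hazards)
    c_rate = _calibrate_censor_hazard(hazards, censor_rate)
    censor = rng.exponential(1.0 / c_rate, size=n_samples)
    event = (death <= censor).astype(int)
    time = np.minimum(death, censor)

    xmat = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))
    surv = SurvivalTable(
        pd.DataFrame({"time": time, "event": event}, index=pd.Index(samples, name="sample"))
    )
    truth = SyntheticTruth(
        set_effects={name: float(effects.get(name, 0.0)) for name in sets.names},
        activities=pd.DataFrame(activities.T, index=samples, columns=sets.names),
        baseline_hazard=baseline_hazard,
        censor_rate=censor_rate,
        seed=seed,
        censor_hazard=c_rate,
    )
    return xmat, surv, truth


def generate_single_cell(
    n_patients: int = 4,
    cells_per_patient: int = 100,
    sets: GeneSetCollection | None = None,
    patient_effects: Mapping[str, float] | None = None,
    dropout_rate: float = 0.5,
    seed: int = 0,
    n_genes: int = 1000,
    n_sets: int = 6,
    set_size: int = 25,
    signal_strength: float = 1.0,
    noise_sd: float = 1.0,
    activity_sd: float = 0.0,
    shifted_sets: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, pd.Series, SyntheticTruth]:
    """Simulate a sparse gene × cell matrix with per-patient activity shifts.

    ``patient_effects`` maps patient id to the latent activity of
    ``shifted_sets`` (all sets by default), so a higher planted shift
    always means a higher expected per-cell score; ``activity_sd`` adds
    optional random patient-level heterogeneity on top.  At dropout 0 the
    per-cell model reduces to the bulk generator's.  Returns the cell
    matrix, a cell → patient map and the ground truth.
    """
    if cells_per_patient < 2:
        raise ValueError("cells_per_patient must be >= 2")
    if not (0.0 <= dropout_rate < 1.0):
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    if sets is None:
        sets = random_gene_sets(genes, n_sets, set_size, seed=seed)
    member = _membership(genes, sets)
    if patient_effects:
        patients = list(patient_effects)
        shifts = np.array([patient_effects[p] for p in patients], dtype=float)
    else:
        patients = [f"p{i + 1:03d}" for i in range(n_patients)]
        shifts = np.zeros(len(patients))
    shifted = list(shifted_sets) if shifted_sets is not None else sets.names
    unknown = [s for s in shifted if s not in sets.sets]
    if unknown:
        raise KeyError(f"shifted_sets refer to unknown sets: {unknown}")
    shift_mask = np.array([1.0 if name in shifted else 0.0 for name in sets.names])

    mu = rng.normal(6.0, 2.0, size=n_genes)
    # patient-level latent activities: the planted shift for designated
    # sets, plus optional random patient heterogeneity
    activities = activity_sd * rng.standard_normal((len(sets), len(patients)))
    activities += shift_mask[:, None] * shifts[None, :]

    cells, cell_patient = [], []
    for j, p in enumerate(patients):
        for c in range(cells_per_patient):
            cells.append(f"{p}_c{c + 1:04d}")
            cell_patient.append(p)
    patient_idx = np.array([patients.index(p) for p in cell_patient])

    signal = mu[:, None] + signal_strength * (member @ activities)  # genes × patients
    expr = signal[:, patient_idx] + rng.normal(0.0, noise_sd, size=(n_genes, len(cells)))
    if dropout_rate > 0:
        keep = rng.random(expr.shape) >= dropout_rate
        expr = expr * keep

    xmat = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=cells))
    mapping = pd.Series(cell_patient, index=cells, name="patient")
    truth = SyntheticTruth(
        set_effects={name: 0.0 for name in sets.names},
        activities=pd.DataFrame(activities.T, index=patients, columns=sets.names),
        baseline_hazard=0.0,
        censor_rate=None,
        seed=seed,
        patient_shifts={p: float(s) for p, s in zip(patients, shifts)},
    )
    return xmat, mapping, truth
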