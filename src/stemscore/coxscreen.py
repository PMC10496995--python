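"""Univariate Cox proportional-hazards screening of gene-set NES values.

Each gene set's normalized enrichment score is regressed against overall
survival one set at a time.  The partial likelihood is maximized by
Newton-Raphson from beta = 0 with the Efron tie correction (Breslow
available for cross-checks); the standard error comes from the observed
information and the p-value is the two-sided Wald test.  Sets with
p below the threshold are retained and labelled by hazard direction:
HR = exp(beta) > 1 -> risk, HR < 1 -> protective; everything else is
dropped.  Fits whose coefficient diverges (monotone likelihood) are
flagged non-converged and dropped rather than clamped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm as normal

from .io import SurvivalTable
from .ssgsea import EnrichmentMatrix

logger = logging.getLogger(__name__)

__all__ = ["CoxFit", "ScreenResult", "fit_cox_univariate", "screen_gene_sets"]


@dataclass
class CoxFit:
    beta: float
    se: float
    wald_p: float
    converged: bool
    n_used: int
    n_events: int

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class ScreenResult:
    set_name: str
    beta: float
    hr: float
    se: float
    wald_p: float
    direction: str  # risk | protective | dropped
    n_used: int


def _partial_likelihood_quantities(
    beta: float,
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str,
) -> tuple[float, float, float]:
    """(log partial likelihood, score U, information I) at beta.

    Inputs must be sorted by ascending time.  Subjects censored exactly at
    an event time stay in the risk set for that time.  With Efron ties the
    l-th of d tied events sees the denominator S0_risk - (l/d) * S0_ties.
    """
    ebx = np.exp(beta * x)
    s0 = np.cumsum(ebx[::-1])[::-1]
    s1 = np.cumsum((x * ebx)[::-1])[::-1]
    s2 = np.cumsum((x * x * ebx)[::-1])[::-1]

    ev = event.astype(bool)
    et, ex, eebx = time[ev], x[ev], ebx[ev]
    uniq, start = np.unique(et, return_index=True)
    d = np.diff(np.append(start, et.size))
    first = np.searchsorted(time, uniq, side="left")

    s0r, s1r, s2r = s0[first], s1[first], s2[first]
    s0t = np.add.reduceat(eebx, start)
    s1t = np.add.reduceat(ex * eebx, start)
    s2t = np.add.reduceat(ex * ex * eebx, start)

    g = np.repeat(np.arange(uniq.size), d)
    if ties == "efron":
        frac = (np.arange(et.size) - start[g]) / d[g]
    elif ties == "breslow":
        frac = np.zeros(et.size)
    else:
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")

    den = s0r[g] - frac * s0t[g]
    num1 = s1r[g] - frac * s1t[g]
    num2 = s2r[g] - frac * s2t[g]
    loglik = float(beta * ex.sum() - np.log(den).sum())
    score = float(ex.sum() - (num1 / den).sum())
    info = float((num2 / den - (num1 / den) ** 2).sum())
    return loglik, score, info


def fit_cox_univariate(
    covariate: np.ndarray,
    surv: SurvivalTable,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
    beta_bound: float = 15.0,
) -> CoxFit:
    """Fit a one-covariate Cox model by damped Newton-Raphson from beta=0.

    Convergence when |delta beta| < ``tol``; |beta| drifting past
    ``beta_bound`` marks a monotone (separating) likelihood and the fit is
    flagged non-converged.
    """
    x = np.asarray(covariate, dtype=float)
    if x.shape[0] != len(surv.sample_ids):
        raise ValueError("covariate length does not match survival table")
    if surv.n_events < 2:
        raise ValueError("need at least 2 events for Cox screening")
    order = np.argsort(surv.time, kind="stable")
    xs, ts, es = x[order], surv.time[order], surv.event[order]
    at_risk_ok = np.ptp(xs) > 0
    if not at_risk_ok:
        raise ValueError("constant covariate; Cox coefficient undefined")

    beta = 0.0
    ll, u, info = _partial_likelihood_quantities(beta, xs, ts, es, ties)
    converged = False
    for _ in range(max_iter):
        if info <= 0 or not np.isfinite(info):
            break
        step = u / info
        # damped update: halve until the partial likelihood does not drop
        for _ in range(30):
            cand = beta + step
            ll_new, u_new, info_new = _partial_likelihood_quantities(
                cand, xs, ts, es, ties
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, u, info = cand, ll_new, u_new, info_new
        if abs(beta) > beta_bound:
            break
        if abs(step) < tol:
            converged = True
            break
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    wald_p = float(2.0 * normal.sf(abs(beta) / se)) if se == se and se > 0 else float("nan")
    return CoxFit(
        beta=float(beta),
        se=se,
        wald_p=wald_p,
        converged=converged,
        n_used=int(xs.size),
        n_events=int(es.sum()),
    )


def screen_gene_sets(
    nes: EnrichmentMatrix | pd.DataFrame,
    surv: SurvivalTable,
    p_threshold: float = 0.05,
    ties: str = "efron",
    require_retained: bool = True,
) -> list[ScreenResult]:
    """Screen every gene set's NES against survival; label retained sets.

    Samples missing from either table are dropped listwise (counts
    logged).  A retained set is ``risk`` when HR > 1 and ``protective``
    when HR < 1; with a Wald p below threshold an HR of exactly 1 cannot
    occur.  With ``require_retained`` (the default) an empty retained list
    raises, advising a larger cohort or threshold; calibration studies
    counting retained sets across null replicates disable it.
    """
    nes_df = nes.nes if isinstance(nes, EnrichmentMatrix) else nes
    shared = [s for s in nes_df.columns if s in set(surv.sample_ids)]
    n_drop = nes_df.shape[1] - len(shared)
    if n_drop:
        logger.info("dropping %d samples without survival data", n_drop)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} samples shared between NES and survival (<10)")
    sub = surv.subset(shared)
    if sub.n_events < 2:
        raise ValueError("fewer than 2 events among shared samples")

    results: list[ScreenResult] = []
    for name, row in nes_df[shared].iterrows():
        try:
            fit = fit_cox_univariate(row.to_numpy(), sub, ties=ties)
        except ValueError as exc:
            warnings.warn(f"set {name!r} not screenable: {exc}")
            results.append(
                ScreenResult(name, float("nan"), float("nan"), float("nan"),
                             float("nan"), "dropped", len(shared))
            )
            continue
        if not fit.converged:
            warnings.warn(f"set {name!r}: Cox fit did not converge; dropped")
            direction = "dropped"
        elif fit.wald_p < p_threshold:
            direction = "risk" if fit.hr > 1 else "protective"
        else:
            direction = "dropped"
        results.append(
            ScreenResult(name, fit.beta, fit.hr, fit.se, fit.wald_p,
                         direction, fit.n_used)
        )
    retained = [r for r in results if r.direction != "dropped"]
    if require_retained and not retained:
        raise ValueError(
            "no gene set passed the survival screen; consider a larger cohort "
            "or a more permissive p threshold"
        )
    return results


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "beta": [r.beta for r in results],
            "HR": [r.hr for r in results],
            "SE": [r.se for r in results],
            "p": [r.wald_p for r in results],
            "direction": [r.direction for r in results],
            "n": [r.n_used for r in results],
        }
    ).set_index("set")
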