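"""Kaplan-Meier estimation and two-group log-rank comparison.

Thin, validated wrappers around lifelines: the product-limit estimator
(subjects censored at an event time remain at risk for that time) and
the standard log-rank test with the hypergeometric variance and no
continuity correction.  A small matplotlib step-plot writer renders the
usual survival figure with censoring ticks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io import SurvivalTable

__all__ = ["KMCurve", "km_estimate", "logrank_test", "km_plot", "write_km_curves"]


@dataclass
class KMCurve:
    """Step representation of a Kaplan-Meier estimate at the event times."""

    event_times: np.ndarray   # increasing distinct times with >=1 event
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray       # n at risk at each event time
    n_events: np.ndarray      # d events at each event time
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.survival.size and self.survival[0] > 1 + 1e-12:
            raise ValueError("survival cannot exceed 1")


def km_estimate(surv: SurvivalTable, label: str = "") -> KMCurve:
    """Product-limit survival estimate S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    if len(surv.sample_ids) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    sf = kmf.survival_function_["KM_estimate"]
    survival = sf.loc[ev.index].to_numpy(dtype=float)
    cens = tbl[tbl["censored"] > 0].index.to_numpy(dtype=float)
    return KMCurve(
        event_times=times,
        survival=survival,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        censor_times=cens,
        label=label,
    )


def logrank_test(
    surv: SurvivalTable, groups: pd.Series | Sequence[str]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p, df=1)."""
    groups = (
        groups.reindex(surv.sample_ids)
        if isinstance(groups, pd.Series)
        else pd.Series(list(groups), index=surv.sample_ids)
    )
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    mask = (groups == labels[0]).to_numpy()
    if mask.all() or not mask.any():
        raise ValueError("one group is empty")
    ev = surv.event
    if ev[mask].sum() + ev[~mask].sum() < 1:
        raise ValueError("no events in either group")
    res = _ll_logrank(
        surv.time[mask], surv.time[~mask], ev[mask], ev[~mask]
    )
    return float(res.test_statistic), float(res.p_value)


def km_plot(
    curves: Sequence[KMCurve],
    labels: Sequence[str] | None = None,
    path: str | Path = "km.png",
) -> Path:
    """Write a step plot of one or more KM curves with censoring ticks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not curves:
        raise ValueError("no curves to plot")
    labels = list(labels) if labels is not None else [c.label or f"group {i}" for i, c in enumerate(curves)]
    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, lab in zip(curves, labels):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=lab)
        if curve.censor_times.size:
            s_at = np.array(
                [s[np.searchsorted(t, ct, side="right") - 1] for ct in curve.censor_times]
            )
            ax.plot(curve.censor_times, s_at, "|", color="k", markersize=6)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_km_curves(curves: Sequence[KMCurve], path: str | Path, params=None) -> None:
    from .io import _comment_header

    frames = []
    for curve in curves:
        frames.append(
            pd.DataFrame(
                {
                    "time": curve.event_times,
                    "survival": curve.survival,
                    "at_risk": curve.at_risk,
                    "events": curve.n_events,
                    "group": curve.label,
                }
            )
        )
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        pd.concat(frames).to_csv(fh, sep="\t", index=False)
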