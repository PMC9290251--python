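"""Outcome association: Kaplan-Meier estimation, log-rank tests and Cox
proportional-hazards fits for epi-cluster labels.

Follow-up times are in months. Ties between events and censorings at the
same time are handled events-first in the product-limit estimator, and the
Cox partial likelihood uses the Efron approximation for tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test


@dataclass
class KMEstimate:
    """Product-limit survival estimate for one group."""

    times: np.ndarray        # distinct observed times (events and censorings)
    at_risk: np.ndarray      # number at risk just before each time
    survival: np.ndarray     # S(t) at each time
    group: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function lookup S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Per-covariate hazard-ratio estimates with 95% Wald intervals."""

    summary: pd.DataFrame    # columns: coef, hr, ci_low, ci_high, pvalue
    converged: bool
    n_events: int


def km_estimate(time, event, group: str = "") -> KMEstimate:
    """Kaplan-Meier product-limit estimate from times and event flags."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tab = kmf.event_table
    obs = (tab["removed"] > 0).to_numpy()  # rows at actual observation times
    surv = kmf.survival_function_["KM_estimate"].reindex(tab.index)
    return KMEstimate(times=tab.index.to_numpy(dtype=float)[obs],
                      at_risk=tab["at_risk"].to_numpy()[obs],
                      survival=surv.to_numpy(dtype=float)[obs],
                      group=group)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels.size}")
    for g in labels:
        if (group == g).sum() == 0 or event[group == g].sum() == 0:
            raise ValueError(f"group {g!r} has no events")
    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str,
            covariates: list[str] | None = None) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Newton iterations).

    ``covariates`` defaults to every column other than the duration and
    event columns; all covariates must be numeric or binary-encoded.
    """
    if covariates is None:
        covariates = [c for c in df.columns if c not in (duration_col, event_col)]
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise ValueError("no events in survival data")
    sub = df[[duration_col, event_col] + covariates]
    cph = CoxPHFitter()
    converged = True
    try:
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except ConvergenceError:
        converged = False
        cph.fit(sub, duration_col=duration_col, event_col=event_col,
                fit_options={"step_size": 0.1, "max_steps": 500})
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "pvalue": s["p"],
    })
    return CoxFit(summary=summary, converged=converged, n_events=n_events)


def truncate_followup(df: pd.DataFrame, months: float, duration_col: str,
                      event_col: str) -> pd.DataFrame:
    """Administrative censoring at a fixed follow-up horizon."""
    out = df.copy()
    over = out[duration_col] > months
    out.loc[over, duration_col] = months
    out.loc[over, event_col] = 0
    return out


def univariate_screen(df: pd.DataFrame, duration_col: str, event_col: str,
                      covariates: list[str], p_threshold: float = 0.05
                      ) -> list[str]:
    """Univariate Cox screen: covariates with Wald p below the threshold.

    The selected covariates are the conventional candidates for a
    subsequent multivariate fit.
    """
    selected = []
    for cov in covariates:
        fit = cox_fit(df.dropna(subset=[cov]), duration_col, event_col, [cov])
        if fit.summary.loc[cov, "pvalue"] < p_threshold:
            selected.append(cov)
    return selected
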