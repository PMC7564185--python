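"""Survival analysis for the dichotomized cohorts.

Kaplan–Meier product-limit curves, the two-group log-rank test, and Cox
proportional-hazards regression (Efron tie handling, Wald confidence
intervals on the hazard-ratio scale) — the estimators used to ask whether
signature-low patients die earlier and whether the group indicator survives
adjustment for clinical covariates such as AFP and tumor stage.

The numerical machinery is lifelines; this module owns input validation,
the tabular result containers, and the TSV exports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ConvergenceError, InvalidArgumentError


def _check_times(time: pd.Series, event: pd.Series) -> None:
    if len(time) == 0:
        raise InvalidArgumentError("no survival records")
    t = time.to_numpy(dtype=float)
    if not np.all(t > 0):
        raise InvalidArgumentError("survival times must be strictly positive")
    e = event.to_numpy(dtype=float)
    if not np.isin(e, (0.0, 1.0)).all():
        raise InvalidArgumentError("event indicator must be 0 or 1")


@dataclass
class KMCurve:
    """Product-limit estimate: survival after each distinct event time."""

    event_times: np.ndarray   # ascending distinct event times
    survival: np.ndarray      # S(t) just after each event time, non-increasing
    at_risk: np.ndarray       # number at risk just before each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"time": self.event_times, "survival": self.survival,
                      "at_risk": self.at_risk}).to_csv(
            path, sep="\t", index=False, float_format="%.10g")


def km_estimate(time: pd.Series, event: pd.Series) -> KMCurve:
    """Kaplan–Meier estimator; censored times shrink the risk set without steps."""
    _check_times(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time.astype(float), event_observed=event.astype(int))
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = np.asarray([kmf.survival_function_at_times(t).iloc[0] for t in times])
    return KMCurve(event_times=times, survival=surv,
                   at_risk=ev["at_risk"].to_numpy(dtype=float))


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    df: int = 1


def logrank_test(time: pd.Series, event: pd.Series, groups: pd.Series) -> LogRankResult:
    """Two-group log-rank test (hypergeometric variance, chi-square df=1)."""
    _check_times(time, event)
    groups = groups.astype(str)
    names = sorted(groups.unique())
    if len(names) != 2:
        raise InvalidArgumentError(f"log-rank needs exactly 2 non-empty groups, got {names}")
    in_a = groups == names[0]
    res = _ll_logrank(time[in_a], time[~in_a],
                      event_observed_A=event[in_a], event_observed_B=event[~in_a])
    return LogRankResult(statistic=float(res.test_statistic),
                         p_value=float(res.p_value))


@dataclass
class CoxFit:
    """Per-covariate hazard ratios with 95% Wald intervals."""

    table: pd.DataFrame  # index: covariate; columns: coef, hr, ci_lower, ci_upper, p_value
    converged: bool
    tie_method: str = "Efron"

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="covariate",
                          float_format="%.10g")


def cox_fit(clinical: pd.DataFrame, covariates: list[str],
            time_col: str = "time", event_col: str = "event") -> CoxFit:
    """Multivariate Cox regression via partial-likelihood maximization.

    Efron tie handling; 95% CI = exp(coef +/- 1.96 SE). Constant covariates
    and n <= p are rejected up front; lifelines convergence failures are
    re-raised as :class:`ConvergenceError` with the original diagnostics.
    """
    _check_times(clinical[time_col], clinical[event_col])
    for cov in covariates:
        if cov not in clinical.columns:
            raise InvalidArgumentError(f"covariate {cov!r} not in clinical table")
        if clinical[cov].nunique() < 2:
            raise InvalidArgumentError(f"covariate {cov!r} is constant")
    if len(clinical) <= len(covariates):
        raise InvalidArgumentError("need more samples than covariates")

    df = clinical[[time_col, event_col, *covariates]].astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError/Warning subclasses
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc

    summary = cph.summary
    table = pd.DataFrame({
        "coef": summary["coef"],
        "hr": summary["exp(coef)"],
        "ci_lower": summary["exp(coef) lower 95%"],
        "ci_upper": summary["exp(coef) upper 95%"],
        "p_value": summary["p"],
    })
    table.index.name = "covariate"
    return CoxFit(table=table, converged=True)
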