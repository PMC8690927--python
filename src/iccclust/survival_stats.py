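"""Kaplan-Meier estimation, log-rank comparison and Cox proportional hazards.

Thin, contract-checked wrappers around lifelines: the product-limit curve
with its median (smallest time where survival drops to 0.5 or below), the
k-sample log-rank chi-square test over pooled event times, and a Cox
partial-likelihood fit with Efron tie handling reporting hazard ratios with
95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import ConvergenceError as _LifelinesConvergenceError

from .errors import ConvergenceError, UndefinedMetricError, ValidationError


def _check_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.size == 0:
        raise ValidationError("need at least one record")
    if (time < 0).any():
        raise ValidationError("times must be non-negative")
    if not np.isin(event, (0.0, 1.0)).all():
        raise ValidationError("event flags must be 0/1")
    return time, event.astype(int)


def km_curve(time, event) -> tuple[pd.DataFrame, float]:
    """Product-limit survival curve and median survival.

    Returns ``(curve, median)`` where ``curve`` has columns ``time`` and
    ``survival`` (step values at the observed times, including t=0) and the
    median is the smallest time with S(t) <= 0.5, NaN when never reached.
    """
    time, event = _check_survival(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    curve = pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})
    reached = curve[curve["survival"] <= 0.5]
    median = float(reached["time"].iloc[0]) if len(reached) else float("nan")
    return curve, median


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int


def logrank(time, event, group) -> LogrankResult:
    """k-sample log-rank test (observed minus expected over pooled event times)."""
    time, event = _check_survival(time, event)
    group = np.asarray(group)
    if len(group) != len(time):
        raise ValidationError("group labels must match the records")
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    if event.sum() == 0:
        raise UndefinedMetricError("log-rank test undefined with no events")
    res = multivariate_logrank_test(time, group, event)
    return LogrankResult(float(res.test_statistic), float(res.p_value), len(levels) - 1)


def km_by_group(data: pd.DataFrame, time_col: str, event_col: str, group_col: str) -> dict[str, tuple[pd.DataFrame, float]]:
    """Kaplan-Meier curve and median per group label."""
    out = {}
    for level, sub in data.groupby(group_col, observed=True):
        out[str(level)] = km_curve(sub[time_col], sub[event_col])
    return out


def cox_fit(
    data: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties); hazard ratios with 95% CIs.

    Rows with any missing value in the used columns are dropped.  Degenerate
    covariates (constant, or perfectly separating) raise
    :class:`~iccclust.errors.ConvergenceError`.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (duration_col, event_col)]
    if not covariates:
        raise ValidationError("no covariates to fit")
    cols = [duration_col, event_col, *covariates]
    df = data[cols].dropna().copy()
    _check_survival(df[duration_col], df[event_col])
    n_events = int(df[event_col].sum())
    if n_events < len(covariates) + 1:
        raise ValidationError(f"{n_events} events cannot support {len(covariates)} covariates")
    for cov in covariates:
        if df[cov].nunique() < 2:
            raise ConvergenceError(f"covariate {cov!r} is constant")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except (_LifelinesConvergenceError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(f"Cox fit failed to converge: {exc}") from exc
    summary = cph.summary
    return pd.DataFrame(
        {
            "covariate": summary.index,
            "hazard_ratio": summary["exp(coef)"].to_numpy(),
            "ci_lower": summary["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": summary["exp(coef) upper 95%"].to_numpy(),
            "p_value": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)
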