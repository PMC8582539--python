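"""Censored-survival machinery: Kaplan–Meier estimation, log-rank tests,
Cox proportional-hazards models (Efron tie handling), and median-dichotomized
feature screens.  Model fitting is delegated to lifelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from . import stats
from .stats import TestResult


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time_days", "event"):
        if col not in records.columns:
            raise ValueError(f"survival records need a {col!r} column")
    if (records["time_days"] <= 0).any():
        raise ValueError("non-positive follow-up time")
    return records


def kaplan_meier(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Censored observations at an event time are counted at risk at that time
    (the standard convention).  Returns a step-function frame with columns
    ``time``, ``survival`` and ``at_risk``.
    """
    records = _check_records(records)
    if records.empty:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_days"], records["event"])
    surv = kmf.survival_function_
    out = pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "survival": surv.iloc[:, 0].to_numpy(dtype=float),
    })
    ev = kmf.event_table["at_risk"]
    out["at_risk"] = [int(ev.get(t, 0)) for t in out["time"]]
    return out


def logrank_test(records: pd.DataFrame, group_col: str = "group") -> TestResult:
    """Log-rank comparison across ≥2 groups (df = groups − 1)."""
    records = _check_records(records)
    groups = records[group_col].unique()
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    res = multivariate_logrank_test(records["time_days"], records[group_col],
                                    records["event"])
    return TestResult(p=float(res.p_value), statistic=float(res.test_statistic),
                      df=len(groups) - 1, method="logrank")


def cox_ph(records: pd.DataFrame, covariate_cols: list[str]) -> pd.DataFrame:
    """Cox proportional-hazards fit with Efron handling of tied event times.

    Returns one row per covariate: hazard ratio, Wald 95% CI and p.
    """
    records = _check_records(records)
    for col in covariate_cols:
        if records[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant")
    n_events = int(records["event"].sum())
    if n_events < len(covariate_cols) + 1:
        raise ValueError(f"only {n_events} events for "
                         f"{len(covariate_cols)} covariate(s)")
    cph = CoxPHFitter()
    df = records[["time_days", "event"] + list(covariate_cols)].astype(float)
    cph.fit(df, duration_col="time_days", event_col="event")
    summ = cph.summary
    out = pd.DataFrame({
        "covariate": summ.index,
        "hr": summ["exp(coef)"].to_numpy(),
        "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
        "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
        "p": summ["p"].to_numpy(),
        "coef": summ["coef"].to_numpy(),
    }).reset_index(drop=True)
    return out


def median_dichotomized_screen(features: pd.DataFrame, records: pd.DataFrame
                               ) -> pd.DataFrame:
    """Per-feature Cox screen on above-median abundance.

    Each feature is dichotomized at its cohort median — strictly above goes
    to the high group, at or below to the low group — and fit as a single
    binary Cox covariate.  BH correction across testable features.
    """
    records = _check_records(records).set_index("sample")
    shared = [s for s in features.columns if s in records.index]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    sub = records.loc[shared]
    if int(sub["event"].sum()) < 2:
        raise ValueError("need at least 2 events")
    rows = []
    for feat in features.index:
        vals = features.loc[feat, shared].astype(float)
        if vals.nunique() < 2:
            rows.append((feat, np.nan, np.nan, np.nan, np.nan, "zero variance"))
            continue
        high = (vals > vals.median()).astype(float)
        df = pd.DataFrame({"time_days": sub["time_days"].to_numpy(),
                           "event": sub["event"].to_numpy(),
                           "high": high.to_numpy()})
        try:
            fit = cox_ph(df, ["high"])
            r = fit.iloc[0]
            rows.append((feat, r["hr"], r["ci_low"], r["ci_high"], r["p"], None))
        except Exception as exc:  # includes lifelines convergence errors
            rows.append((feat, np.nan, np.nan, np.nan, np.nan, str(exc)))
    out = pd.DataFrame(rows, columns=["feature", "hr", "ci_low", "ci_high",
                                      "p", "note"])
    testable = out["p"].notna()
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable.to_numpy()] = stats.bh_adjust(out.loc[testable, "p"].to_numpy())
    out["q"] = q
    return out
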