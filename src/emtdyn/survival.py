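"""Survival stratification of PEP clusters.

Kaplan-Meier product-limit curves, the k-sample log-rank test and Cox
proportional-hazards ratios against a reference cluster, computed with
lifelines.  Clusters are filtered to the "major" ones (strictly more than
``min_n`` samples) before testing, keeping the reference cluster whenever it
is nonempty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .containers import ValidationError

__all__ = [
    "make_survival_data",
    "filter_major_clusters",
    "km_estimator",
    "logrank_test",
    "cox_hazard_ratios",
    "LogrankResult",
    "CoxResult",
]

DEFAULT_REFERENCE = "h0-8"


def make_survival_data(
    survival: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Join survival records (sample, time_months, event) with group labels."""
    df = survival.copy()
    required = {"sample", "time_months", "event"}
    if not required.issubset(df.columns):
        raise ValidationError(f"survival table needs columns {sorted(required)}")
    if (df["time_months"] <= 0).any() or not np.isfinite(df["time_months"]).all():
        raise ValidationError("survival times must be finite and positive")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event flags must be 0 (censored) or 1 (event)")
    df["group"] = df["sample"].map(groups)
    df = df.dropna(subset=["group"]).reset_index(drop=True)
    if df.empty:
        raise ValidationError("no samples remain after joining group labels")
    return df


def filter_major_clusters(
    data: pd.DataFrame,
    min_n: int = 10,
    reference: str = DEFAULT_REFERENCE,
) -> pd.DataFrame:
    """Keep clusters with strictly more than ``min_n`` samples.

    The reference cluster is always retained when nonempty, regardless of
    size.  Samples of dropped clusters are excluded (logged via warning).
    Fails when fewer than two clusters remain.
    """
    sizes = data["group"].value_counts()
    keep = set(sizes.index[sizes > min_n])
    if reference in sizes.index:
        keep.add(reference)
    dropped = data.loc[~data["group"].isin(keep)]
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} sample(s) in minor clusters "
            f"{sorted(set(dropped['group']))}"
        )
    out = data.loc[data["group"].isin(keep)].reset_index(drop=True)
    if out["group"].nunique() < 2:
        raise ValidationError(
            f"need >= 2 clusters after filtering, got {out['group'].nunique()}"
        )
    return out


def km_estimator(data: pd.DataFrame, group: str) -> pd.DataFrame:
    """Kaplan-Meier curve for one group.

    Returns a frame with ``time``, ``survival`` and ``at_risk`` rows at every
    distinct observed time (event or censoring); survival drops only at event
    times.
    """
    sub = data.loc[data["group"] == group]
    if sub.empty:
        raise ValidationError(f"group {group!r} has no samples")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time_months"], sub["event"])
    times = kmf.survival_function_.index.to_numpy()
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy()
    return pd.DataFrame({"time": times, "survival": surv, "at_risk": at_risk})


@dataclass
class LogrankResult:
    statistic: float
    df: int
    pvalue: float


def logrank_test(data: pd.DataFrame) -> LogrankResult:
    """K-sample log-rank test across all groups present in ``data``."""
    groups = data["group"].astype(str)
    if groups.nunique() < 2:
        raise ValidationError("log-rank test needs >= 2 groups")
    res = multivariate_logrank_test(data["time_months"], groups, data["event"])
    return LogrankResult(
        statistic=float(res.test_statistic),
        df=int(groups.nunique() - 1),
        pvalue=float(res.p_value),
    )


@dataclass
class CoxResult:
    """Hazard ratios per non-reference group (reference HR is 1)."""

    table: pd.DataFrame     # group, hr, ci_low, ci_high, pvalue
    reference: str
    converged: bool


def cox_hazard_ratios(
    data: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE,
) -> CoxResult:
    """Cox proportional-hazards ratios of each cluster vs the reference.

    Group indicators (reference omitted) enter a Cox partial-likelihood fit
    with Breslow tie handling.  A group with no events produces a monotone
    likelihood; the result is then flagged (``converged=False``) with
    boundary estimates reported as fit.
    """
    if reference not in set(data["group"]):
        raise ValidationError(f"reference group {reference!r} not present")
    groups = sorted(set(data["group"]) - {reference})
    X = pd.DataFrame({"T": data["time_months"].values, "E": data["event"].values})
    for g in groups:
        X[f"g_{g}"] = (data["group"] == g).astype(float).values
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(X, duration_col="T", event_col="E")
        except ConvergenceError:
            converged = False
            cph = CoxPHFitter(penalizer=1e-6)
            cph.fit(X, duration_col="T", event_col="E")
    rows = []
    summ = cph.summary
    for g in groups:
        row = summ.loc[f"g_{g}"]
        rows.append(
            (g, float(np.exp(row["coef"])),
             float(np.exp(row["coef lower 95%"])),
             float(np.exp(row["coef upper 95%"])),
             float(row["p"]))
        )
    table = pd.DataFrame(rows, columns=["group", "hr", "ci_low", "ci_high",
                                        "pvalue"])
    if not converged:
        warnings.warn("Cox fit did not converge (monotone likelihood?); "
                      "boundary estimates reported")
    return CoxResult(table=table, reference=reference, converged=converged)
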