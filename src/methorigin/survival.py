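"""Disease-free survival: Kaplan-Meier estimation and log-rank comparison.

Thin wrappers over lifelines exposing the product-limit estimator with
Greenwood standard errors and the multi-group log-rank chi-square test.
Ties between events and censorings at the same time follow the
conventional rule: events precede censorings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .containers import SampleSheet, ValidationError

logger = logging.getLogger(__name__)


def survival_table(sheet: SampleSheet, group_col: str = "group") -> pd.DataFrame:
    """Extract (time, event, group) rows for samples with outcome data."""
    t = sheet.table
    out = pd.DataFrame(
        {
            "time": t["relapse_time"],
            "event": t["relapse_event"],
            "group": t[group_col].astype(str),
        }
    ).dropna(subset=["time", "event"])
    out = out[out["group"] != ""]
    if (out["time"] < 0).any():
        raise ValidationError("negative relapse_time")
    out["event"] = out["event"].astype(int)
    return out


def km_estimate(table: pd.DataFrame, group: Optional[str] = None) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood standard errors.

    ``table`` needs columns time/event (and group if ``group`` given).
    Returns a DataFrame indexed by distinct times with columns
    ``survival``, ``se`` and the at-risk/event counts. Censored-only
    input yields survival identically 1.
    """
    sub = table if group is None else table[table["group"] == group]
    if len(sub) == 0:
        raise ValidationError(f"no subjects in group {group!r}")
    if (sub["time"] < 0).any():
        raise ValidationError("negative time")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    surv = kmf.survival_function_["KM_estimate"]
    # Greenwood variance -> SE of S(t)
    ci_table = kmf.event_table
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = ci_table["observed"] / (
            ci_table["at_risk"] * (ci_table["at_risk"] - ci_table["observed"])
        )
    greenwood = surv.to_numpy() * np.sqrt(np.maximum(terms.fillna(0).cumsum(), 0.0))
    out = pd.DataFrame(
        {
            "survival": surv.to_numpy(),
            "se": np.nan_to_num(greenwood, nan=0.0),
            "at_risk": ci_table["at_risk"].to_numpy(),
            "events": ci_table["observed"].to_numpy(),
            "censored": ci_table["censored"].to_numpy(),
        },
        index=surv.index.rename("time"),
    )
    return out


def logrank_test(table: pd.DataFrame) -> dict:
    """Multi-group log-rank test: chi-square statistic, df, p value."""
    groups = table["group"].unique()
    if len(groups) < 2:
        raise ValidationError("log-rank needs at least 2 groups")
    if table["event"].sum() < 1:
        raise ValidationError("log-rank needs at least 1 event")
    res = multivariate_logrank_test(table["time"], table["group"], table["event"])
    return {
        "statistic": float(res.test_statistic),
        "df": int(len(groups) - 1),
        "p_value": float(res.p_value),
    }
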