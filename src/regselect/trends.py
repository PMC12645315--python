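"""Descriptive cohort surfaces: per-cohort means with 95% CIs and extreme-cohort tables."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .register import add_timing

logger = logging.getLogger(__name__)

VARIABLES = ("offspring", "AFB", "ALB", "IBI")

SUMMARY_COLUMNS = ("variable", "sex", "education", "birth_year", "mean", "ci_low", "ci_high", "n")


def _variable_values(df: pd.DataFrame, variable: str) -> pd.Series:
    """Eligibility differs by variable: offspring counts everyone, AFB/ALB the
    parous, IBI those with at least two children."""
    if variable == "offspring":
        return df["n_children"].astype(float)
    if variable in ("AFB", "ALB", "IBI"):
        timed = df if variable in df.columns else add_timing(df)
        return timed[variable].astype(float)
    raise ValueError(f"unknown variable {variable!r}")


def cohort_summary(
    df: pd.DataFrame,
    variable: str,
    by: Sequence[str] = ("sex",),
    ci: str = "normal",
) -> pd.DataFrame:
    """Birth-cohort means with 95% CIs per group.

    ``by`` is ``("sex",)`` (education reported as "all") or
    ``("sex", "education")``. The CI is the normal approximation
    mean +- 1.96*SD/sqrt(n) by default; ``ci="t"`` substitutes the
    t critical value for small groups. Groups with n < 2 are omitted.
    """
    if ci not in ("normal", "t"):
        raise ValueError(f"unknown ci method {ci!r}")
    values = _variable_values(df, variable)
    work = pd.DataFrame({"value": values, "birth_year": df["birth_year"], "sex": df["sex"]})
    work["education"] = df["education"] if "education" in by else "all"
    work = work.dropna(subset=["value"])
    grp = work.groupby(["sex", "education", "birth_year"], observed=True)["value"]
    out = grp.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size").reset_index()
    out = out[out["n"] >= 2].copy()
    crit = (
        1.96 if ci == "normal" else stats.t.ppf(0.975, out["n"].to_numpy() - 1)
    )
    half = crit * out["sd"].to_numpy() / np.sqrt(out["n"].to_numpy())
    out["ci_low"] = out["mean"] - half
    out["ci_high"] = out["mean"] + half
    out["variable"] = variable
    return out[list(SUMMARY_COLUMNS)].sort_values(["sex", "education", "birth_year"]).reset_index(drop=True)


def extreme_cohorts(summaries: pd.DataFrame) -> pd.DataFrame:
    """Birth cohorts attaining the maximum and minimum mean per (sex, education).

    Ties are broken toward the earlier cohort so output is deterministic.
    Input rows must come from :func:`cohort_summary` (typically for offspring).
    """
    rows = []
    for (sex, edu), sub in summaries.groupby(["sex", "education"], observed=True):
        if sub.empty:
            continue
        sub = sub.sort_values("birth_year")  # earlier year wins ties via idxmax/idxmin order
        i_max = sub["mean"].idxmax()
        i_min = sub["mean"].idxmin()
        rows.append(
            {
                "sex": sex,
                "education": edu,
                "max_cohort": int(sub.loc[i_max, "birth_year"]),
                "max_mean": float(sub.loc[i_max, "mean"]),
                "min_cohort": int(sub.loc[i_min, "birth_year"]),
                "min_mean": float(sub.loc[i_min, "mean"]),
            }
        )
    return pd.DataFrame(rows, columns=["sex", "education", "max_cohort", "max_mean", "min_cohort", "min_mean"])
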