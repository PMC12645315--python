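"""Lande-Arnold selection gradients on register data.

Relative lifetime reproductive success (rLRS) is an individual's offspring
count divided by the mean offspring count of their sex x birth-year cohort, so
that cohort mean rLRS is 1 and a regression slope of rLRS on a standardized
trait is a selection gradient in SD units. Linear gradients (beta) come from
the linear model ``rLRS = a + beta*z``; quadratic gradients use
``rLRS = a + beta_Q*z + (1/2)*gamma*z**2`` so that the reported gamma is twice
the fitted coefficient of ``z**2``. Negative gamma means a concave
(stabilizing-type) fitness surface with peak at ``-beta_Q/gamma``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .register import KNOWN_EDUCATION_LEVELS, TRAITS, add_timing

logger = logging.getLogger(__name__)

#: Normal critical value used for every 95% interval in the package.
Z_CRIT = 1.96

DEFAULT_MIN_STRATUM_SIZE = 30

GRADIENT_COLUMNS = (
    "trait",
    "sex",
    "education",
    "cohort_from",
    "cohort_to",
    "model",
    "beta",
    "se_beta",
    "beta_ci_low",
    "beta_ci_high",
    "gamma",
    "se_gamma",
    "gamma_ci_low",
    "gamma_ci_high",
    "n",
)


class DegenerateDataError(ValueError):
    """Raised when a regression design is degenerate (no trait variance, etc.)."""


@dataclass
class GradientEstimate:
    """A fitted selection gradient with its uncertainty and stratum labels.

    For ``model == "quadratic"``, ``beta`` is the linear coefficient beta_Q of
    the quadratic model and ``gamma`` is twice the fitted z**2 coefficient.
    ``coefs``/``cov`` hold the full coefficient vector (intercept, z[, z**2])
    and its covariance so prediction bands can be formed later.
    """

    trait: str
    model: str
    beta: float
    se_beta: float
    beta_ci_low: float
    beta_ci_high: float
    n: int
    sex: str = "all"
    education: str = "all"
    cohort_from: Optional[int] = None
    cohort_to: Optional[int] = None
    gamma: Optional[float] = None
    se_gamma: Optional[float] = None
    gamma_ci_low: Optional[float] = None
    gamma_ci_high: Optional[float] = None
    coefs: Optional[np.ndarray] = field(default=None, repr=False)
    cov: Optional[np.ndarray] = field(default=None, repr=False)


def cohort_mean_fitness(df: pd.DataFrame, basis: str = "cohort") -> pd.DataFrame:
    """Mean offspring count per (sex, birth_year), the rLRS denominator.

    ``basis="cohort"`` averages over every cohort member (childless and
    unknown-education individuals included). ``basis="parous"`` averages over
    parous members only, for sensitivity analyses in which relative fitness is
    defined among reproducers. Cohorts whose mean is zero are flagged
    ``degenerate`` and must be dropped downstream.
    """
    if basis not in ("cohort", "parous"):
        raise ValueError(f"unknown rLRS basis {basis!r}")
    sub = df if basis == "cohort" else df[df["n_children"] >= 1]
    grp = sub.groupby(["sex", "birth_year"], observed=True)["n_children"]
    out = grp.agg(mean="mean", n="size").reset_index()
    out["mean"] = out["mean"].astype(float)
    out["degenerate"] = ~(out["mean"] > 0)
    n_bad = int(out["degenerate"].sum())
    if n_bad:
        logger.warning("cohort_mean_fitness: %d all-childless cohorts flagged", n_bad)
    return out


def relative_fitness(
    df: pd.DataFrame,
    means: Optional[pd.DataFrame] = None,
    basis: str = "cohort",
) -> pd.DataFrame:
    """Return a copy of *df* with an ``rlrs`` column.

    Individuals from degenerate (zero-mean) cohorts are excluded with a log
    entry. With the default basis, mean rLRS within every retained sex x
    birth-year cohort is 1 up to floating error.
    """
    if means is None:
        means = cohort_mean_fitness(df, basis=basis)
    merged = df.merge(
        means.rename(columns={"mean": "_cohort_mean", "n": "_cohort_n"}),
        on=["sex", "birth_year"],
        how="left",
    )
    merged.index = df.index
    dropped = merged["degenerate"].fillna(True).astype(bool)
    if dropped.any():
        logger.warning(
            "relative_fitness: dropped %d individuals in degenerate cohorts", int(dropped.sum())
        )
    out = df.loc[~dropped.to_numpy()].copy()
    out["rlrs"] = (
        merged.loc[~dropped.to_numpy(), "n_children"] / merged.loc[~dropped.to_numpy(), "_cohort_mean"]
    ).astype(float)
    return out


def standardize_trait(
    df: pd.DataFrame,
    trait: str,
    group: Sequence[str] = ("sex", "birth_year"),
) -> pd.Series:
    """Cohort z-scores of a timing trait (NaN where undefined or group dropped).

    Standardization uses the sample SD (n-1 denominator) within each group,
    computed over the individuals for whom the trait is defined. Groups with
    fewer than two defined values or zero variance are dropped with a warning.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    values = df[trait] if trait in df.columns else add_timing(df)[trait]
    work = pd.DataFrame({"value": values})
    for g in group:
        work[g] = df[g]
    grp = work.dropna(subset=["value"]).groupby(list(group), observed=True)["value"]
    stats = grp.agg(_mean="mean", _sd=lambda s: s.std(ddof=1), _n="size")
    bad = (stats["_n"] < 2) | ~(stats["_sd"] > 0)
    if bad.any():
        logger.warning(
            "standardize_trait(%s): dropped %d groups (size<2 or zero variance)",
            trait,
            int(bad.sum()),
        )
    stats = stats[~bad]
    merged = work.join(stats, on=list(group))
    z = (merged["value"] - merged["_mean"]) / merged["_sd"]
    z.name = f"z_{trait}"
    return z


def _fit_ols(y: np.ndarray, X: np.ndarray, robust: bool) -> sm.regression.linear_model.RegressionResultsWrapper:
    model = sm.OLS(y, X)
    return model.fit(cov_type="HC1") if robust else model.fit()


def _clean_xy(rlrs, z) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(rlrs, dtype=float)
    x = np.asarray(z, dtype=float)
    if y.shape != x.shape:
        raise ValueError("rlrs and z must have equal length")
    ok = np.isfinite(y) & np.isfinite(x)
    return y[ok], x[ok]


def linear_gradient(rlrs, z, *, robust: bool = False, **labels) -> GradientEstimate:
    """Directional selection gradient: OLS slope of rLRS on the z-scored trait.

    The slope is identically cov(rlrs, z)/var(z); the 95% CI uses the
    coefficient standard error with the 1.96 normal critical value.
    """
    y, x = _clean_xy(rlrs, z)
    if len(y) < 2:
        raise DegenerateDataError("need at least two observations")
    if np.ptp(x) == 0:
        raise DegenerateDataError("trait z-scores have zero variance")
    X = np.column_stack([np.ones_like(x), x])
    res = _fit_ols(y, X, robust)
    beta, se = float(res.params[1]), float(res.bse[1])
    return GradientEstimate(
        trait=labels.pop("trait", ""),
        model="linear",
        beta=beta,
        se_beta=se,
        beta_ci_low=beta - Z_CRIT * se,
        beta_ci_high=beta + Z_CRIT * se,
        n=len(y),
        coefs=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        **labels,
    )


def quadratic_gradient(rlrs, z, *, robust: bool = False, **labels) -> GradientEstimate:
    """Quadratic model fit; reported gamma is twice the z**2 coefficient."""
    y, x = _clean_xy(rlrs, z)
    if len(np.unique(x)) < 3:
        raise DegenerateDataError("quadratic fit needs at least three distinct z values")
    X = np.column_stack([np.ones_like(x), x, x**2])
    res = _fit_ols(y, X, robust)
    beta, se_b = float(res.params[1]), float(res.bse[1])
    gamma, se_g = 2.0 * float(res.params[2]), 2.0 * float(res.bse[2])
    return GradientEstimate(
        trait=labels.pop("trait", ""),
        model="quadratic",
        beta=beta,
        se_beta=se_b,
        beta_ci_low=beta - Z_CRIT * se_b,
        beta_ci_high=beta + Z_CRIT * se_b,
        gamma=gamma,
        se_gamma=se_g,
        gamma_ci_low=gamma - Z_CRIT * se_g,
        gamma_ci_high=gamma + Z_CRIT * se_g,
        n=len(y),
        coefs=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        **labels,
    )


def _prepare(df, trait, basis, within_stratum):
    """Attach rlrs and z columns; returns the working frame."""
    timed = add_timing(df)
    work = relative_fitness(timed, basis=basis)
    group = ["sex", "birth_year"] + (["education"] if within_stratum else [])
    work["z"] = standardize_trait(work, trait, group=group)
    return work


def gradient_by_stratum(
    df: pd.DataFrame,
    trait: str,
    *,
    models: Sequence[str] = ("linear", "quadratic"),
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE,
    basis: str = "cohort",
    robust: bool = False,
    standardize_within_stratum: bool = False,
) -> list[GradientEstimate]:
    """Per (sex, education) gradients, pooling all cohorts.

    Individuals with unknown education contribute to cohort means and to the
    pooled standardization but never form a stratum. Strata smaller than
    ``min_stratum_size`` (after dropping undefined traits) are omitted with a
    warning.
    """
    work = _prepare(df, trait, basis, standardize_within_stratum)
    out: list[GradientEstimate] = []
    for (sex, edu), sub in work.groupby(["sex", "education"], observed=True):
        if edu not in KNOWN_EDUCATION_LEVELS:
            continue
        sub = sub.dropna(subset=["z", "rlrs"])
        if len(sub) < min_stratum_size:
            logger.warning(
                "gradient_by_stratum: stratum (%s,%s) omitted (n=%d < %d)",
                sex, edu, len(sub), min_stratum_size,
            )
            continue
        labels = dict(
            trait=trait,
            sex=sex,
            education=edu,
            cohort_from=int(sub["birth_year"].min()),
            cohort_to=int(sub["birth_year"].max()),
        )
        if "linear" in models:
            out.append(linear_gradient(sub["rlrs"], sub["z"], robust=robust, **labels))
        if "quadratic" in models:
            out.append(quadratic_gradient(sub["rlrs"], sub["z"], robust=robust, **labels))
    return out


def gradient_by_cohort(
    df: pd.DataFrame,
    trait: str,
    *,
    models: Sequence[str] = ("linear",),
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE,
    basis: str = "cohort",
    robust: bool = False,
    standardize_within_stratum: bool = False,
) -> list[GradientEstimate]:
    """Per (sex, education, birth_year) gradients, ordered by cohort.

    Cohorts below the minimum size leave a gap in the series, not an error.
    """
    work = _prepare(df, trait, basis, standardize_within_stratum)
    out: list[GradientEstimate] = []
    keys = sorted(
        (k for k in work.groupby(["sex", "education", "birth_year"], observed=True).groups),
        key=lambda k: (k[0], k[1], k[2]),
    )
    grouped = work.groupby(["sex", "education", "birth_year"], observed=True)
    for sex, edu, year in keys:
        if edu not in KNOWN_EDUCATION_LEVELS:
            continue
        sub = grouped.get_group((sex, edu, year)).dropna(subset=["z", "rlrs"])
        if len(sub) < min_stratum_size:
            continue
        labels = dict(trait=trait, sex=sex, education=edu, cohort_from=int(year), cohort_to=int(year))
        try:
            if "linear" in models:
                out.append(linear_gradient(sub["rlrs"], sub["z"], robust=robust, **labels))
            if "quadratic" in models:
                out.append(quadratic_gradient(sub["rlrs"], sub["z"], robust=robust, **labels))
        except DegenerateDataError:
            logger.warning("gradient_by_cohort: degenerate cohort (%s,%s,%s) skipped", sex, edu, year)
    return out


def education_gradient(
    df: pd.DataFrame,
    *,
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE,
    basis: str = "cohort",
    robust: bool = False,
) -> list[GradientEstimate]:
    """Selection gradients for educational attainment, per sex.

    rLRS is regressed on indicator variables for secondary, vocational and
    tertiary education with primary as the reference level, so each beta is
    numerically the difference in mean rLRS between that level and primary.
    Unknown education is excluded from the regression (but not from the
    cohort means behind rLRS).
    """
    work = relative_fitness(df, basis=basis)
    out: list[GradientEstimate] = []
    for sex, sub in work.groupby("sex", observed=True):
        sub = sub[sub["education"].isin(KNOWN_EDUCATION_LEVELS)]
        if (sub["education"] == "primary").sum() == 0:
            raise DegenerateDataError(f"no primary-education reference group for sex {sex}")
        levels = [e for e in ("secondary", "vocational", "tertiary") if (sub["education"] == e).any()]
        X = np.column_stack(
            [np.ones(len(sub))] + [(sub["education"] == e).to_numpy(float) for e in levels]
        )
        res = _fit_ols(sub["rlrs"].to_numpy(float), X, robust)
        cohort_from, cohort_to = int(sub["birth_year"].min()), int(sub["birth_year"].max())
        for j, e in enumerate(levels, start=1):
            n_level = int((sub["education"] == e).sum())
            if n_level < min_stratum_size:
                logger.warning("education_gradient: level %s (%s) omitted, n=%d", e, sex, n_level)
                continue
            beta, se = float(res.params[j]), float(res.bse[j])
            out.append(
                GradientEstimate(
                    trait="EDUCATION",
                    model="linear",
                    beta=beta,
                    se_beta=se,
                    beta_ci_low=beta - Z_CRIT * se,
                    beta_ci_high=beta + Z_CRIT * se,
                    n=n_level,
                    sex=sex,
                    education=e,
                    cohort_from=cohort_from,
                    cohort_to=cohort_to,
                )
            )
    return out


def fitness_curve(estimate: GradientEstimate, z_grid: Sequence[float]) -> pd.DataFrame:
    """Predicted quadratic fitness surface with a pointwise 95% band.

    Predictions are ``a + beta_Q*z + (1/2)*gamma*z**2``; the band comes from
    the standard error of the linear combination of fitted coefficients. The
    peak of a concave curve sits at ``-beta_Q/gamma``.
    """
    if estimate.model != "quadratic" or estimate.coefs is None or estimate.cov is None:
        raise ValueError("fitness_curve needs a quadratic estimate with coefficients and covariance")
    grid = np.asarray(list(z_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty z grid")
    X = np.column_stack([np.ones_like(grid), grid, grid**2])
    fit = X @ estimate.coefs
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, estimate.cov, X))
    return pd.DataFrame(
        {
            "trait": estimate.trait,
            "sex": estimate.sex,
            "education": estimate.education,
            "z": grid,
            "fit": fit,
            "ci_low": fit - Z_CRIT * se,
            "ci_high": fit + Z_CRIT * se,
        }
    )


def curve_peak(estimate: GradientEstimate) -> float:
    """Stationary point -beta_Q/gamma of a fitted quadratic surface."""
    if estimate.model != "quadratic" or not estimate.gamma:
        raise ValueError("peak defined only for a quadratic fit with nonzero gamma")
    return -estimate.beta / estimate.gamma


def ci_overlap(a: Sequence[float], b: Sequence[float]) -> bool:
    """True when two 95% CIs do NOT overlap ("indicative difference").

    Touching intervals count as overlapping (conservative reading).
    """
    a_low, a_high = float(a[0]), float(a[1])
    b_low, b_high = float(b[0]), float(b[1])
    if a_low > a_high or b_low > b_high:
        raise ValueError("malformed interval")
    return a_high < b_low or b_high < a_low


def gradients_to_frame(estimates: Iterable[GradientEstimate]) -> pd.DataFrame:
    """Tabulate estimates in the gradient CSV schema (gamma columns empty for linear fits)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "trait": e.trait,
                "sex": e.sex,
                "education": e.education,
                "cohort_from": e.cohort_from,
                "cohort_to": e.cohort_to,
                "model": e.model,
                "beta": e.beta,
                "se_beta": e.se_beta,
                "beta_ci_low": e.beta_ci_low,
                "beta_ci_high": e.beta_ci_high,
                "gamma": e.gamma,
                "se_gamma": e.se_gamma,
                "gamma_ci_low": e.gamma_ci_low,
                "gamma_ci_high": e.gamma_ci_high,
                "n": e.n,
            }
        )
    return pd.DataFrame(rows, columns=list(GRADIENT_COLUMNS))
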