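"""Monte-Carlo experiments that validate the estimation chain end to end.

Each experiment generates registers from a :mod:`regselect.scenarios` config,
pushes them through the full pipeline (filtering, timing traits, relative
fitness, cohort z-scores, gradient regressions) and compares estimates with
the configured truths. Replicate seeds are derived from one base seed and kept
below 2**31.

Recovery experiments use the parous relative-fitness basis: timing traits
exist only for parous individuals, so the truth of a timing-trait gradient is
defined on the parous scale (see docs/methods.md).
"""

from __future__ import annotations

import pandas as pd

from . import scenarios
from .selection import education_gradient, gradient_by_stratum, linear_gradient, relative_fitness, standardize_trait
from .register import add_timing
from .simulate import apply_father_underregistration, simulate_register

#: Truths used by the recovery experiments (stratum -> true gradient).
AFB_TRUTHS = {"primary": -0.30, "tertiary": -0.14}
ALB_TRUTH = 0.38
IBI_GAMMA_TRUTH = -0.40


def _rep_seed(seed: int, experiment: int, replicate: int) -> int:
    return (seed * 1_000_003 + experiment * 7_919 + replicate) % 2**31


def afb_recovery_replicates(n_per_stratum: int = 50_000, n_replicates: int = 200, seed: int = 0) -> pd.DataFrame:
    """Recover directional gradients on age at first birth (two strata at once)."""
    rows = []
    for rep in range(n_replicates):
        cfg = scenarios.recovery_afb_config(n_per_stratum, seed=_rep_seed(seed, 1, rep))
        df, _ = simulate_register(cfg)
        for est in gradient_by_stratum(df, "AFB", models=("linear",), basis="parous"):
            rows.append(
                {
                    "replicate": rep,
                    "trait": "AFB",
                    "education": est.education,
                    "truth": AFB_TRUTHS[est.education],
                    "estimate": est.beta,
                    "n": est.n,
                }
            )
    return pd.DataFrame(rows)


def alb_recovery_replicates(n_individuals: int = 50_000, n_replicates: int = 200, seed: int = 0) -> pd.DataFrame:
    """Recover the positive directional gradient on age at last birth."""
    rows = []
    for rep in range(n_replicates):
        cfg = scenarios.recovery_alb_config(n_individuals, seed=_rep_seed(seed, 2, rep))
        df, _ = simulate_register(cfg)
        est = gradient_by_stratum(df, "ALB", models=("linear",), basis="parous")[0]
        rows.append(
            {"replicate": rep, "trait": "ALB", "education": "primary", "truth": ALB_TRUTH,
             "estimate": est.beta, "n": est.n}
        )
    return pd.DataFrame(rows)


def ibi_recovery_replicates(n_individuals: int = 50_000, n_replicates: int = 200, seed: int = 0) -> pd.DataFrame:
    """Recover the stabilizing (quadratic) gradient on the interbirth interval."""
    rows = []
    for rep in range(n_replicates):
        cfg = scenarios.recovery_ibi_config(n_individuals, seed=_rep_seed(seed, 3, rep))
        df, _ = simulate_register(cfg)
        est = gradient_by_stratum(df, "IBI", models=("quadratic",), basis="parous")[0]
        rows.append(
            {"replicate": rep, "trait": "IBI", "education": "primary", "truth": IBI_GAMMA_TRUTH,
             "estimate": est.gamma, "n": est.n}
        )
    return pd.DataFrame(rows)


def null_calibration_replicates(n_individuals: int = 5_000, n_replicates: int = 500, seed: int = 0) -> pd.DataFrame:
    """Flat-fitness calibration: how often does the 95% CI cover beta = 0?"""
    rows = []
    for rep in range(n_replicates):
        cfg = scenarios.null_config(n_individuals, seed=_rep_seed(seed, 4, rep))
        df, _ = simulate_register(cfg)
        work = relative_fitness(add_timing(df))
        work["z"] = standardize_trait(work, "AFB")
        sub = work.dropna(subset=["z"])
        est = linear_gradient(sub["rlrs"], sub["z"], trait="AFB")
        rows.append(
            {
                "replicate": rep,
                "beta": est.beta,
                "ci_low": est.beta_ci_low,
                "ci_high": est.beta_ci_high,
                "covered": est.beta_ci_low <= 0.0 <= est.beta_ci_high,
                "n": est.n,
            }
        )
    return pd.DataFrame(rows)


def underregistration_experiment(
    n_individuals: int = 120_000,
    seed: int = 0,
    q_background: float = 0.05,
    q_primary_raised: float = 0.35,
) -> dict:
    """Isolate the father-unlinking bias on men's education gradients.

    One population with identical fitness in every stratum is degraded twice:
    once with a uniform unlink probability, once with the probability raised
    for primary-educated men only. Returns the estimated mean relative fitness
    of primary-educated men and the education contrasts (vs. primary) under
    both conditions.
    """
    cfg = scenarios.bias_demo_config(n_individuals, seed=_rep_seed(seed, 5, 0))
    df, _ = simulate_register(cfg)
    levels = ("primary", "secondary", "vocational", "tertiary")

    def _analyze(q_primary: float) -> dict:
        q = {lvl: q_background for lvl in levels}
        q["primary"] = q_primary
        degraded = apply_father_underregistration(df, q, seed=_rep_seed(seed, 6, 0))
        w = relative_fitness(degraded)
        men = w[w["sex"] == "M"]
        contrasts = {
            e.education: e.beta for e in education_gradient(degraded) if e.sex == "M"
        }
        return {
            "mean_rlrs_primary_men": float(men.loc[men["education"] == "primary", "rlrs"].mean()),
            "contrasts": contrasts,
            "n_men": int(len(men)),
        }

    return {
        "uniform": _analyze(q_background),
        "raised": _analyze(q_primary_raised),
        "q_background": q_background,
        "q_primary_raised": q_primary_raised,
    }
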