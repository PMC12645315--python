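"""Relative fitness, cohort z-scores, and selection-gradient estimation.

The regression fits are checked against hand-written oracles (covariance
ratio for the linear slope; normal equations solved directly for the
quadratic fit) that never touch the implementation path.
"""

import numpy as np
import pandas as pd
import pytest

from regselect.register import IndividualRecord, add_timing, records_to_frame
from regselect.selection import (
    DegenerateDataError,
    Z_CRIT,
    ci_overlap,
    cohort_mean_fitness,
    curve_peak,
    education_gradient,
    fitness_curve,
    gradient_by_cohort,
    gradient_by_stratum,
    linear_gradient,
    quadratic_gradient,
    relative_fitness,
    standardize_trait,
)


def _cohort(children, education=None, sex="F", year=1950, start="p"):
    education = education or ["primary"] * len(children)
    recs = []
    for i, (n, edu) in enumerate(zip(children, education)):
        first = year + 25 if n else None
        last = (year + 25 + n) if n >= 2 else first
        recs.append(IndividualRecord(f"{start}{i}", sex, year, edu, n, first, last))
    return records_to_frame(recs)


# --- cohort means and relative fitness -------------------------------------


def test_cohort_mean_includes_unknown_education():
    df = _cohort([0, 2, 4])
    assert cohort_mean_fitness(df)["mean"].item() == 2.0
    df2 = pd.concat([df, _cohort([3], ["unknown"], start="q")], ignore_index=True)
    assert cohort_mean_fitness(df2)["mean"].item() == 2.25


def test_all_childless_cohort_flagged_and_dropped():
    df = _cohort([0, 0, 0])
    means = cohort_mean_fitness(df)
    assert means["degenerate"].item()
    assert relative_fitness(df).empty


def test_relative_fitness_worked_values():
    df = _cohort([0, 2, 4])
    out = relative_fitness(df)
    assert list(out["rlrs"]) == [0.0, 1.0, 2.0]
    df2 = pd.concat([df, _cohort([3], ["unknown"], start="q")], ignore_index=True)
    out2 = relative_fitness(df2)
    assert out2["rlrs"].iloc[3] == pytest.approx(3 / 2.25)
    assert out2["rlrs"].mean() == pytest.approx(1.0, abs=1e-12)


def test_rlrs_zero_iff_childless(default_register):
    df, _, _ = default_register
    out = relative_fitness(df)
    assert ((out["rlrs"] == 0) == (out["n_children"] == 0)).all()


def test_rlrs_normalization_invariant(default_register):
    df, _, _ = default_register
    out = relative_fitness(df)
    dev = (out.groupby(["sex", "birth_year"])["rlrs"].mean() - 1.0).abs()
    assert dev.max() <= 1e-12


def test_parous_basis_mean_is_one_over_parous():
    df = _cohort([0, 2, 4])
    out = relative_fitness(df, basis="parous")
    parous = out[out["n_children"] >= 1]
    assert parous["rlrs"].mean() == pytest.approx(1.0, abs=1e-12)


# --- standardization --------------------------------------------------------


def _frame_with_afb(values, year=1950, sex="F"):
    recs = [
        IndividualRecord(f"s{i}", sex, year, "primary", 1, year + v, year + v)
        for i, v in enumerate(values)
    ]
    return add_timing(records_to_frame(recs))


def test_standardize_worked_case():
    df = _frame_with_afb([20, 24, 28])
    z = standardize_trait(df, "AFB")
    assert list(z) == [-1.0, 0.0, 1.0]  # sample SD (n-1) is 4


def test_standardize_location_invariance():
    a = _frame_with_afb([20, 24, 28], year=1950)
    b = _frame_with_afb([25, 29, 33], year=1951)
    df = pd.concat([a, b], ignore_index=True)
    z = standardize_trait(df, "AFB")
    assert list(z[:3]) == list(z[3:])


def test_standardize_drops_small_and_constant_groups():
    single = _frame_with_afb([22], year=1950)
    constant = _frame_with_afb([22, 22], year=1951)
    ok = _frame_with_afb([20, 24], year=1952)
    df = pd.concat([single, constant, ok], ignore_index=True)
    z = standardize_trait(df, "AFB")
    assert z[:3].isna().all() and z[3:].notna().all()


def test_standardize_invariant_on_generated_data(default_register):
    df, _, _ = default_register
    timed = add_timing(df)
    for trait in ("AFB", "ALB", "IBI"):
        z = standardize_trait(timed, trait)
        grp = timed.assign(z=z).dropna(subset=["z"]).groupby(["sex", "birth_year"])["z"]
        assert grp.mean().abs().max() <= 1e-10
        assert (grp.std(ddof=1) - 1).abs().max() <= 1e-10


# --- gradient fits vs oracles -----------------------------------------------


def test_linear_gradient_three_point_case():
    est = linear_gradient([0.5, 1.0, 1.5], [-1.0, 0.0, 1.0])
    assert est.beta == pytest.approx(0.5, abs=1e-12)
    assert est.se_beta == pytest.approx(0.0, abs=1e-12)  # exact fit
    assert est.beta_ci_low <= est.beta <= est.beta_ci_high


def test_linear_gradient_flat_fitness_is_zero():
    est = linear_gradient([1.0, 1.0, 1.0, 1.0], [-1.0, 0.0, 0.5, 1.0])
    assert est.beta == pytest.approx(0.0, abs=1e-12)


def test_linear_gradient_equals_cov_over_var(rng):
    for _ in range(1000):
        n = rng.integers(5, 200)
        z = rng.normal(size=n)
        y = rng.normal(size=n)
        est = linear_gradient(y, z)
        oracle = np.cov(y, z, ddof=1)[0, 1] / np.var(z, ddof=1)
        assert est.beta == pytest.approx(oracle, abs=1e-10)


def test_quadratic_gradient_three_point_interpolation():
    est = quadratic_gradient([1.5, 1.0, 1.5], [-1.0, 0.0, 1.0])
    assert est.coefs[0] == pytest.approx(1.0, abs=1e-12)
    assert est.beta == pytest.approx(0.0, abs=1e-12)
    assert est.gamma == pytest.approx(1.0, abs=1e-12)  # doubled 0.5 coefficient


def test_quadratic_gradient_on_linear_data():
    z = np.array([-1.0, 0.0, 1.0, 2.0])
    est = quadratic_gradient(1 + 0.3 * z, z)
    assert est.beta == pytest.approx(0.3, abs=1e-12)
    assert est.gamma == pytest.approx(0.0, abs=1e-12)


def test_quadratic_gradient_matches_normal_equations(rng):
    for _ in range(1000):
        n = rng.integers(6, 200)
        z = rng.normal(size=n)
        y = 1 + 0.2 * z - 0.1 * z**2 + rng.normal(scale=0.3, size=n)
        est = quadratic_gradient(y, z)
        X = np.column_stack([np.ones(n), z, z**2])
        coefs = np.linalg.solve(X.T @ X, X.T @ y)  # independent normal equations
        assert est.beta == pytest.approx(coefs[1], abs=1e-8)
        assert est.gamma == pytest.approx(2.0 * coefs[2], abs=1e-8)  # doubling rule, exactly


@pytest.mark.parametrize("func", [linear_gradient, quadratic_gradient])
def test_gradient_errors_on_degenerate_design(func):
    with pytest.raises(DegenerateDataError):
        func([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])


def test_scale_equivariance_of_standardized_gradients(rng):
    """Multiplying the raw trait by a constant leaves standardized gradients unchanged."""
    year = 1950
    afb = rng.integers(18, 36, size=200)
    n_children = rng.integers(0, 5, size=200)
    recs = []
    for i, (a, n) in enumerate(zip(afb, n_children)):
        first = year + int(a) if n else None
        last = first + int(n) if n >= 2 else first
        recs.append(IndividualRecord(f"e{i}", "F", year, "primary", int(n), first, last))
    df = add_timing(records_to_frame(recs))
    w = relative_fitness(df)
    z1 = standardize_trait(w, "AFB")
    scaled = w.assign(AFB=w["AFB"] * 3.7)
    z2 = standardize_trait(scaled, "AFB")
    ok = z1.notna()
    b1 = linear_gradient(w.loc[ok, "rlrs"], z1[ok])
    b2 = linear_gradient(w.loc[ok, "rlrs"], z2[ok])
    assert b1.beta == pytest.approx(b2.beta, abs=1e-12)


# --- stratified drivers -----------------------------------------------------


def test_gradient_by_stratum_omits_small_and_unknown(default_register):
    df, _, _ = default_register
    ests = gradient_by_stratum(df, "AFB", models=("linear",), min_stratum_size=30)
    strata = {(e.sex, e.education) for e in ests}
    assert all(edu != "unknown" for _, edu in strata)
    assert all(e.n >= 30 for e in ests)
    small = gradient_by_stratum(df.head(200), "AFB", models=("linear",), min_stratum_size=10_000)
    assert small == []


def test_gradient_by_cohort_orders_and_gaps(default_register):
    df, _, _ = default_register
    sub = df[df["education"] == "primary"]
    ests = gradient_by_cohort(sub, "AFB", models=("linear",), min_stratum_size=30)
    assert ests, "expected per-cohort estimates"
    for e in ests:
        assert e.cohort_from == e.cohort_to and e.n >= 30
    years = [(e.sex, e.cohort_from) for e in ests]
    assert years == sorted(years)


def test_gradient_by_cohort_single_sex_cohort(rng):
    recs = []
    for i in range(40):  # one all-female cohort with varying timing
        afb = 20 + int(rng.integers(0, 12))
        n = 1 + int(rng.integers(0, 4))
        first = 1950 + afb
        last = first + n if n >= 2 else first
        recs.append(IndividualRecord(f"w{i}", "F", 1950, "primary", n, first, last))
    ests = gradient_by_cohort(records_to_frame(recs), "AFB", models=("linear",), min_stratum_size=5)
    assert ests and {e.sex for e in ests} == {"F"}


# --- education gradients ----------------------------------------------------


def test_education_gradient_equals_group_mean_difference():
    df = pd.concat(
        [
            _cohort([1, 2], ["primary", "primary"], start="a"),
            _cohort([3, 1], ["tertiary", "tertiary"], start="b"),
            _cohort([2, 2], ["secondary", "secondary"], start="c"),
        ],
        ignore_index=True,
    )
    w = relative_fitness(df)
    oracle = {
        e: w.loc[w["education"] == e, "rlrs"].mean() - w.loc[w["education"] == "primary", "rlrs"].mean()
        for e in ("secondary", "tertiary")
    }
    ests = {e.education: e for e in education_gradient(df, min_stratum_size=2)}
    for level, exp in oracle.items():
        assert ests[level].beta == pytest.approx(exp, abs=1e-10)


def test_education_gradient_zero_when_levels_identical(rng):
    children = list(rng.integers(0, 5, size=40))
    df = pd.concat(
        [_cohort(children, [e] * 40, start=e[0]) for e in ("primary", "secondary", "vocational", "tertiary")],
        ignore_index=True,
    )
    for e in education_gradient(df, min_stratum_size=2):
        assert e.beta == pytest.approx(0.0, abs=1e-10)


def test_education_gradient_requires_primary_reference():
    df = _cohort([1, 2, 3], ["tertiary"] * 3)
    with pytest.raises(DegenerateDataError, match="primary"):
        education_gradient(df, min_stratum_size=1)


# --- fitness curves and CI overlap ------------------------------------------


def _quadratic_fit(a, b, c, n=400, scale=0.2, seed=5):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    y = a + b * z + 0.5 * c * z**2 + rng.normal(scale=scale, size=n)
    return quadratic_gradient(y, z), z, y


def test_fitness_curve_prediction_and_peak():
    est, _, _ = _quadratic_fit(1.2, 0.0, -0.5, scale=1e-12)
    curve = fitness_curve(est, [0.0])
    assert curve["fit"].item() == pytest.approx(1.2, abs=1e-6)
    est2, _, _ = _quadratic_fit(1.0, 0.3, -0.2, scale=1e-12)
    assert curve_peak(est2) == pytest.approx(1.5, abs=1e-6)


def test_fitness_curve_band_matches_bootstrap():
    est, z, y = _quadratic_fit(1.0, 0.1, -0.3, n=400, scale=0.3)
    grid = np.array([-1.5, 0.0, 1.5])
    band = fitness_curve(est, grid)
    analytic_se = (band["ci_high"] - band["fit"]) / Z_CRIT
    rng = np.random.default_rng(99)
    preds = np.empty((2000, grid.size))
    X = np.column_stack([np.ones_like(z), z, z**2])
    G = np.column_stack([np.ones_like(grid), grid, grid**2])
    for b in range(2000):
        idx = rng.integers(0, len(z), len(z))
        coef = np.linalg.lstsq(X[idx], y[idx], rcond=None)[0]
        preds[b] = G @ coef
    boot_se = preds.std(axis=0, ddof=1)
    assert np.allclose(analytic_se, boot_se, rtol=0.2)


def test_fitness_curve_rejects_empty_grid():
    est, _, _ = _quadratic_fit(1.0, 0.0, -0.1)
    with pytest.raises(ValueError, match="empty"):
        fitness_curve(est, [])


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((0.10, 0.30), (0.35, 0.50), True),
        ((0.10, 0.30), (0.25, 0.40), False),
        ((0.10, 0.30), (0.30, 0.50), False),  # touching counts as overlap
        ((0.35, 0.50), (0.10, 0.30), True),  # symmetric
    ],
)
def test_ci_overlap_rule(a, b, expected):
    assert ci_overlap(a, b) is expected


def test_ci_overlap_rejects_malformed():
    with pytest.raises(ValueError):
        ci_overlap((0.5, 0.1), (0.0, 1.0))
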