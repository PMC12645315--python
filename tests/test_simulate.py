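"""Synthetic register generator: determinism, marginal fidelity, under-registration."""

import io

import numpy as np
import pandas as pd
import pytest

from regselect import scenarios
from regselect.register import validate_register, write_register
from regselect.simulate import (
    ConfigError,
    EducationBlock,
    SimulationConfig,
    StratumModel,
    SelectionTruth,
    apply_father_underregistration,
    config_from_dict,
    config_from_yaml,
    config_to_dict,
    config_to_yaml,
    simulate_register,
    truth_frame,
)


def _csv_bytes(df):
    buf = io.StringIO()
    write_register(df, buf)
    return buf.getvalue().encode()


def test_same_config_and_seed_byte_identical():
    cfg = scenarios.default_register_config(1_000, seed=7)
    a, _ = simulate_register(cfg)
    b, _ = simulate_register(scenarios.default_register_config(1_000, seed=7))
    assert _csv_bytes(a) == _csv_bytes(b)


def test_different_seed_differs():
    a, _ = simulate_register(scenarios.default_register_config(1_000, seed=7))
    b, _ = simulate_register(scenarios.default_register_config(1_000, seed=8))
    assert _csv_bytes(a) != _csv_bytes(b)


def test_extending_population_preserves_early_draws():
    small, _ = simulate_register(scenarios.default_register_config(500, seed=7))
    large, _ = simulate_register(scenarios.default_register_config(2_000, seed=7))
    pd.testing.assert_frame_equal(small, large.head(500))


def test_truth_sidecar_echoes_config():
    cfg = scenarios.default_register_config(100, seed=3)
    _, truth = simulate_register(cfg)
    row = truth.set_index(["sex", "education"]).loc[("F", "primary")]
    assert row["beta_AFB"] == -0.25
    assert row["gamma_IBI"] == -0.15
    assert row["seed"] == 3
    assert row["mean_children"] == cfg.stratum("F", "primary").mean_children


def test_generated_records_valid_and_filters_exercised(default_register):
    df, _, cfg = default_register
    validate_register(df)
    assert df["birth_year"].between(*cfg.birth_year_range).all()
    # deaths recorded only before age 15, so the survival filter has work to do
    deaths = df["age_at_death"].dropna()
    assert len(deaths) > 0 and (deaths < 15).all()


def test_marginal_fidelity(default_register):
    """Stratum means of AFB, offspring counts and education shares track the config."""
    df, truth, cfg = default_register
    timed = df.assign(AFB=(df["first_child_year"] - df["birth_year"]).astype("Float64").astype(float))
    for (sex, edu), sub in df.groupby(["sex", "education"]):
        m = cfg.stratum(sex, edu)
        parous = sub[sub["n_children"] >= 1]
        if len(parous) < 500:
            continue
        mean_w = parous["n_children"].mean()
        se_w = parous["n_children"].std(ddof=1) / np.sqrt(len(parous))
        assert abs(mean_w - m.mean_children) <= 3 * se_w + 0.02  # small floor/rounding slack
        afb = timed.loc[parous.index, "AFB"]
        se_afb = afb.std(ddof=1) / np.sqrt(len(afb))
        assert abs(afb.mean() - m.afb_mean) <= 3 * se_afb + 0.15  # whole-year rounding + age-15 clip
    # education shares within the 1960-1977 block
    late = df[df["birth_year"] >= 1960]
    shares = late["education"].value_counts(normalize=True)
    expected = cfg.education_blocks[2].probs
    for level, p in expected.items():
        se = np.sqrt(p * (1 - p) / len(late))
        assert abs(shares.get(level, 0.0) - p) <= 4 * se


def test_childlessness_rate_matches_config(default_register):
    df, _, cfg = default_register
    alive = df[df["age_at_death"].isna()]
    sub = alive[(alive["sex"] == "F") & (alive["education"] == "tertiary")]
    p = cfg.stratum("F", "tertiary").childless_prob
    rate = (sub["n_children"] == 0).mean()
    # childless flag plus nothing else: parity floor is 1, so zero counts only from the flag
    assert rate == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / len(sub)))


def test_fitness_floor_rarely_active_in_default_scenario(caplog):
    cfg = scenarios.default_register_config(50_000, seed=5)
    with caplog.at_level("WARNING", logger="regselect.simulate"):
        simulate_register(cfg)
    floor_msgs = [r for r in caplog.records if "fitness floor" in r.message]
    for r in floor_msgs:
        n_floor, n_parous = r.args[0], r.args[1]
        assert n_floor / n_parous < 0.001


def test_invalid_configs_rejected():
    base = scenarios.default_register_config(10, seed=1)
    bad = scenarios.default_register_config(10, seed=1)
    bad.sex_ratio = 1.5
    with pytest.raises(ConfigError, match="sex_ratio"):
        bad.validate()
    bad2 = scenarios.default_register_config(10, seed=1)
    bad2.stratum_overrides[("F", "primary")].selection["AFB"] = SelectionTruth(beta=0.9)
    with pytest.raises(ConfigError, match="beta"):
        bad2.validate()
    bad3 = scenarios.default_register_config(10, seed=1)
    bad3.education_blocks = bad3.education_blocks[:1]
    with pytest.raises(ConfigError, match="cover"):
        bad3.validate()
    assert base.seed == 1  # untouched original still valid
    base.validate()


def test_config_yaml_round_trip(tmp_path):
    cfg = scenarios.default_register_config(2_000, seed=42)
    path = tmp_path / "cfg.yaml"
    config_to_yaml(cfg, path)
    back = config_from_yaml(path)
    assert config_to_dict(back) == config_to_dict(cfg)
    a, _ = simulate_register(cfg)
    b, _ = simulate_register(back)
    assert _csv_bytes(a) == _csv_bytes(b)


def test_config_requires_seed():
    d = config_to_dict(scenarios.default_register_config(10, seed=1))
    d.pop("seed")
    with pytest.raises(ConfigError, match="seed"):
        config_from_dict(d)


# --- father under-registration ----------------------------------------------


def _males(default_register):
    df, _, _ = default_register
    return df


def test_unlink_identity_at_zero(default_register):
    df, _, _ = default_register
    out = apply_father_underregistration(df, {e: 0.0 for e in ("primary", "secondary")}, seed=1)
    pd.testing.assert_frame_equal(out, df)


def test_unlink_all_at_one(default_register):
    df, _, _ = default_register
    q = {e: 1.0 for e in ("primary", "secondary", "vocational", "tertiary", "unknown")}
    out = apply_father_underregistration(df, q, seed=1)
    males = out[out["sex"] == "M"]
    assert (males["n_children"] == 0).all()
    assert males["first_child_year"].isna().all()
    females = out[out["sex"] == "F"]
    pd.testing.assert_frame_equal(females, df[df["sex"] == "F"])


def test_unlink_binomial_expectation():
    cfg = scenarios.bias_demo_config(40_000, seed=9)
    df, _ = simulate_register(cfg)
    q = {e: 0.5 for e in ("primary", "secondary", "vocational", "tertiary", "unknown")}
    out = apply_father_underregistration(df, q, seed=9)
    fathers = df[(df["sex"] == "M") & (df["n_children"] >= 1)]
    linked = out.loc[fathers.index, "n_children"]
    total = int(fathers["n_children"].sum())
    se = np.sqrt(total * 0.25)
    assert abs(linked.sum() - 0.5 * total) <= 4 * se


def test_unlink_preserves_record_invariants(default_register):
    df, _, cfg = default_register
    out = apply_father_underregistration(df, {"primary": 0.4, "tertiary": 0.2}, seed=2)
    validate_register(out)


def test_unlink_rejects_bad_probability(default_register):
    df, _, _ = default_register
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        apply_father_underregistration(df, {"primary": 1.2}, seed=1)


def test_unlink_deterministic(default_register):
    df, _, _ = default_register
    a = apply_father_underregistration(df, {"primary": 0.3}, seed=5)
    b = apply_father_underregistration(df, {"primary": 0.3}, seed=5)
    pd.testing.assert_frame_equal(a, b)
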