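"""Ready-made simulation scenarios.

``default_register_config`` is the package's standing picture of a
register-like population: 1925-1977 cohorts, an education composition that
shifts from mostly-primary toward secondary/vocational/tertiary across cohort
blocks, stratum-specific childlessness and reproductive timing, moderate
directional selection for earlier first birth and mild stabilizing selection
on the interbirth pace, and education-dependent under-registration of
fatherhood.

The ``recovery_*`` scenarios are designed experiments for parameter recovery.
They bound the latent trait support and raise mean parity so the configured
linear/quadratic fitness function is a strictly positive conditional mean over
the whole trait range — with an unbounded normal trait, a gradient like
gamma = -0.40 would demand negative expected offspring counts beyond
|z| ~ 2.45, i.e. the configured truth would not be a realizable conditional
mean and there would be nothing well-defined to recover. They also set
structural childlessness to zero because timing traits exist only for parous
individuals: the truth is defined on the parous relative-fitness scale (see
docs/methods.md).
"""

from __future__ import annotations

from .simulate import EducationBlock, SelectionTruth, SimulationConfig, StratumModel

__all__ = [
    "default_register_config",
    "recovery_afb_config",
    "recovery_alb_config",
    "recovery_ibi_config",
    "null_config",
    "bias_demo_config",
]


def _default_blocks() -> list[EducationBlock]:
    # Secular expansion of post-primary education across cohort blocks.
    return [
        EducationBlock(1925, 1939, {"primary": 0.52, "secondary": 0.20, "vocational": 0.14, "tertiary": 0.07, "unknown": 0.07}),
        EducationBlock(1940, 1959, {"primary": 0.30, "secondary": 0.30, "vocational": 0.22, "tertiary": 0.13, "unknown": 0.05}),
        EducationBlock(1960, 1977, {"primary": 0.12, "secondary": 0.36, "vocational": 0.27, "tertiary": 0.22, "unknown": 0.03}),
    ]


def default_register_config(n_individuals: int = 100_000, seed: int = 0) -> SimulationConfig:
    """Register-like defaults.

    Parous mean counts are set so that full-stratum means (including the
    childless) land near 2.1 for primary-educated and 1.7 for
    tertiary-educated women, the observed order of completed fertility by
    education. Selection truths are moderate (|beta| <= 0.25, |gamma| <= 0.15)
    so the fitness floor stays essentially inactive (< 0.1% of parous draws)
    with an unbounded trait.
    """
    overrides = {
        ("F", "primary"): StratumModel(
            childless_prob=0.10, mean_children=2.38, afb_mean=21.5, afb_sd=3.8,
            ibi_mean=2.0, ibi_sd=0.6,
            selection={"AFB": SelectionTruth(beta=-0.25), "IBI": SelectionTruth(gamma=-0.15)},
        ),
        ("F", "secondary"): StratumModel(
            childless_prob=0.12, mean_children=2.15, afb_mean=23.0, afb_sd=4.0,
            selection={"AFB": SelectionTruth(beta=-0.18), "IBI": SelectionTruth(gamma=-0.12)},
        ),
        ("F", "vocational"): StratumModel(
            childless_prob=0.12, mean_children=2.15, afb_mean=23.2, afb_sd=4.0,
            selection={"AFB": SelectionTruth(beta=-0.18), "IBI": SelectionTruth(gamma=-0.12)},
        ),
        ("F", "tertiary"): StratumModel(
            childless_prob=0.18, mean_children=2.12, afb_mean=25.5, afb_sd=4.2,
            selection={"AFB": SelectionTruth(beta=-0.12), "IBI": SelectionTruth(gamma=-0.10)},
        ),
        ("F", "unknown"): StratumModel(
            childless_prob=0.15, mean_children=2.10, afb_mean=23.0, afb_sd=4.0,
            selection={"AFB": SelectionTruth(beta=-0.15), "IBI": SelectionTruth(gamma=-0.10)},
        ),
        ("M", "primary"): StratumModel(
            childless_prob=0.15, mean_children=2.45, afb_mean=24.5, afb_sd=4.5, ibi_mean=2.1,
            selection={"AFB": SelectionTruth(beta=-0.15), "IBI": SelectionTruth(gamma=-0.12)},
        ),
        ("M", "secondary"): StratumModel(
            childless_prob=0.15, mean_children=2.30, afb_mean=25.5, afb_sd=4.5, ibi_mean=2.1,
            selection={"AFB": SelectionTruth(beta=-0.15), "IBI": SelectionTruth(gamma=-0.12)},
        ),
        ("M", "vocational"): StratumModel(
            childless_prob=0.14, mean_children=2.35, afb_mean=25.5, afb_sd=4.5, ibi_mean=2.1,
            selection={"AFB": SelectionTruth(beta=-0.15), "IBI": SelectionTruth(gamma=-0.12)},
        ),
        ("M", "tertiary"): StratumModel(
            childless_prob=0.16, mean_children=2.40, afb_mean=27.0, afb_sd=4.4, ibi_mean=2.1,
            selection={"AFB": SelectionTruth(beta=-0.12), "IBI": SelectionTruth(gamma=-0.10)},
        ),
        ("M", "unknown"): StratumModel(
            childless_prob=0.16, mean_children=2.30, afb_mean=25.5, afb_sd=4.5, ibi_mean=2.1,
            selection={"AFB": SelectionTruth(beta=-0.12), "IBI": SelectionTruth(gamma=-0.10)},
        ),
    }
    return SimulationConfig(
        n_individuals=n_individuals,
        seed=seed,
        education_blocks=_default_blocks(),
        father_unlink_prob={"primary": 0.08, "secondary": 0.06, "vocational": 0.06, "tertiary": 0.04, "unknown": 0.08},
        default_stratum=StratumModel(),
        stratum_overrides=overrides,
        infant_death_prob=0.02,
    )


def _single_block(probs: dict[str, float]) -> list[EducationBlock]:
    return [EducationBlock(1925, 1977, probs)]


def recovery_afb_config(n_per_stratum: int = 50_000, seed: int = 0) -> SimulationConfig:
    """Directional-selection recovery on age at first birth (women).

    Two equal strata with identical trait and fertility distributions but
    different truths: beta = -0.30 (primary) and beta = -0.14 (tertiary).
    Bounded trait support (+-1.5 latent SD) with mean parity 4.5 keeps the
    conditional mean strictly positive and un-floored, so the OLS gradient of
    parous relative fitness on the cohort z-score targets the truth exactly.
    """
    common = dict(childless_prob=0.0, mean_children=4.5, afb_mean=23.0, afb_sd=4.0,
                  ibi_mean=1.2, ibi_sd=0.25)
    overrides = {
        ("F", "primary"): StratumModel(selection={"AFB": SelectionTruth(beta=-0.30)}, **common),
        ("F", "tertiary"): StratumModel(selection={"AFB": SelectionTruth(beta=-0.14)}, **common),
    }
    return SimulationConfig(
        n_individuals=2 * n_per_stratum,
        seed=seed,
        sex_ratio=0.0,
        infant_death_prob=0.0,
        trait_z_bound=1.5,
        education_blocks=_single_block({"primary": 0.5, "tertiary": 0.5}),
        default_stratum=StratumModel(**common),
        stratum_overrides=overrides,
    )


def recovery_alb_config(n_individuals: int = 50_000, seed: int = 0) -> SimulationConfig:
    """Directional-selection recovery on age at last birth: beta = +0.38.

    Timing is anchored on ALB (birth years are reconstructed backwards from the
    last birth), so the register-derived ALB reproduces the latent selected
    trait exactly.
    """
    stratum = StratumModel(
        childless_prob=0.0, mean_children=4.5, min_parity=1,
        afb_mean=23.0, afb_sd=4.0, ibi_mean=1.2, ibi_sd=0.25,
        alb_mean=32.0, alb_sd=4.0,
        selection={"ALB": SelectionTruth(beta=0.38)},
    )
    return SimulationConfig(
        n_individuals=n_individuals,
        seed=seed,
        sex_ratio=0.0,
        infant_death_prob=0.0,
        trait_z_bound=1.5,
        anchor_trait="ALB",
        education_blocks=_single_block({"primary": 1.0}),
        default_stratum=stratum,
        stratum_overrides={("F", "primary"): stratum},
    )


def recovery_ibi_config(n_individuals: int = 50_000, seed: int = 0) -> SimulationConfig:
    """Stabilizing-selection recovery on the interbirth interval: gamma = -0.40.

    Every parous individual has parity >= 2 (so the interval is defined for the
    whole sample) and mean parity 5.5, which keeps the quadratic conditional
    mean above the parity floor across the bounded trait support. The interval
    SD is generous (1.4 years) because the register records whole calendar
    years: the derived interval is round(IBI * n) / n, and its rounding noise
    must stay a negligible share of the trait variance or measured curvature
    attenuates.
    """
    stratum = StratumModel(
        childless_prob=0.0, mean_children=5.5, min_parity=2,
        afb_mean=20.0, afb_sd=2.5, ibi_mean=2.6, ibi_sd=1.4,
        selection={"IBI": SelectionTruth(gamma=-0.40)},
    )
    return SimulationConfig(
        n_individuals=n_individuals,
        seed=seed,
        sex_ratio=0.0,
        infant_death_prob=0.0,
        trait_z_bound=1.5,
        education_blocks=_single_block({"primary": 1.0}),
        default_stratum=stratum,
        stratum_overrides={("F", "primary"): stratum},
    )


def null_config(n_individuals: int = 5_000, seed: int = 0) -> SimulationConfig:
    """Flat fitness (no selection): the calibration scenario for CI coverage."""
    stratum = StratumModel(childless_prob=0.12, mean_children=2.2, afb_mean=23.0, afb_sd=4.0)
    return SimulationConfig(
        n_individuals=n_individuals,
        seed=seed,
        sex_ratio=0.0,
        infant_death_prob=0.0,
        education_blocks=_single_block({"primary": 1.0}),
        default_stratum=stratum,
        stratum_overrides={("F", "primary"): stratum},
    )


def bias_demo_config(n_individuals: int = 120_000, seed: int = 0) -> SimulationConfig:
    """Identical fitness in every stratum; used to isolate under-registration bias.

    All sex x education strata share one fertility and timing model and carry
    no selection, so any estimated education contrast is pure artefact of the
    father-child unlinking applied afterwards.
    """
    stratum = StratumModel(childless_prob=0.12, mean_children=2.3, afb_mean=24.0, afb_sd=4.0)
    return SimulationConfig(
        n_individuals=n_individuals,
        seed=seed,
        sex_ratio=0.5,
        infant_death_prob=0.0,
        education_blocks=_single_block(
            {"primary": 0.25, "secondary": 0.25, "vocational": 0.25, "tertiary": 0.25}
        ),
        default_stratum=stratum,
    )
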