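"""Synthetic population-register generator with known selection truths.

The generator emulates a national register extract: cohorts with a drifting
education composition, stratum-specific childlessness and reproductive-timing
distributions, offspring counts driven by a configurable linear/quadratic
fitness function of the standardized trait, and education-dependent
under-registration of father-child links.

Fitness model. Each parous individual carries latent standardized traits
``v_t`` (unit variance by construction). Expected offspring count is

    lambda = mean_children * max(eps, 1 + sum_t [beta_t*v_t + 0.5*gamma_t*(v_t**2 - 1)])

so that the stratum mean count is unchanged by gamma (the ``v**2 - 1`` term has
zero mean) and the regression of relative fitness on ``v`` targets ``beta_t``
directly. Counts are drawn as ``min_parity + Poisson(max(lambda - min_parity, 0))``,
which keeps the conditional mean exactly ``lambda`` wherever
``lambda >= min_parity`` — the property parameter-recovery experiments rely on.
Activations of the fitness floor ``eps`` and of the parity floor are logged.

Randomness. One shared seed keys a counter-based (Philox) substream per field,
with individuals consuming each stream in row order, so enlarging a population
never perturbs the draws of earlier individuals.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from .register import EDUCATION_LEVELS, REGISTER_COLUMNS, TRAITS, _coerce_dtypes

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Relative fitness floor: expected counts never fall below eps * mean_children.
FITNESS_FLOOR = 0.01

# Field ids for the per-field Philox substreams.
_F_BIRTH, _F_SEX, _F_EDU, _F_DEATH, _F_DEATH_AGE, _F_CHILDLESS = 1, 2, 3, 4, 5, 6
_F_Z_AFB, _F_Z_IBI, _F_Z_ALB, _F_COUNT, _F_UNLINK = 7, 8, 9, 10, 11


class ConfigError(ValueError):
    """Invalid simulation configuration (raised before any sampling)."""


@dataclass(frozen=True)
class SelectionTruth:
    """True gradients on the standardized-trait scale."""

    beta: float = 0.0
    gamma: float = 0.0


@dataclass
class StratumModel:
    """Per sex x education parameters of the generated population.

    ``mean_children`` is the mean offspring count among parous individuals;
    ``min_parity`` is the smallest parity a parous individual can have (2 for
    experiments that need the interbirth interval defined for everyone).
    ``afb_trend`` shifts the AFB mean linearly across cohorts (years per
    birth-year, centred on the cohort-window midpoint). ``alb_mean``/``alb_sd``
    are used only when the simulation anchors timing on ALB.
    """

    childless_prob: float = 0.12
    mean_children: float = 2.3
    min_parity: int = 1
    afb_mean: float = 23.5
    afb_sd: float = 4.0
    afb_trend: float = 0.0
    ibi_mean: float = 2.0
    ibi_sd: float = 0.6
    alb_mean: Optional[float] = None
    alb_sd: Optional[float] = None
    selection: dict[str, SelectionTruth] = field(default_factory=dict)

    def truth(self, trait: str) -> SelectionTruth:
        return self.selection.get(trait, SelectionTruth())


@dataclass
class EducationBlock:
    """Education-attainment probabilities for a block of birth cohorts."""

    from_year: int
    to_year: int
    probs: dict[str, float]


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic register (including the seed)."""

    n_individuals: int
    seed: int
    birth_year_range: tuple[int, int] = (1925, 1977)
    sex_ratio: float = 0.5  # probability of M
    infant_death_prob: float = 0.02
    fitness_floor: float = FITNESS_FLOOR
    #: Truncation of latent trait draws, in latent SDs; None = unbounded normal.
    trait_z_bound: Optional[float] = None
    #: Which timing trait the birth years are anchored on ("AFB" or "ALB").
    anchor_trait: str = "AFB"
    education_blocks: list[EducationBlock] = field(default_factory=list)
    father_unlink_prob: dict[str, float] = field(default_factory=dict)
    default_stratum: StratumModel = field(default_factory=StratumModel)
    stratum_overrides: dict[tuple[str, str], StratumModel] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def stratum(self, sex: str, education: str) -> StratumModel:
        return self.stratum_overrides.get((sex, education), self.default_stratum)

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals must be positive")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        y0, y1 = self.birth_year_range
        if y0 > y1:
            raise ConfigError("birth_year_range must be ordered")
        for name, p in (("sex_ratio", self.sex_ratio), ("infant_death_prob", self.infant_death_prob)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.anchor_trait not in ("AFB", "ALB"):
            raise ConfigError("anchor_trait must be AFB or ALB")
        if self.trait_z_bound is not None and self.trait_z_bound <= 0:
            raise ConfigError("trait_z_bound must be positive")
        if not self.education_blocks:
            raise ConfigError("at least one education block is required")
        covered = np.zeros(y1 - y0 + 1, dtype=int)
        for blk in self.education_blocks:
            unknown = set(blk.probs) - set(EDUCATION_LEVELS)
            if unknown:
                raise ConfigError(f"unknown education levels {sorted(unknown)}")
            total = sum(blk.probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"education probabilities sum to {total}, not 1")
            if any(p < 0 for p in blk.probs.values()):
                raise ConfigError("education probabilities must be non-negative")
            lo = max(blk.from_year, y0)
            hi = min(blk.to_year, y1)
            if lo <= hi:
                covered[lo - y0 : hi - y0 + 1] += 1
        if (covered != 1).any():
            raise ConfigError("education blocks must cover every birth year exactly once")
        for edu, q in self.father_unlink_prob.items():
            if edu not in EDUCATION_LEVELS:
                raise ConfigError(f"father_unlink_prob for unknown level {edu!r}")
            if not 0.0 <= q <= 1.0:
                raise ConfigError("father_unlink_prob values must be in [0, 1]")
        for key, model in self._all_strata().items():
            self._validate_stratum(key, model)

    def _all_strata(self) -> dict[tuple[str, str] | str, StratumModel]:
        out: dict = {"default": self.default_stratum}
        out.update(self.stratum_overrides)
        return out

    def _validate_stratum(self, key, m: StratumModel) -> None:
        if not 0.0 <= m.childless_prob <= 1.0:
            raise ConfigError(f"stratum {key}: childless_prob outside [0, 1]")
        if m.mean_children <= 0:
            raise ConfigError(f"stratum {key}: mean_children must be positive")
        if m.min_parity < 1:
            raise ConfigError(f"stratum {key}: min_parity must be >= 1")
        for sd_name in ("afb_sd", "ibi_sd"):
            if getattr(m, sd_name) <= 0:
                raise ConfigError(f"stratum {key}: {sd_name} must be positive")
        for trait, truth in m.selection.items():
            if trait not in TRAITS:
                raise ConfigError(f"stratum {key}: selection on unknown trait {trait!r}")
            if abs(truth.beta) > 0.4 or abs(truth.gamma) > 0.6:
                raise ConfigError(
                    f"stratum {key}: |beta| <= 0.4 and |gamma| <= 0.6 required "
                    "(keeps the fitness floor inactive)"
                )
            off_anchor = "ALB" if self.anchor_trait == "AFB" else "AFB"
            bad = m.truth(off_anchor)
            if bad.beta != 0.0 or bad.gamma != 0.0:
                raise ConfigError(
                    f"stratum {key}: selection on {off_anchor} requires anchor_trait={off_anchor}"
                )
        if self.anchor_trait == "ALB" and (m.alb_mean is None or m.alb_sd is None or m.alb_sd <= 0):
            raise ConfigError(f"stratum {key}: ALB anchoring needs alb_mean and positive alb_sd")


# ---------------------------------------------------------------------------
# (De)serialization


def _stratum_to_dict(m: StratumModel) -> dict:
    d = dataclasses.asdict(m)
    d["selection"] = {t: {"beta": s.beta, "gamma": s.gamma} for t, s in m.selection.items()}
    return d


def _stratum_from_dict(d: dict) -> StratumModel:
    d = dict(d)
    sel = {t: SelectionTruth(**s) for t, s in d.pop("selection", {}).items()}
    return StratumModel(selection=sel, **d)


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "schema_version": config.schema_version,
        "n_individuals": config.n_individuals,
        "seed": config.seed,
        "birth_year_range": list(config.birth_year_range),
        "sex_ratio": config.sex_ratio,
        "infant_death_prob": config.infant_death_prob,
        "fitness_floor": config.fitness_floor,
        "trait_z_bound": config.trait_z_bound,
        "anchor_trait": config.anchor_trait,
        "education_blocks": [dataclasses.asdict(b) for b in config.education_blocks],
        "father_unlink_prob": dict(config.father_unlink_prob),
        "default_stratum": _stratum_to_dict(config.default_stratum),
        "stratum_overrides": [
            {"sex": sex, "education": edu, **_stratum_to_dict(m)}
            for (sex, edu), m in config.stratum_overrides.items()
        ],
    }


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "seed" not in d or d["seed"] is None:
        raise ConfigError("config is missing required field 'seed'")
    if "n_individuals" not in d:
        raise ConfigError("config is missing required field 'n_individuals'")
    overrides = {}
    for o in d.pop("stratum_overrides", []):
        o = dict(o)
        key = (o.pop("sex"), o.pop("education"))
        overrides[key] = _stratum_from_dict(o)
    blocks = [EducationBlock(**b) for b in d.pop("education_blocks", [])]
    default = _stratum_from_dict(d.pop("default_stratum", {}))
    rng = d.pop("birth_year_range", [1925, 1977])
    cfg = SimulationConfig(
        n_individuals=int(d.pop("n_individuals")),
        seed=int(d.pop("seed")),
        birth_year_range=(int(rng[0]), int(rng[1])),
        education_blocks=blocks,
        default_stratum=default,
        stratum_overrides=overrides,
        **d,
    )
    cfg.validate()
    return cfg


def config_from_yaml(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def truth_frame(config: SimulationConfig) -> pd.DataFrame:
    """Per-stratum true parameters, echoed verbatim with the seed (the sidecar table)."""
    rows = []
    levels = sorted({lvl for blk in config.education_blocks for lvl, p in blk.probs.items() if p > 0})
    for sex in ("F", "M"):
        for edu in levels:
            m = config.stratum(sex, edu)
            row = {
                "sex": sex,
                "education": edu,
                "childless_prob": m.childless_prob,
                "mean_children": m.mean_children,
                "min_parity": m.min_parity,
                "afb_mean": m.afb_mean,
                "afb_sd": m.afb_sd,
                "afb_trend": m.afb_trend,
                "ibi_mean": m.ibi_mean,
                "ibi_sd": m.ibi_sd,
                "alb_mean": m.alb_mean,
                "alb_sd": m.alb_sd,
            }
            for trait in TRAITS:
                t = m.truth(trait)
                row[f"beta_{trait}"] = t.beta
                row[f"gamma_{trait}"] = t.gamma
            row["father_unlink_prob"] = config.father_unlink_prob.get(edu, 0.0)
            row["seed"] = config.seed
            row["schema_version"] = config.schema_version
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sampling machinery


def _stream(seed: int, field_id: int) -> np.random.Generator:
    """Counter-based substream keyed by (seed, field id)."""
    return np.random.Generator(np.random.Philox(key=np.array([seed, field_id], dtype=np.uint64)))


def _standard_normal(u: np.ndarray, bound: Optional[float]) -> tuple[np.ndarray, float]:
    """Map uniforms to (possibly truncated) standard-normal draws.

    Returns the draws and the SD of the truncated distribution, so callers can
    rescale to exactly unit variance.
    """
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    if bound is None:
        return ndtri(u), 1.0
    lo = ndtr(-bound)
    z = ndtri(lo + u * (1.0 - 2.0 * lo))
    # Var of standard normal truncated at +-b: 1 - 2*b*phi(b) / (2*Phi(b) - 1)
    phi_b = np.exp(-0.5 * bound * bound) / np.sqrt(2.0 * np.pi)
    var = 1.0 - 2.0 * bound * phi_b / (1.0 - 2.0 * lo)
    return z, float(np.sqrt(var))


def _row_params(sex: np.ndarray, edu: np.ndarray, config: SimulationConfig) -> dict[str, np.ndarray]:
    """All per-row stratum parameters at once (vectorized via a lookup table)."""
    pairs = pd.MultiIndex.from_arrays([sex, edu])
    uniq = pairs.unique()
    codes = uniq.get_indexer(pairs)
    attrs = [
        "childless_prob", "mean_children", "min_parity",
        "afb_mean", "afb_sd", "afb_trend", "ibi_mean", "ibi_sd",
    ]
    table: dict[str, np.ndarray] = {a: np.empty(len(uniq)) for a in attrs}
    for t in TRAITS:
        table[f"beta_{t}"] = np.empty(len(uniq))
        table[f"gamma_{t}"] = np.empty(len(uniq))
    table["alb_mean"] = np.zeros(len(uniq))
    table["alb_sd"] = np.ones(len(uniq))
    for j, (s, e) in enumerate(uniq):
        m = config.stratum(s, e)
        for a in attrs:
            table[a][j] = getattr(m, a)
        for t in TRAITS:
            truth = m.truth(t)
            table[f"beta_{t}"][j] = truth.beta
            table[f"gamma_{t}"][j] = truth.gamma
        if m.alb_mean is not None:
            table["alb_mean"][j] = m.alb_mean
            table["alb_sd"][j] = m.alb_sd
    return {name: arr[codes] for name, arr in table.items()}


def simulate_register(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a register and the truth table actually used.

    The same config and seed reproduce the dataset bit-for-bit.
    """
    config.validate()
    n = config.n_individuals
    seed = int(config.seed)
    y0, y1 = config.birth_year_range
    mid = 0.5 * (y0 + y1)

    birth_year = _stream(seed, _F_BIRTH).integers(y0, y1 + 1, size=n)
    sex = np.where(_stream(seed, _F_SEX).random(n) < config.sex_ratio, "M", "F")

    # Education: per-cohort-block attainment probabilities.
    blocks = config.education_blocks
    cum = np.zeros((len(blocks), len(EDUCATION_LEVELS)))
    for b, blk in enumerate(blocks):
        cum[b] = np.cumsum([blk.probs.get(lvl, 0.0) for lvl in EDUCATION_LEVELS])
    block_of_year = np.zeros(y1 - y0 + 1, dtype=int)
    for b, blk in enumerate(blocks):
        lo, hi = max(blk.from_year, y0), min(blk.to_year, y1)
        block_of_year[lo - y0 : hi - y0 + 1] = b
    row_cum = cum[block_of_year[birth_year - y0]]
    u_edu = _stream(seed, _F_EDU).random(n)
    edu_idx = (u_edu[:, None] < row_cum).argmax(axis=1)
    education = np.array(EDUCATION_LEVELS, dtype=object)[edu_idx]

    died = _stream(seed, _F_DEATH).random(n) < config.infant_death_prob
    death_age = _stream(seed, _F_DEATH_AGE).integers(0, 15, size=n)

    params = _row_params(sex, education, config)
    childless = _stream(seed, _F_CHILDLESS).random(n) < params["childless_prob"]
    parous = ~childless & ~died

    z_afb, s_trunc = _standard_normal(_stream(seed, _F_Z_AFB).random(n), config.trait_z_bound)
    z_ibi, _ = _standard_normal(_stream(seed, _F_Z_IBI).random(n), config.trait_z_bound)
    z_alb, _ = _standard_normal(_stream(seed, _F_Z_ALB).random(n), config.trait_z_bound)

    # Unit-variance latents on which the fitness function acts.
    v = {"AFB": z_afb / s_trunc, "ALB": z_alb / s_trunc, "IBI": z_ibi / s_trunc}
    fitness = np.ones(n)
    for t in TRAITS:
        fitness += params[f"beta_{t}"] * v[t] + 0.5 * params[f"gamma_{t}"] * (v[t] ** 2 - 1.0)

    floored = fitness < config.fitness_floor
    rate_full = params["mean_children"] * np.maximum(config.fitness_floor, fitness)
    min_parity = params["min_parity"]
    shifted = rate_full - min_parity
    parity_clipped = parous & (shifted < 0)
    n_floor, n_clip = int((floored & parous).sum()), int(parity_clipped.sum())
    n_parous = max(int(parous.sum()), 1)
    if n_floor:
        logger.warning(
            "simulate_register: fitness floor active for %d/%d parous individuals (%.3f%%)",
            n_floor, n_parous, 100.0 * n_floor / n_parous,
        )
    if n_clip:
        logger.info(
            "simulate_register: parity floor active for %d/%d parous individuals (%.3f%%)",
            n_clip, n_parous, 100.0 * n_clip / n_parous,
        )
    counts = min_parity.astype(int) + _stream(seed, _F_COUNT).poisson(np.maximum(shifted, 0.0))
    n_children = np.where(parous, counts, 0)

    # Timing: interbirth intervals and the anchored trait.
    ibi_raw = np.maximum(0.1, params["ibi_mean"] + params["ibi_sd"] * z_ibi)
    span = np.where(n_children >= 2, np.rint(ibi_raw * n_children), 0.0).astype(int)
    if config.anchor_trait == "AFB":
        afb_raw = params["afb_mean"] + params["afb_trend"] * (birth_year - mid) + params["afb_sd"] * z_afb
        afb = np.maximum(15, np.rint(afb_raw).astype(int))
        first = birth_year + afb
        last = first + span
    else:
        alb_raw = params["alb_mean"] + params["alb_sd"] * z_alb
        alb = np.maximum(16, np.rint(alb_raw).astype(int))
        span = np.clip(span, 0, alb - 15)
        last = birth_year + alb
        first = last - span

    person_id = np.array([f"I{i:07d}" for i in range(n)], dtype=object)
    df = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_year": birth_year.astype("int64"),
            "education": education,
            "n_children": n_children.astype("int64"),
            "first_child_year": pd.array(np.where(parous, first, 0), dtype="Int64"),
            "last_child_year": pd.array(np.where(parous, last, 0), dtype="Int64"),
            "age_at_death": pd.array(death_age, dtype="Int64"),
        }
    )
    df.loc[~parous, ["first_child_year", "last_child_year"]] = pd.NA
    df.loc[~died, "age_at_death"] = pd.NA
    return _coerce_dtypes(df[list(REGISTER_COLUMNS)]), truth_frame(config)


def apply_father_underregistration(
    df: pd.DataFrame,
    father_unlink_prob: dict[str, float],
    seed: int,
) -> pd.DataFrame:
    """Randomly unlink father-child links, per-child, with education-specific probability.

    Each child of a male record is dropped independently with probability
    ``q(education)``; counts and first/last child years are recomputed from the
    surviving children (a man losing every link becomes childless). Female
    records are never touched. Child birth years are reconstructed internally
    as evenly spaced between the recorded first and last births.
    """
    for edu, q in father_unlink_prob.items():
        if edu not in EDUCATION_LEVELS:
            raise ValueError(f"father_unlink_prob for unknown level {edu!r}")
        if not 0.0 <= q <= 1.0:
            raise ValueError("father_unlink_prob values must be in [0, 1]")
    out = df.copy()
    mask = (out["sex"] == "M") & (out["n_children"] >= 1)
    if not mask.any():
        return out
    males = out.loc[mask]
    W = males["n_children"].to_numpy(dtype=np.int64)
    first = males["first_child_year"].to_numpy(dtype=np.int64)
    last = males["last_child_year"].to_numpy(dtype=np.int64)
    q_row = males["education"].map(lambda e: father_unlink_prob.get(e, 0.0)).to_numpy(dtype=float)

    total = int(W.sum())
    row = np.repeat(np.arange(len(males)), W)
    offsets = np.concatenate([[0], np.cumsum(W)[:-1]])
    child_rank = np.arange(total) - np.repeat(offsets, W)
    denom = np.maximum(W - 1, 1)
    years = first[row] + np.rint((last - first)[row] * child_rank / denom[row]).astype(np.int64)

    keep = _stream(int(seed), _F_UNLINK).random(total) >= q_row[row]
    kept_n = np.bincount(row, weights=keep.astype(np.int64), minlength=len(males)).astype(np.int64)
    big = np.iinfo(np.int64).max
    new_first = np.minimum.reduceat(np.where(keep, years, big), offsets)
    new_last = np.maximum.reduceat(np.where(keep, years, -big), offsets)

    any_kept = kept_n > 0
    idx = males.index
    out.loc[idx, "n_children"] = kept_n
    fc = pd.array(np.where(any_kept, new_first, 0), dtype="Int64")
    lc = pd.array(np.where(any_kept, new_last, 0), dtype="Int64")
    fc[~any_kept] = pd.NA
    lc[~any_kept] = pd.NA
    out.loc[idx, "first_child_year"] = fc
    out.loc[idx, "last_child_year"] = lc
    logger.info(
        "apply_father_underregistration: %d of %d father-child links removed; %d men became childless",
        int(total - keep.sum()), total, int((~any_kept).sum()),
    )
    return out
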