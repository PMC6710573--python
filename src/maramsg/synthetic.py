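"""Synthetic census generator with known ground-truth pairwise attraction.

The field data behind this kind of analysis are rarely deposited, so every
downstream stage is validated against simulated censuses whose attraction
structure is known exactly.  The generator emulates a savannah herbivore
census: ~a dozen species with strongly unequal abundances, counts split over
three NDVI-defined ecological conditions (migrants present only in the low
condition), and per-session mixes of solitary individuals, single-species
groups and mixed-species groups (MSGs).

Group assembly works on the same building blocks the null models hold fixed:
each unit draws a species richness, recruits that many distinct species, and
draws an independent conspecific block size for each.  Recruitment is where
the ground truth enters: after a first species is drawn proportionally to
abundance weight, each further candidate C is drawn with probability
proportional to ``weight_C * gmean(theta[C, s] for s already recruited)``.
The geometric-mean form keeps ``theta == 1`` exactly neutral (the factor is
then 1 regardless of what was recruited first) and is insensitive to
recruitment order in expectation.  Block sizes are drawn independently of
partners: attraction acts on species co-presence, which is also what the
affinity index rewards through co-membership weighting.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .census import CensusSession, SocialUnit
from .errors import ConfigurationError

_GEN_CAP = 10_000  # resampling cap before declaring a config infeasible


@dataclass(frozen=True)
class SpeciesSpec:
    """One species: abundance weight, conspecific group-size model, migrancy.

    ``mean_block_size``/``dispersion`` parameterize a zero-truncated negative
    binomial for the number of conspecifics a unit's block contains; migratory
    species are only recruited in conditions flagged ``migrants_present``.
    """

    name: str
    weight: float
    mean_block_size: float = 5.0
    dispersion: float = 1.5
    migratory: bool = False

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ConfigurationError(f"{self.name}: weight must be positive")
        if self.mean_block_size < 1:
            raise ConfigurationError(f"{self.name}: mean_block_size must be >= 1")


@dataclass(frozen=True)
class ConditionSpec:
    """One ecological condition: session count, NDVI model, migrant flag."""

    label: str
    n_sessions: int
    ndvi_mean: float
    ndvi_sd: float
    ndvi_low: float
    ndvi_high: float
    migrants_present: bool
    theta: pd.DataFrame | None = None  # per-condition attraction override


@dataclass(frozen=True)
class GeneratorConfig:
    species: tuple[SpeciesSpec, ...]
    conditions: tuple[ConditionSpec, ...]
    units_per_session: float = 30.0
    richness_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    p_solitary_given_richness1: float = 0.4
    theta: pd.DataFrame | None = None  # base attraction matrix (1 = neutral)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate species names")
        probs = dict(self.richness_probs)
        if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
            raise ConfigurationError("richness probabilities must sum to 1")
        if any(r < 1 for r in probs):
            raise ConfigurationError("richness values must be >= 1")
        if not 0 <= self.p_solitary_given_richness1 <= 1:
            raise ConfigurationError("p_solitary_given_richness1 must be in [0, 1]")
        for theta in [self.theta] + [c.theta for c in self.conditions]:
            if theta is not None:
                _validate_theta(theta, names)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def theta_for(self, condition: ConditionSpec) -> pd.DataFrame:
        base = condition.theta if condition.theta is not None else self.theta
        if base is None:
            names = list(self.species_names)
            base = pd.DataFrame(1.0, index=names, columns=names)
        return base


def _validate_theta(theta: pd.DataFrame, names: Sequence[str]) -> None:
    missing = set(names) - set(theta.index)
    if missing or set(theta.index) != set(theta.columns):
        raise ConfigurationError("theta must index all species on both axes")
    M = theta.loc[list(names), list(names)].to_numpy(dtype=float)
    if (M <= 0).any():
        raise ConfigurationError("theta entries must be strictly positive")
    if not np.allclose(M, M.T):
        raise ConfigurationError("theta must be symmetric")
    if not np.allclose(np.diag(M), 1.0):
        raise ConfigurationError("theta must have unit diagonal")


def neutral_theta(names: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(1.0, index=list(names), columns=list(names))


def theta_with(
    names: Sequence[str], pairs: Mapping[tuple[str, str], float]
) -> pd.DataFrame:
    """Neutral theta with the given dyads set to the given attraction values."""
    t = neutral_theta(names)
    for (a, b), v in pairs.items():
        t.loc[a, b] = v
        t.loc[b, a] = v
    return t


@dataclass(frozen=True)
class GroundTruth:
    """The attraction structure a generated census was assembled under."""

    theta_by_condition: Mapping[str, pd.DataFrame]
    config: GeneratorConfig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, theta in self.theta_by_condition.items():
            names = list(theta.index)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    rows.append(
                        {
                            "condition": label, "species_a": a, "species_b": b,
                            "theta": float(theta.loc[a, b]),
                        }
                    )
        return pd.DataFrame(rows)


def _zt_negbinom(
    rng: np.random.Generator, mean: float, dispersion: float, minimum: int = 1
) -> int:
    """Zero-truncated negative binomial draw via Gamma-Poisson mixing."""
    if mean <= minimum:
        return minimum
    for _ in range(_GEN_CAP):
        lam = rng.gamma(dispersion, mean / dispersion)
        x = rng.poisson(lam)
        if x >= minimum:
            return int(x)
    return minimum


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(_GEN_CAP):
        x = rng.normal(mean, sd)
        if lo <= x < hi:
            return float(x)
    return float(np.clip(mean, lo, np.nextafter(hi, lo)))


def _recruit_species(
    rng: np.random.Generator,
    richness: int,
    weights: np.ndarray,
    theta: np.ndarray,
) -> list[int]:
    """Sequentially recruit ``richness`` distinct species indices."""
    chosen: list[int] = []
    available = np.ones(len(weights), dtype=bool)
    for _ in range(richness):
        w = weights.copy()
        w[~available] = 0.0
        if chosen:
            w *= np.exp(np.log(theta[:, chosen]).mean(axis=1))
            w[~available] = 0.0
        total = w.sum()
        idx = int(rng.choice(len(w), p=w / total))
        chosen.append(idx)
        available[idx] = False
    return chosen


def generate_census(
    config: GeneratorConfig,
) -> tuple[list[CensusSession], GroundTruth]:
    """Generate a full synthetic census; byte-identical for a given config."""
    rng = np.random.default_rng(config.seed)
    names = list(config.species_names)
    specs = {s.name: s for s in config.species}
    richness_vals = np.array(sorted(config.richness_probs))
    richness_p = np.array([config.richness_probs[r] for r in richness_vals])
    sessions: list[CensusSession] = []
    theta_by_condition: dict[str, pd.DataFrame] = {}
    base_date = _dt.date(2015, 9, 1)
    day = 0
    for cond in config.conditions:
        theta_df = config.theta_for(cond)
        theta_by_condition[cond.label] = theta_df
        eligible = [
            n for n in names if cond.migrants_present or not specs[n].migratory
        ]
        e_index = {n: k for k, n in enumerate(eligible)}
        weights = np.array([specs[n].weight for n in eligible], dtype=float)
        theta = theta_df.loc[eligible, eligible].to_numpy(dtype=float)
        max_richness = len(eligible)
        for s_i in range(cond.n_sessions):
            session_id = f"{cond.label}-{s_i:03d}"
            n_units = max(1, int(rng.poisson(config.units_per_session)))
            units: list[SocialUnit] = []
            for u_i in range(n_units):
                for _ in range(_GEN_CAP):
                    r = int(rng.choice(richness_vals, p=richness_p))
                    if r <= max_richness:
                        break
                else:
                    raise ConfigurationError(
                        f"cannot draw feasible richness <= {max_richness}"
                    )
                members = _recruit_species(rng, r, weights, theta)
                comp: dict[str, int] = {}
                if r == 1:
                    sp = eligible[members[0]]
                    if rng.random() < config.p_solitary_given_richness1:
                        comp[sp] = 1
                    else:
                        comp[sp] = _zt_negbinom(
                            rng, specs[sp].mean_block_size,
                            specs[sp].dispersion, minimum=2,
                        )
                else:
                    for m in members:
                        sp = eligible[m]
                        comp[sp] = _zt_negbinom(
                            rng, specs[sp].mean_block_size, specs[sp].dispersion
                        )
                units.append(SocialUnit(f"{session_id}-u{u_i:04d}", comp))
            ndvi = _truncated_normal(
                rng, cond.ndvi_mean, cond.ndvi_sd, cond.ndvi_low, cond.ndvi_high
            )
            sessions.append(
                CensusSession(
                    session_id=session_id,
                    date=base_date + _dt.timedelta(days=day),
                    ndvi=ndvi,
                    migrants_present=cond.migrants_present,
                    units=tuple(units),
                )
            )
            day += 16
    return sessions, GroundTruth(theta_by_condition, config)


def default_mara_config(seed: int = 0, scale: float = 1.0) -> GeneratorConfig:
    """Full-scale savannah-community configuration.

    Eleven resident species (strongly unequal abundances) plus a migratory
    wildebeest-like species active only under low NDVI; 27/12/27 sessions in
    the low/intermediate/high conditions; about 134 social units per session
    of which roughly 40 are solitary, 62 single-species groups and 32 MSGs in
    expectation.  A handful of dyads carry condition-dependent attraction so
    that the default census has recoverable preference/avoidance structure.
    ``scale`` < 1 shrinks session and unit counts proportionally for quick
    runs without changing per-unit structure.
    """
    species = (
        SpeciesSpec("Tho", 30.0, 12.0),
        SpeciesSpec("Gra", 6.0, 5.0),
        SpeciesSpec("Imp", 20.0, 11.0),
        SpeciesSpec("War", 4.0, 3.0),
        SpeciesSpec("Ost", 2.0, 2.0),
        SpeciesSpec("Top", 12.0, 8.0),
        SpeciesSpec("Har", 5.0, 5.0),
        SpeciesSpec("Zeb", 18.0, 10.0),
        SpeciesSpec("Buf", 6.0, 15.0),
        SpeciesSpec("Ela", 4.0, 6.0),
        SpeciesSpec("Gir", 3.0, 3.0),
        SpeciesSpec("Wil", 40.0, 35.0, migratory=True),
    )
    names = [s.name for s in species]
    # attraction structure: a persistent backbone shared by all conditions
    # (real communities keep most of their social structure year-round) plus
    # condition-dependent dyads — a rainfall-following dyad, a dry-season
    # dyad, and wildebeest attraction in the low condition
    backbone = {
        ("Imp", "Tho"): 5.0,
        ("Tho", "Top"): 4.0,
        ("Top", "Zeb"): 4.0,
        ("Gra", "Tho"): 3.0,
        ("Har", "Top"): 3.0,
        ("Imp", "Zeb"): 2.5,
        ("War", "Har"): 2.5,
        ("Buf", "Ost"): 0.3,
        ("Gir", "Tho"): 0.4,
        ("Buf", "Gra"): 0.4,
    }
    theta_low = theta_with(
        names,
        {
            **backbone,
            ("Ela", "Zeb"): 1.5,
            ("Gra", "Ost"): 3.0,
            ("Zeb", "Wil"): 4.0,
            ("Tho", "Wil"): 3.0,
            ("Top", "Wil"): 2.0,
        },
    )
    theta_int = theta_with(
        names, {**backbone, ("Ela", "Zeb"): 2.0}
    )
    theta_high = theta_with(
        names, {**backbone, ("Ela", "Zeb"): 4.0, ("War", "Top"): 2.5}
    )
    n_low, n_int, n_high = (
        max(1, round(27 * scale)), max(1, round(12 * scale)),
        max(1, round(27 * scale)),
    )
    conditions = (
        ConditionSpec("low", n_low, 3670, 550, 2500, 5000, True, theta_low),
        ConditionSpec("intermediate", n_int, 5155, 130, 5000, 5500, False, theta_int),
        ConditionSpec("high", n_high, 6627, 420, 5500, 7500, False, theta_high),
    )
    return GeneratorConfig(
        species=species,
        conditions=conditions,
        units_per_session=max(2.0, 134.0 * scale),
        richness_probs={1: 0.765, 2: 0.16, 3: 0.05, 4: 0.018, 5: 0.007},
        p_solitary_given_richness1=0.39,
        seed=seed,
    )


def small_test_config(
    n_species: int = 6,
    n_sessions: int = 8,
    units_per_session: float = 10.0,
    theta: pd.DataFrame | None = None,
    seed: int = 0,
    migrants: bool = False,
    conditions: Sequence[str] = ("low",),
) -> GeneratorConfig:
    """Compact single- or multi-condition config for simulations and tests."""
    base_names = ["S%02d" % i for i in range(n_species)]
    species = tuple(
        SpeciesSpec(n, weight=1.0 + 0.25 * i, mean_block_size=3.0 + (i % 3))
        for i, n in enumerate(base_names)
    )
    cond_params = {
        "low": (3670, 550, 2500, 5000, migrants),
        "intermediate": (5155, 130, 5000, 5500, False),
        "high": (6627, 420, 5500, 7500, False),
    }
    conds = tuple(
        ConditionSpec(label, n_sessions, *cond_params[label])
        for label in conditions
    )
    return GeneratorConfig(
        species=species,
        conditions=conds,
        units_per_session=units_per_session,
        richness_probs={1: 0.5, 2: 0.3, 3: 0.2},
        p_solitary_given_richness1=0.4,
        theta=theta,
        seed=seed,
    )


def config_to_yaml(config: GeneratorConfig) -> str:
    """Echo a generator configuration as YAML (thetas in long dyad form)."""
    def theta_entry(theta: pd.DataFrame | None):
        if theta is None:
            return None
        names = list(theta.index)
        return {
            f"{a}|{b}": float(theta.loc[a, b])
            for i, a in enumerate(names) for b in names[i + 1:]
            if float(theta.loc[a, b]) != 1.0
        }

    doc = {
        "seed": config.seed,
        "units_per_session": config.units_per_session,
        "richness_probs": {int(k): float(v) for k, v in config.richness_probs.items()},
        "p_solitary_given_richness1": config.p_solitary_given_richness1,
        "species": [
            {
                "name": s.name, "weight": s.weight,
                "mean_block_size": s.mean_block_size,
                "dispersion": s.dispersion, "migratory": s.migratory,
            }
            for s in config.species
        ],
        "theta": theta_entry(config.theta),
        "conditions": [
            {
                "label": c.label, "n_sessions": c.n_sessions,
                "ndvi_mean": c.ndvi_mean, "ndvi_sd": c.ndvi_sd,
                "ndvi_low": c.ndvi_low, "ndvi_high": c.ndvi_high,
                "migrants_present": c.migrants_present,
                "theta": theta_entry(c.theta),
            }
            for c in config.conditions
        ],
    }
    buf = io.StringIO()
    yaml.safe_dump(doc, buf, sort_keys=False)
    return buf.getvalue()
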