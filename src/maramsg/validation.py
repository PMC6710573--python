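"""Simulation experiments validating the statistical machinery.

Each function freezes one experimental design — data-generating configuration,
replicate counts, permutation counts — and returns a small result object, so
the test suite, the acceptance script and the analysis drivers all run the
same experiment.  Problem sizes were chosen to give the experiments clear
power while keeping a full run in minutes on one core; docs/methods.md
records them.

Experiments:

* ``sampler_gof`` — goodness of fit of sampled null distributions against
  exhaustive enumeration on a small census.
* ``calibration_experiment`` — type-I error of the one-tailed per-focal
  preference test on neutral (theta == 1) communities.
* ``change_recovery_experiment`` — power to detect a between-condition
  attraction contrast as a significant "up" change.
* ``monotone_recovery_experiment`` — monotone recovery of the affinity index
  across an attraction grid under shared random seeds.
* ``preference_power_experiment`` — power of the dyadic valence test under
  strong attraction.
* ``neutral_null_consistency`` — the exact-enumeration mean of W equals the
  sampler's mean on a tiny census.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .affinity import affinity_from_counts, pairwise_affinity
from .census import CensusSession, ConditionDataset, SocialUnit
from .nullmodels import (
    AffinityNull,
    ConditionSampler,
    change_test,
    exact_null_oracle,
)
from .synthetic import (
    ConditionSpec,
    GeneratorConfig,
    SpeciesSpec,
    generate_census,
    theta_with,
)

_NAMES6 = tuple("S%02d" % i for i in range(6))


def _six_species_config(
    theta=None, n_sessions=6, units_per_session=12.0, seed=0,
    richness_probs=None, label="low",
) -> GeneratorConfig:
    """Six moderately uneven species in one condition; the workhorse design."""
    species = tuple(
        SpeciesSpec(n, weight=1.0 + 0.25 * i, mean_block_size=3.0 + (i % 3))
        for i, n in enumerate(_NAMES6)
    )
    cond = ConditionSpec(label, n_sessions, 3670, 550, 2500, 5000, False)
    return GeneratorConfig(
        species=species,
        conditions=(cond,),
        units_per_session=units_per_session,
        richness_probs=richness_probs or {1: 0.5, 2: 0.3, 3: 0.2},
        p_solitary_given_richness1=0.4,
        theta=theta,
        seed=seed,
    )


def _as_condition(config: GeneratorConfig, label: str) -> ConditionDataset:
    sessions, _ = generate_census(config)
    return ConditionDataset(label, tuple(sessions))


# ---------------------------------------------------------------------------
# Sampler goodness of fit


def gof_toy_dataset() -> ConditionDataset:
    """Six-unit, three-species census; 2511 valid null arrangements."""
    units = (
        SocialUnit("u1", {"A": 2, "B": 1}),
        SocialUnit("u2", {"A": 1, "C": 1}),
        SocialUnit("u3", {"B": 2, "C": 1}),
        SocialUnit("u4", {"A": 1}),
        SocialUnit("u5", {"B": 1}),
        SocialUnit("u6", {"C": 2}),
    )
    sess = CensusSession("toy", _dt.date(2020, 1, 1), 3000.0, False, units)
    return ConditionDataset("low", (sess,))


@dataclass(frozen=True)
class GofResult:
    mode: str
    chi2: float
    p: float
    n_draws: int
    n_support: int


def sampler_gof(
    dataset: ConditionDataset | None = None,
    dyad: tuple[str, str] = ("A", "B"),
    n_draws: int = 30_000,
    seed: int = 0,
    mode: str = "auto",
    cap: int = 10**6,
) -> GofResult:
    """Chi-square GoF of the sampler's null of W_AB against enumeration.

    Support points with expected count below 5 are pooled into their
    neighbour so the chi-square approximation holds.
    """
    if dataset is None:
        dataset = gof_toy_dataset()
    a, b = dyad
    if (
        dataset.species_totals.get(a, 0) == 0
        or dataset.species_totals.get(b, 0) == 0
    ):
        from .errors import UndefinedStatisticError

        raise UndefinedStatisticError(
            f"dyad ({a}, {b}) unmeasurable in condition {dataset.label!r}"
        )
    exact = exact_null_oracle(dataset, lambda d: pairwise_affinity(d, a, b), cap=cap)
    sampler = ConditionSampler(dataset, mode=mode)
    rng = np.random.default_rng(seed)
    totals = np.array(
        [dataset.species_totals.get(sp, 0) for sp in sampler.species], dtype=float
    )
    ia = sampler.species.index(a)
    ib = sampler.species.index(b)
    counts: dict[float, int] = {}
    for _ in range(n_draws):
        assignment = sampler.sample_assignment(rng)
        U = sampler.unit_counts(assignment)
        W = affinity_from_counts(U, totals, dataset.community_total)
        v = round(float(W[ia, ib]), 12)
        counts[v] = counts.get(v, 0) + 1
    values = sorted(exact)
    observed = np.array([counts.get(v, 0) for v in values], dtype=float)
    expected = np.array([exact[v] * n_draws for v in values])
    # pool adjacent small-expectation bins
    obs_bins, exp_bins = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            obs_bins.append(acc_o)
            exp_bins.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp_bins:
        obs_bins[-1] += acc_o
        exp_bins[-1] += acc_e
    obs_arr = np.array(obs_bins)
    exp_arr = np.array(exp_bins)
    chi2, p = sps.chisquare(obs_arr, exp_arr * obs_arr.sum() / exp_arr.sum())
    return GofResult(
        mode=sampler.mode, chi2=float(chi2), p=float(p),
        n_draws=n_draws, n_support=len(values),
    )


def neutral_null_consistency(
    seed: int = 0, n_draws: int = 4000
) -> tuple[float, float, float]:
    """(exact mean, sampler mean, standard error) of W_AB on the toy census."""
    dataset = gof_toy_dataset()
    exact = exact_null_oracle(dataset, lambda d: pairwise_affinity(d, "A", "B"))
    exact_mean = sum(v * p for v, p in exact.items())
    sampler = ConditionSampler(dataset)
    rng = np.random.default_rng(seed)
    totals = np.array(
        [dataset.species_totals[sp] for sp in sampler.species], dtype=float
    )
    ia = sampler.species.index("A")
    ib = sampler.species.index("B")
    draws = np.empty(n_draws)
    for t in range(n_draws):
        U = sampler.unit_counts(sampler.sample_assignment(rng))
        draws[t] = affinity_from_counts(U, totals, dataset.community_total)[ia, ib]
    return exact_mean, float(draws.mean()), float(draws.std(ddof=1) / np.sqrt(n_draws))


# ---------------------------------------------------------------------------
# Type-I calibration


@dataclass(frozen=True)
class CalibrationResult:
    n_tests: int
    n_rejections: int
    alpha: float
    lo99: int  # 0.5% binomial quantile of the rejection count
    hi99: int  # 99.5% quantile

    @property
    def rate(self) -> float:
        return self.n_rejections / self.n_tests

    @property
    def within_band(self) -> bool:
        return self.lo99 <= self.n_rejections <= self.hi99


def calibration_experiment(
    n_datasets: int = 17,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> CalibrationResult:
    """Type-I error of the one-tailed per-focal preference test.

    Generates neutral six-species communities (theta == 1; 6 sessions of ~12
    units each) and runs the upper-tail test of the standardized affinity
    S_A(B) for every ordered focal-partner pair — 30 per dataset, 510 in the
    default design.  Under the null the rejection count should sit inside the
    central 99% band of Binomial(n_tests, alpha).
    """
    n_rej = 0
    n_tests = 0
    for k in range(n_datasets):
        cfg = _six_species_config(seed=seed * 10_000 + k)
        ds = _as_condition(cfg, "low")
        null = AffinityNull(ds, n_perm=n_perm, seed=seed * 10_000 + k)
        S = len(null.species)
        for i in range(S):
            for j in range(S):
                if i == j:
                    continue
                obs = null.observed.S[i, j]
                if np.isnan(obs):
                    continue
                draws = null.S_draws[:, i, j]
                valid = draws[~np.isnan(draws)]
                p_up = (1.0 + (valid >= obs).sum()) / (1.0 + valid.size)
                n_rej += p_up < alpha
                n_tests += 1
    lo = int(sps.binom.ppf(0.005, n_tests, alpha))
    hi = int(sps.binom.ppf(0.995, n_tests, alpha))
    return CalibrationResult(n_tests, int(n_rej), alpha, lo, hi)


# ---------------------------------------------------------------------------
# Recovery experiments


@dataclass(frozen=True)
class RecoveryResult:
    n_success: int
    n_replicates: int

    @property
    def rate(self) -> float:
        return self.n_success / self.n_replicates


def change_recovery_experiment(
    n_replicates: int = 100,
    theta_low: float = 1.0,
    theta_high: float = 6.0,
    n_sessions: int = 30,
    units_per_session: float = 25.0,
    n_perm: int = 499,
    alpha: float = 0.05,
    seed: int = 0,
) -> RecoveryResult:
    """Detection of an attraction contrast as a significant upward change.

    One dyad's attraction rises from ``theta_low`` to ``theta_high`` between
    two conditions (all else neutral); success means the change test reports
    direction "up" at the given alpha.
    """
    a, b = _NAMES6[0], _NAMES6[1]
    hits = 0
    for r in range(n_replicates):
        base = seed * 1_000_000 + 2 * r
        ds1 = _as_condition(
            _six_species_config(
                theta=theta_with(_NAMES6, {(a, b): theta_low}),
                n_sessions=n_sessions, units_per_session=units_per_session,
                seed=base,
            ),
            "low",
        )
        ds2 = _as_condition(
            _six_species_config(
                theta=theta_with(_NAMES6, {(a, b): theta_high}),
                n_sessions=n_sessions, units_per_session=units_per_session,
                seed=base + 1, label="high",
            ),
            "high",
        )
        n1 = AffinityNull(ds1, n_perm=n_perm, seed=base)
        n2 = AffinityNull(ds2, n_perm=n_perm, seed=base + 1)
        t = change_test(ds1, ds2, a, b, alpha=alpha, null1=n1, null2=n2, seed=r)
        hits += t.direction == "up"
    return RecoveryResult(int(hits), n_replicates)


def monotone_recovery_experiment(
    n_sets: int = 30,
    grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0),
    n_sessions: int = 60,
    units_per_session: float = 30.0,
    seed: int = 0,
) -> RecoveryResult:
    """Strict monotonicity of the estimated W_AB in the attraction theta_AB.

    Within a replicate set, the five datasets share a seed (common random
    numbers) and differ only in theta_AB; success means the estimated W_AB is
    strictly increasing along the grid.  Uses an MSG-rich design (richness
    probabilities 0.4/0.35/0.25) so the dyad is observed together often.
    """
    a, b = _NAMES6[0], _NAMES6[1]
    rich = {1: 0.4, 2: 0.35, 3: 0.25}
    hits = 0
    for r in range(n_sets):
        ws = []
        for th in grid:
            ds = _as_condition(
                _six_species_config(
                    theta=theta_with(_NAMES6, {(a, b): th}),
                    n_sessions=n_sessions, units_per_session=units_per_session,
                    seed=seed * 100_000 + r, richness_probs=rich,
                ),
                "low",
            )
            ws.append(pairwise_affinity(ds, a, b))
        hits += all(x < y for x, y in zip(ws, ws[1:]))
    return RecoveryResult(int(hits), n_sets)


def preference_power_experiment(
    n_replicates: int = 30,
    theta: float = 8.0,
    n_sessions: int = 16,
    units_per_session: float = 18.0,
    n_perm: int = 499,
    alpha: float = 0.05,
    seed: int = 0,
) -> RecoveryResult:
    """Power of the dyadic valence test under strong pairwise attraction."""
    from .nullmodels import dyad_valence_test

    a, b = _NAMES6[0], _NAMES6[1]
    hits = 0
    for r in range(n_replicates):
        ds = _as_condition(
            _six_species_config(
                theta=theta_with(_NAMES6, {(a, b): theta}),
                n_sessions=n_sessions, units_per_session=units_per_session,
                seed=seed * 1_000_000 + r,
            ),
            "low",
        )
        null = AffinityNull(ds, n_perm=n_perm, seed=r)
        t = dyad_valence_test(ds, a, b, alpha=alpha, null=null)
        hits += t.valence == "preference"
    return RecoveryResult(int(hits), n_replicates)


def theta_dominance_experiment(
    n_replicates: int = 100,
    theta: float = 8.0,
    n_sessions: int = 16,
    units_per_session: float = 18.0,
    seed: int = 0,
) -> RecoveryResult:
    """W of the attracted dyad exceeds the median W of all other dyads."""
    from .affinity import affinity_matrix

    a, b = _NAMES6[0], _NAMES6[1]
    hits = 0
    for r in range(n_replicates):
        ds = _as_condition(
            _six_species_config(
                theta=theta_with(_NAMES6, {(a, b): theta}),
                n_sessions=n_sessions, units_per_session=units_per_session,
                seed=seed * 1_000_000 + r,
            ),
            "low",
        )
        res = affinity_matrix(ds)
        i, j = res.index(a), res.index(b)
        iu = np.triu_indices(len(res.species), k=1)
        others = [
            res.W[x, y] for x, y in zip(*iu) if not (x == i and y == j)
        ]
        hits += res.W[i, j] > np.nanmedian(others)
    return RecoveryResult(int(hits), n_replicates)
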