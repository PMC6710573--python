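"""Constrained randomization of group membership and permutation tests.

The null hypothesis is that species associate at random given the observed
social organization.  A randomized dataset rebuilds every social unit by
reassigning conspecific *blocks* — a (species, group-size) parcel of
individuals — to unit skeletons, holding fixed, per ecological condition:

  (a) the total abundance of each species,
  (b) the multiset of conspecific block sizes of each species,
  (c) the number of social units, and
  (d) the multiset of per-unit species richness values

with no unit receiving two blocks of the same species.  Solitary individuals
are richness-1 skeletons whose single block moves like any other.

Two samplers draw uniformly from this constrained arrangement space:

* ``rejection`` — deal blocks uniformly at random into unit slots and reject
  arrangements with a conspecific collision.  Exactly uniform and i.i.d.;
  the acceptance rate falls with the number and richness of mixed units.
* ``mcmc`` — a Metropolis chain over block swaps between units (symmetric
  proposal, so the uniform distribution is stationary), started from the
  observed arrangement, with burn-in and thinning proportional to the number
  of blocks.  Used for instances where rejection becomes too slow.

The default ``auto`` mode probes the rejection acceptance rate and falls back
to the chain.  Both samplers are validated against exhaustive enumeration of
small instances (:func:`exact_null_oracle`).

Empirical p-values use the add-one convention p = (1 + #{null >= obs}) /
(1 + n), so p is never 0.  Dyadic valence tests use the standardized affinity
from each focal species and report the smaller p-value of the two focals;
between-condition change tests randomize each condition independently and
compare the paired difference; centrality tests are two-tailed on the
weighted degree.
"""

from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .affinity import affinity_from_counts, affinity_matrix
from .census import CensusSession, ConditionDataset, SocialUnit
from .errors import (
    ConfigurationError,
    EnumerationCapError,
    InfeasibleRandomizationError,
    MaramsgError,
    UndefinedStatisticError,
)

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 5000
DEFAULT_ALPHA = 0.05


def _swap_kernel_py(
    state: np.ndarray, contents: np.ndarray, block_species: np.ndarray,
    xs: np.ndarray, ys: np.ndarray,
) -> None:
    """Metropolis block-swap chain step kernel (see ConditionSampler).

    ``state`` maps block -> unit; ``contents`` is a unit x species membership
    matrix.  A proposal swaps the units of two blocks and is accepted unless
    it would put two conspecific blocks in one unit; the proposal is
    symmetric, so the uniform distribution over valid arrangements is
    stationary.
    """
    for t in range(xs.size):
        x, y = xs[t], ys[t]
        kx, ky = state[x], state[y]
        if kx == ky:
            continue
        sx, sy = block_species[x], block_species[y]
        if sx == sy:
            state[x], state[y] = ky, kx
            continue
        if contents[ky, sx] or contents[kx, sy]:
            continue
        state[x], state[y] = ky, kx
        contents[kx, sx] = False
        contents[kx, sy] = True
        contents[ky, sy] = False
        contents[ky, sx] = True


try:  # JIT-compile the hot loop when numba is available
    from numba import njit

    _swap_kernel = njit(cache=True)(_swap_kernel_py)
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    _swap_kernel = _swap_kernel_py


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic random substream for a master seed and a key tuple.

    Keyed by stable CRC32 hashes of the string forms of the keys, so adding
    further analyses never perturbs the draws of existing ones.
    """
    spawn_key = tuple(zlib.crc32(str(k).encode("utf-8")) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


# ---------------------------------------------------------------------------
# Constraints


@dataclass(frozen=True)
class RandomizationConstraints:
    """Record of the invariants every randomization preserves (all always on)."""

    preserve_species_totals: bool = True
    preserve_block_multiset: bool = True
    preserve_unit_count: bool = True
    preserve_richness_multiset: bool = True


def _block_multisets(dataset: ConditionDataset) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for u in dataset.units:
        for sp, n in u.composition.items():
            out.setdefault(sp, []).append(n)
    return {sp: sorted(v) for sp, v in out.items()}


def check_constraints(
    original: ConditionDataset, randomized: ConditionDataset
) -> dict[str, bool]:
    """Verify the four conservation constraints between two datasets."""
    checks = {
        "species_totals": original.species_totals == randomized.species_totals,
        "block_multiset": _block_multisets(original) == _block_multisets(randomized),
        "unit_count": len(original.units) == len(randomized.units),
        "richness_multiset": sorted(u.richness for u in original.units)
        == sorted(u.richness for u in randomized.units),
    }
    return checks


# ---------------------------------------------------------------------------
# Samplers


class ConditionSampler:
    """Uniform sampler over constrained rearrangements of one condition.

    Parameters
    ----------
    dataset:
        The observed condition; its units define blocks and skeletons.
    mode:
        ``"rejection"``, ``"mcmc"`` or ``"auto"`` (probe rejection first).
    mcmc_burnin, mcmc_thin:
        Chain steps before the first draw and between draws, as multiples of
        the number of blocks (defaults 30 and 8; see docs/methods.md).
    within_sessions:
        Restrict block movement to the session a unit was observed in (a
        stricter null preserving per-session species totals); default pools
        all units of the condition.
    """

    REJECTION_CAP = 100_000
    AUTO_PROBE_ATTEMPTS = 300
    AUTO_PROBE_SUCCESSES = 3

    def __init__(
        self,
        dataset: ConditionDataset,
        mode: str = "auto",
        mcmc_burnin: int = 30,
        mcmc_thin: int = 8,
        within_sessions: bool = False,
    ) -> None:
        if mode not in {"auto", "rejection", "mcmc"}:
            raise ConfigurationError(f"unknown sampler mode {mode!r}")
        self.dataset = dataset
        self.requested_mode = mode
        self.mode: str | None = None if mode == "auto" else mode
        units = dataset.units
        if not units:
            raise InfeasibleRandomizationError("condition has no units")
        self.species = dataset.species
        sp_index = {sp: j for j, sp in enumerate(self.species)}
        block_species: list[int] = []
        block_size: list[int] = []
        block_skel: list[int] = []
        caps: list[int] = []
        for k, u in enumerate(units):
            caps.append(u.richness)
            for sp, n in u.composition.items():
                block_species.append(sp_index[sp])
                block_size.append(n)
                block_skel.append(k)
        self.block_species = np.asarray(block_species, dtype=np.int64)
        self.block_size = np.asarray(block_size, dtype=np.int64)
        self.observed_skel = np.asarray(block_skel, dtype=np.int64)
        self.caps = np.asarray(caps, dtype=np.int64)
        self.n_blocks = len(self.block_species)
        self.n_units = len(units)
        # slot k repeated caps[k] times, grouped by skeleton
        self.slot_skel = np.repeat(np.arange(self.n_units), self.caps)
        self.within_sessions = within_sessions
        # contiguous block ranges per session (units iterate in session order)
        bounds = [0]
        for sess in dataset.sessions:
            bounds.append(bounds[-1] + sum(u.richness for u in sess.units))
        self._session_bounds = np.asarray(bounds, dtype=np.int64)
        starts = self._session_bounds[:-1]
        lens = np.diff(self._session_bounds)
        self._block_sess_start = np.repeat(starts, lens)
        self._block_sess_len = np.repeat(lens, lens)
        counts = np.bincount(self.block_species, minlength=len(self.species))
        if (counts > self.n_units).any():
            bad = [self.species[j] for j in np.flatnonzero(counts > self.n_units)]
            raise InfeasibleRandomizationError(
                "species with more conspecific blocks than units: " + ", ".join(bad)
            )
        self._burnin = mcmc_burnin * max(self.n_blocks, 1)
        self._thin = mcmc_thin * max(self.n_blocks, 1)
        self._chain_state: np.ndarray | None = None

    # -- rejection ---------------------------------------------------------

    def _permute_blocks(self, rng: np.random.Generator) -> np.ndarray:
        if not self.within_sessions:
            return rng.permutation(self.n_blocks)
        parts = [
            lo + rng.permutation(hi - lo)
            for lo, hi in zip(self._session_bounds[:-1], self._session_bounds[1:])
        ]
        return np.concatenate(parts)

    def _try_rejection(self, rng: np.random.Generator) -> np.ndarray | None:
        perm = self._permute_blocks(rng)
        key = self.slot_skel * len(self.species) + self.block_species[perm]
        key.sort()
        if (key[1:] == key[:-1]).any():
            return None
        assignment = np.empty(self.n_blocks, dtype=np.int64)
        assignment[perm] = self.slot_skel
        return assignment

    def _sample_rejection(self, rng: np.random.Generator) -> np.ndarray:
        for _ in range(self.REJECTION_CAP):
            a = self._try_rejection(rng)
            if a is not None:
                return a
        raise MaramsgError(
            f"rejection sampler exceeded {self.REJECTION_CAP} attempts; "
            "use mode='mcmc' for this instance"
        )

    # -- MCMC --------------------------------------------------------------

    def _mcmc_steps(
        self, state: np.ndarray, contents: np.ndarray, n_steps: int,
        rng: np.random.Generator,
    ) -> None:
        n = self.n_blocks
        xs = rng.integers(0, n, size=n_steps)
        if self.within_sessions:
            m = self._block_sess_len[xs]
            offs = rng.integers(0, np.maximum(m - 1, 1))
            ys = self._block_sess_start[xs] + offs
            ys += (ys >= xs) & (m > 1)
        else:
            ys = rng.integers(0, n - 1, size=n_steps)
            ys += ys >= xs
        _swap_kernel(state, contents, self.block_species, xs, ys)

    def _contents(self, state: np.ndarray) -> np.ndarray:
        contents = np.zeros((self.n_units, len(self.species)), dtype=np.bool_)
        contents[state, self.block_species] = True
        return contents

    def _sample_mcmc(self, rng: np.random.Generator) -> np.ndarray:
        if self._chain_state is None:
            self._chain_state = self.observed_skel.copy()
            self._chain_contents = self._contents(self._chain_state)
            self._mcmc_steps(self._chain_state, self._chain_contents, self._burnin, rng)
        self._mcmc_steps(self._chain_state, self._chain_contents, self._thin, rng)
        return self._chain_state.copy()

    # -- public ------------------------------------------------------------

    def _resolve_mode(self, rng: np.random.Generator) -> str:
        if self.mode is None:
            successes = 0
            for _ in range(self.AUTO_PROBE_ATTEMPTS):
                if self._try_rejection(rng) is not None:
                    successes += 1
                    if successes >= self.AUTO_PROBE_SUCCESSES:
                        break
            self.mode = "rejection" if successes >= self.AUTO_PROBE_SUCCESSES else "mcmc"
            log.debug(
                "condition %s: auto sampler chose %s", self.dataset.label, self.mode
            )
        return self.mode

    def sample_assignment(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one arrangement: skeleton index for every block."""
        mode = self._resolve_mode(rng)
        if mode == "rejection":
            return self._sample_rejection(rng)
        return self._sample_mcmc(rng)

    def unit_counts(self, assignment: np.ndarray) -> np.ndarray:
        """Units x species count matrix of an arrangement (species order fixed)."""
        U = np.zeros((self.n_units, len(self.species)), dtype=np.int64)
        np.add.at(U, (assignment, self.block_species), self.block_size)
        return U

    def to_dataset(self, assignment: np.ndarray) -> ConditionDataset:
        """Rebuild a full :class:`ConditionDataset` from an arrangement.

        Units keep their identifier and session; only their compositions move.
        """
        comps: list[dict[str, int]] = [dict() for _ in range(self.n_units)]
        for b, k in enumerate(assignment):
            comps[k][self.species[self.block_species[b]]] = int(self.block_size[b])
        new_sessions: list[CensusSession] = []
        k = 0
        for sess in self.dataset.sessions:
            new_units = []
            for u in sess.units:
                new_units.append(SocialUnit(u.unit_id, comps[k]))
                k += 1
            new_sessions.append(replace(sess, units=tuple(new_units)))
        return ConditionDataset(self.dataset.label, tuple(new_sessions))


def randomize_condition(
    dataset: ConditionDataset,
    rng: np.random.Generator | int | None = None,
    mode: str = "auto",
    within_sessions: bool = False,
) -> ConditionDataset:
    """One constrained randomization of group membership within a condition."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sampler = ConditionSampler(dataset, mode=mode, within_sessions=within_sessions)
    return sampler.to_dataset(sampler.sample_assignment(rng))


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle


def _blocks_by_species(dataset: ConditionDataset) -> dict[str, list[int]]:
    return _block_multisets(dataset)


def count_arrangements(dataset: ConditionDataset, cap: int = 10**6) -> int:
    """Count valid arrangements (same-species same-size blocks exchangeable).

    Dynamic program over the histogram of remaining unit capacities; raises
    :class:`EnumerationCapError` beyond ``cap``.
    """
    blocks = _blocks_by_species(dataset)
    caps = [u.richness for u in dataset.units]
    max_cap = max(caps)
    hist0 = tuple(caps.count(c) for c in range(max_cap + 1))
    species = sorted(blocks, key=lambda sp: -len(blocks[sp]))
    size_perm_mult = []
    for sp in species:
        sizes = blocks[sp]
        mult = math.factorial(len(sizes))
        for sz in set(sizes):
            mult //= math.factorial(sizes.count(sz))
        size_perm_mult.append(mult)
    memo: dict[tuple[int, tuple[int, ...]], int] = {}

    def rec(si: int, hist: tuple[int, ...]) -> int:
        if si == len(species):
            return 1
        key = (si, hist)
        if key in memo:
            return memo[key]
        b = len(blocks[species[si]])
        total = 0
        classes = [c for c in range(1, len(hist)) if hist[c] > 0]

        def distribute(ci: int, remaining: int, ways: int, h: list[int]) -> None:
            nonlocal total
            if remaining == 0:
                total += ways * rec(si + 1, tuple(h))
                if total > cap * 10:  # guard against runaway recursion
                    raise EnumerationCapError("arrangement count exceeds cap")
                return
            if ci == len(classes):
                return
            c = classes[ci]
            for k in range(0, min(hist[c], remaining) + 1):
                h2 = list(h)
                h2[c] -= k
                h2[c - 1] += k
                distribute(ci + 1, remaining - k, ways * math.comb(hist[c], k), h2)

        distribute(0, b, 1, list(hist))
        memo[key] = total
        return total

    total = rec(0, hist0)
    for m in size_perm_mult:
        total *= m
    if total > cap:
        raise EnumerationCapError(
            f"{total} arrangements exceed the enumeration cap of {cap}"
        )
    return total


def enumerate_arrangements(
    dataset: ConditionDataset, cap: int = 10**6
) -> Iterable[ConditionDataset]:
    """Yield every valid arrangement as a rebuilt dataset, each exactly once.

    Blocks of the same species and size are exchangeable: arrangements are
    distinguished only by which (species, size) blocks each labelled unit
    holds.  Counts first and refuses instances above ``cap``.
    """
    count_arrangements(dataset, cap=cap)  # raises if too large
    sampler = ConditionSampler(dataset, mode="rejection")
    blocks = _blocks_by_species(dataset)
    species = sorted(blocks, key=lambda sp: -len(blocks[sp]))
    n_units = sampler.n_units
    caps0 = list(sampler.caps)

    def rec(si: int, rem: list[int], partial: list[list[tuple[str, int]]]):
        if si == len(species):
            yield [list(p) for p in partial]
            return
        sp = species[si]
        sizes = blocks[sp]
        k = len(sizes)
        open_units = [j for j in range(n_units) if rem[j] > 0]
        if len(open_units) < k:
            return
        for subset in itertools.combinations(open_units, k):
            seen: set[tuple[int, ...]] = set()
            for perm in itertools.permutations(sizes):
                if perm in seen:
                    continue
                seen.add(perm)
                for j, sz in zip(subset, perm):
                    partial[j].append((sp, sz))
                    rem[j] -= 1
                yield from rec(si + 1, rem, partial)
                for j in subset:
                    partial[j].pop()
                    rem[j] += 1

    for arrangement in rec(0, caps0, [[] for _ in range(n_units)]):
        comps = [dict(p) for p in arrangement]
        assignment = np.empty(sampler.n_blocks, dtype=np.int64)
        # map back to an assignment vector for to_dataset
        b = 0
        taken: list[dict[str, int]] = comps
        # rebuild sessions directly
        new_sessions: list[CensusSession] = []
        k = 0
        for sess in dataset.sessions:
            new_units = []
            for u in sess.units:
                new_units.append(SocialUnit(u.unit_id, taken[k]))
                k += 1
            new_sessions.append(replace(sess, units=tuple(new_units)))
        yield ConditionDataset(dataset.label, tuple(new_sessions))


def exact_null_oracle(
    dataset: ConditionDataset,
    statistic_fn: Callable[[ConditionDataset], float],
    cap: int = 10**6,
    decimals: int = 12,
) -> dict[float, float]:
    """Exact null distribution of a statistic by exhaustive enumeration.

    Every constrained arrangement carries equal probability.  Statistic values
    are rounded to ``decimals`` places for use as dictionary keys.
    """
    counts: dict[float, int] = {}
    n = 0
    for arr in enumerate_arrangements(dataset, cap=cap):
        v = round(float(statistic_fn(arr)), decimals)
        counts[v] = counts.get(v, 0) + 1
        n += 1
    return {v: c / n for v, c in counts.items()}


# ---------------------------------------------------------------------------
# Ensembles and tests


@dataclass(frozen=True)
class NullEnsemble:
    """Draws of one statistic under the constrained randomization."""

    statistic_name: str
    observed: float
    draws: np.ndarray
    n_perm: int
    seed: int
    constraints: RandomizationConstraints = RandomizationConstraints()
    n_sentinel: int = 0
    unreliable: bool = False

    @property
    def valid_draws(self) -> np.ndarray:
        return self.draws[~np.isnan(self.draws)]

    def p_upper(self) -> float:
        v = self.valid_draws
        return (1.0 + (v >= self.observed).sum()) / (1.0 + v.size)

    def p_lower(self) -> float:
        v = self.valid_draws
        return (1.0 + (v <= self.observed).sum()) / (1.0 + v.size)


def build_null_ensemble(
    dataset: ConditionDataset,
    statistic_fn: Callable[[ConditionDataset], float],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    mode: str = "auto",
    statistic_name: str = "statistic",
) -> NullEnsemble:
    """Ensemble of a statistic over independent constrained randomizations."""
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    observed = float(statistic_fn(dataset))
    sampler = ConditionSampler(dataset, mode=mode)
    rng = substream(seed, dataset.label, statistic_name)
    draws = np.empty(n_perm)
    for t in range(n_perm):
        draws[t] = statistic_fn(sampler.to_dataset(sampler.sample_assignment(rng)))
    n_sent = int(np.isnan(draws).sum())
    unreliable = n_sent > 0.05 * n_perm
    if unreliable:
        log.warning(
            "%s: %d/%d sentinel draws, ensemble flagged unreliable",
            statistic_name, n_sent, n_perm,
        )
    return NullEnsemble(
        statistic_name, observed, draws, n_perm, seed,
        n_sentinel=n_sent, unreliable=unreliable,
    )


def _tail_ps(draws: np.ndarray, observed: float) -> tuple[float, float]:
    valid = draws[~np.isnan(draws)]
    n = valid.size
    p_up = (1.0 + (valid >= observed).sum()) / (1.0 + n)
    p_lo = (1.0 + (valid <= observed).sum()) / (1.0 + n)
    return float(p_up), float(p_lo)


class AffinityNull:
    """Null ensemble of whole affinity matrices for one condition.

    One randomization of group membership yields every dyad's statistic at
    once, so all dyadic, change and centrality tests within a condition share
    these draws (keyed by the master seed and the condition label).
    """

    def __init__(
        self,
        dataset: ConditionDataset,
        species: Sequence[str] | None = None,
        n_perm: int = DEFAULT_N_PERM,
        seed: int = 0,
        mode: str = "auto",
        within_sessions: bool = False,
    ) -> None:
        if n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        self.dataset = dataset
        self.observed = affinity_matrix(dataset, species)
        self.species = self.observed.species
        self.n_perm = n_perm
        self.seed = seed
        sampler = ConditionSampler(
            dataset, mode=mode, within_sessions=within_sessions
        )
        # restrict the sampler's species order to the requested list
        totals = np.array(
            [dataset.species_totals.get(sp, 0) for sp in self.species], dtype=float
        )
        n_tot = dataset.community_total
        rng = substream(seed, dataset.label, "affinity")
        S_count = len(self.species)
        col = {sp: j for j, sp in enumerate(self.species)}
        keep = np.array([sp in col for sp in sampler.species])
        remap = np.array([col.get(sp, -1) for sp in sampler.species])
        self.W_draws = np.empty((n_perm, S_count, S_count))
        for t in range(n_perm):
            assignment = sampler.sample_assignment(rng)
            U_full = sampler.unit_counts(assignment)
            U = np.zeros((sampler.n_units, S_count), dtype=np.int64)
            U[:, remap[keep]] = U_full[:, keep]
            self.W_draws[t] = affinity_from_counts(U, totals, n_tot)
        with np.errstate(invalid="ignore", divide="ignore"):
            sums = np.nansum(self.W_draws, axis=2, keepdims=True)
            self.S_draws = np.where(sums > 0, self.W_draws / sums, np.nan)
        self.sampler_mode = sampler.mode

    def index(self, sp: str) -> int:
        return self.observed.index(sp)


@dataclass(frozen=True)
class DyadTest:
    """Within-condition valence test for one dyad."""

    dyad: tuple[str, str]
    condition: str
    observed: Mapping[str, float]  # standardized affinity per focal
    p_upper: float
    p_lower: float
    valence: str  # preference | avoidance | none
    focal_used: str  # species name or "min-of-both"
    n_perm: int
    seed: int
    alpha: float = DEFAULT_ALPHA


@dataclass(frozen=True)
class ChangeTest:
    """Between-condition change test for one dyad."""

    dyad: tuple[str, str]
    conditions: tuple[str, str]
    delta: Mapping[str, float]  # observed delta-S per focal
    delta_reported: float  # delta of the minimum-p focal
    p: float
    direction: str  # up | down | ns  (up = higher in the second condition)
    focal_used: str
    n_perm: int
    seed: int
    alpha: float = DEFAULT_ALPHA


@dataclass(frozen=True)
class CentralityTest:
    """Two-tailed weighted-degree test for one species."""

    species: str
    condition: str
    observed: float
    null_mean: float
    deviation: float
    p: float
    n_perm: int
    seed: int
    alpha: float = DEFAULT_ALPHA


def dyad_valence_test(
    dataset: ConditionDataset,
    a: str,
    b: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "auto",
    null: AffinityNull | None = None,
    statistic: str = "standardized",
) -> DyadTest:
    """Test whether a dyad's affinity exceeds (or falls short of) the null.

    By default the statistic is the standardized affinity computed from each
    focal species; per tail the smaller of the two focals' p-values is
    reported, reflecting the strongest affinity signal.  Preference means the
    upper-tail p is below alpha; avoidance the lower tail.
    ``statistic="raw_w"`` tests the symmetric unstandardized index instead
    (one statistic, both focals identical), for sensitivity analysis.
    """
    if statistic not in {"standardized", "raw_w"}:
        raise ConfigurationError(f"unknown valence statistic {statistic!r}")
    if null is None:
        null = AffinityNull(dataset, n_perm=n_perm, seed=seed, mode=mode)
    try:
        i, j = null.index(a), null.index(b)
    except KeyError:
        raise UndefinedStatisticError(
            f"dyad ({a}, {b}): species missing from {dataset.label!r}"
        ) from None
    if np.isnan(null.observed.W[i, j]):
        raise UndefinedStatisticError(
            f"dyad ({a}, {b}) has no measurable affinity in {dataset.label!r}"
        )
    if statistic == "raw_w":
        obs = null.observed.W[i, j]
        matrix = null.W_draws
    else:
        matrix = null.S_draws
    results = {}
    for focal, (r, c) in {a: (i, j), b: (j, i)}.items():
        obs = null.observed.W[i, j] if statistic == "raw_w" else null.observed.S[r, c]
        if np.isnan(obs):
            continue
        pu, pl = _tail_ps(matrix[:, r, c], obs)
        results[focal] = (obs, pu, pl)
    if not results:
        raise UndefinedStatisticError(
            f"dyad ({a}, {b}): standardized affinity undefined for both focals"
        )
    p_upper = min(pu for _, pu, _ in results.values())
    p_lower = min(pl for _, _, pl in results.values())
    best = min(results, key=lambda f: min(results[f][1], results[f][2]))
    ps = {f: min(v[1], v[2]) for f, v in results.items()}
    focal_used = best if len(set(ps.values())) > 1 else "min-of-both"
    if p_upper < alpha:
        valence = "preference"
    elif p_lower < alpha:
        valence = "avoidance"
    else:
        valence = "none"
    return DyadTest(
        dyad=(a, b), condition=dataset.label,
        observed={f: v[0] for f, v in results.items()},
        p_upper=p_upper, p_lower=p_lower, valence=valence,
        focal_used=focal_used, n_perm=null.n_perm, seed=null.seed, alpha=alpha,
    )


def change_test(
    dataset1: ConditionDataset,
    dataset2: ConditionDataset,
    a: str,
    b: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "auto",
    null1: AffinityNull | None = None,
    null2: AffinityNull | None = None,
) -> ChangeTest:
    """Test a between-condition change in standardized affinity for one dyad.

    The null pairs independent randomizations of the two conditions and takes
    the difference of the standardized index (second minus first).  The test is
    two-tailed by tail doubling; the smaller of the two focals' p-values is
    reported, with the direction taken from that focal's observed difference.
    """
    if null1 is None:
        null1 = AffinityNull(dataset1, n_perm=n_perm, seed=seed, mode=mode)
    if null2 is None:
        null2 = AffinityNull(dataset2, n_perm=n_perm, seed=seed, mode=mode)
    if null1.n_perm != null2.n_perm:
        raise ConfigurationError("paired ensembles need equal n_perm")
    deltas: dict[str, tuple[float, float]] = {}
    for focal, partner in ((a, b), (b, a)):
        try:
            r1, c1 = null1.index(focal), null1.index(partner)
            r2, c2 = null2.index(focal), null2.index(partner)
        except KeyError:
            continue
        s1, s2 = null1.observed.S[r1, c1], null2.observed.S[r2, c2]
        if np.isnan(s1) or np.isnan(s2):
            continue
        obs = s2 - s1
        draw_delta = null2.S_draws[:, r2, c2] - null1.S_draws[:, r1, c1]
        pu, pl = _tail_ps(draw_delta, obs)
        p2 = min(1.0, 2.0 * min(pu, pl))
        deltas[focal] = (obs, p2)
    if not deltas:
        raise UndefinedStatisticError(
            f"dyad ({a}, {b}): standardized affinity undefined in one of "
            f"{dataset1.label!r}, {dataset2.label!r} for both focals"
        )
    best = min(deltas, key=lambda f: deltas[f][1])
    obs_best, p = deltas[best]
    if p < alpha and obs_best != 0:
        direction = "up" if obs_best > 0 else "down"
    else:
        direction = "ns"
    return ChangeTest(
        dyad=(a, b), conditions=(dataset1.label, dataset2.label),
        delta={f: v[0] for f, v in deltas.items()},
        delta_reported=obs_best, p=p, direction=direction,
        focal_used=best, n_perm=null1.n_perm, seed=seed, alpha=alpha,
    )


def centrality_test(
    dataset: ConditionDataset,
    species: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    mode: str = "auto",
    null: AffinityNull | None = None,
) -> CentralityTest:
    """Two-tailed test of a species' weighted degree against the null."""
    if null is None:
        null = AffinityNull(dataset, n_perm=n_perm, seed=seed, mode=mode)
    i = null.index(species)
    row = null.observed.W[i]
    if np.isnan(row).all():
        raise UndefinedStatisticError(
            f"species {species!r}: weighted degree unmeasurable (all sentinel)"
        )
    observed = float(np.nansum(row))
    draws = np.nansum(null.W_draws[:, i, :], axis=1)
    pu, pl = _tail_ps(draws, observed)
    p = min(1.0, 2.0 * min(pu, pl))
    null_mean = float(np.mean(draws))
    return CentralityTest(
        species=species, condition=dataset.label, observed=observed,
        null_mean=null_mean, deviation=observed - null_mean, p=p,
        n_perm=null.n_perm, seed=null.seed, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Bulk tables (share one AffinityNull per condition)


def valence_table(
    null: AffinityNull, alpha: float = DEFAULT_ALPHA
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Valence tests for every dyad of a condition; returns (table, skipped)."""
    rows, skipped = [], []
    for a, b in null.observed.dyads():
        try:
            t = dyad_valence_test(null.dataset, a, b, alpha=alpha, null=null)
        except UndefinedStatisticError:
            skipped.append((a, b))
            continue
        rows.append(
            {
                "condition": t.condition, "species_a": a, "species_b": b,
                "s_a_b": t.observed.get(a, np.nan),
                "s_b_a": t.observed.get(b, np.nan),
                "p_upper": t.p_upper, "p_lower": t.p_lower,
                "valence": t.valence, "focal_used": t.focal_used,
                "n_perm": t.n_perm, "seed": t.seed,
            }
        )
    return pd.DataFrame(rows), skipped


def change_table(
    null1: AffinityNull, null2: AffinityNull, alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Change tests for every dyad between two conditions."""
    rows, skipped = [], []
    species = sorted(set(null1.species) | set(null2.species))
    for a, b in itertools.combinations(species, 2):
        try:
            t = change_test(
                null1.dataset, null2.dataset, a, b,
                alpha=alpha, null1=null1, null2=null2, seed=seed,
            )
        except (UndefinedStatisticError, KeyError):
            skipped.append((a, b))
            continue
        rows.append(
            {
                "condition_1": t.conditions[0], "condition_2": t.conditions[1],
                "species_a": a, "species_b": b,
                "delta_s": t.delta_reported, "p": t.p,
                "direction": t.direction, "focal_used": t.focal_used,
                "n_perm": t.n_perm, "seed": t.seed,
            }
        )
    return pd.DataFrame(rows), skipped


def centrality_table(
    null: AffinityNull, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Weighted-degree centrality tests for every species of a condition."""
    rows = []
    for sp in null.species:
        try:
            t = centrality_test(null.dataset, sp, alpha=alpha, null=null)
        except UndefinedStatisticError:
            continue
        rows.append(
            {
                "condition": t.condition, "species": sp,
                "weighted_degree": t.observed, "null_mean": t.null_mean,
                "deviation": t.deviation, "p": t.p,
                "n_perm": t.n_perm, "seed": t.seed,
            }
        )
    return pd.DataFrame(rows)


# statistic helpers -----------------------------------------------------------


def dyad_w_statistic(a: str, b: str) -> Callable[[ConditionDataset], float]:
    """Statistic closure: raw affinity W_AB of a fixed dyad."""
    from .affinity import pairwise_affinity

    def stat(ds: ConditionDataset) -> float:
        return pairwise_affinity(ds, a, b)

    stat.__name__ = f"W_{a}_{b}"
    return stat


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional multiple-testing mode).

    Off by default throughout the pipeline, matching the convention of
    reporting raw permutation p-values at alpha = 0.05.
    """
    from statsmodels.stats.multitest import multipletests

    arr = np.asarray(pvals, dtype=float)
    out = np.full_like(arr, np.nan)
    ok = ~np.isnan(arr)
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out
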