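"""Abundance-controlled interspecific social affinity.

The pairwise index W_AB measures the average proportion of a social unit, as
experienced by an individual of species A, that consists of species B,
relative to B's share of the community at large::

    W_AB = [ sum over units i of N_iA * N_iB / (N_i - 1) ] * (N_tot - 1) / (N_A * N_B)

where N_iA is the count of species A in unit i, N_i the unit's size, and N_A,
N_B, N_tot the condition-wide totals.  The subtraction of 1 in both places
discounts the focal individual itself, so that the index is exactly 1 when
species mix at random, is symmetric in A and B, and is invariant to replicating
the whole dataset.  Units of size 1 contribute nothing (a solitary individual
experiences no groupmates).

For comparisons across conditions, each focal species' row is standardized to
S_A(B) = W_AB / sum_C W_AC, which controls for the species' overall propensity
to join mixed-species groups; standardized rows sum to 1 but are not symmetric.

Entries that are not measurable (a species absent from the condition, or the
focal species itself) carry the IEEE NaN sentinel — never 0, so "no affinity"
and "not measurable" stay distinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .census import ConditionDataset
from .errors import ConfigurationError, UndefinedStatisticError

log = logging.getLogger(__name__)

#: Sentinel for "not measurable" (species absent, diagonal, masked dyad).
UNDEFINED = float("nan")


def unit_species_matrix(
    dataset: ConditionDataset, species: Sequence[str]
) -> np.ndarray:
    """Units x species matrix of individual counts, in the given species order."""
    index = {sp: j for j, sp in enumerate(species)}
    U = np.zeros((len(dataset.units), len(species)), dtype=np.int64)
    for i, unit in enumerate(dataset.units):
        for sp, n in unit.composition.items():
            j = index.get(sp)
            if j is not None:
                U[i, j] = n
    return U


def affinity_from_counts(U: np.ndarray, totals: np.ndarray, n_tot: int) -> np.ndarray:
    """W matrix from a units-x-species count matrix and condition-wide totals.

    ``totals``/``n_tot`` are passed separately because a species list may cover
    species absent from ``U`` (NaN rows), and because the totals are condition
    properties that randomizations must hold fixed.
    """
    n_i = U.sum(axis=1)
    multi = n_i >= 2
    V = U[multi].astype(float)
    if V.size:
        weights = 1.0 / (n_i[multi] - 1.0)
        numer = (V * weights[:, None]).T @ V
        numer = 0.5 * (numer + numer.T)  # enforce exact (bitwise) symmetry
    else:
        numer = np.zeros((U.shape[1], U.shape[1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        W = numer * (n_tot - 1.0) / np.outer(totals, totals)
    W[totals == 0, :] = UNDEFINED
    W[:, totals == 0] = UNDEFINED
    np.fill_diagonal(W, UNDEFINED)
    return W


def pairwise_affinity(dataset: ConditionDataset, a: str, b: str) -> float:
    """W_AB for one dyad, evaluated directly from the unit list.

    Returns the NaN sentinel when either species is absent from the condition.
    Raises for a conspecific request: the index is defined across species only.
    """
    if a == b:
        raise ConfigurationError("conspecific affinity W_AA is not defined")
    n_a = dataset.species_totals.get(a, 0)
    n_b = dataset.species_totals.get(b, 0)
    if n_a == 0 or n_b == 0:
        return UNDEFINED
    acc = 0.0
    for unit in dataset.units:
        if unit.size >= 2:
            acc += unit.count(a) * unit.count(b) / (unit.size - 1)
    return acc * (dataset.community_total - 1) / (n_a * n_b)


def dyad_support(dataset: ConditionDataset, species: Sequence[str]) -> np.ndarray:
    """Per-dyad g: the number of units in which both species occur."""
    P = unit_species_matrix(dataset, species) > 0
    return (P.astype(np.int64).T @ P.astype(np.int64))


def standardize_affinity(w_row: np.ndarray) -> np.ndarray:
    """Standardize one focal species' affinity row: S_A(B) = W_AB / sum_C W_AC.

    Sentinel entries are excluded from the sum and stay sentinel.  An all-zero
    row (the focal never associates) has no defined standardization and comes
    back all-sentinel.
    """
    w_row = np.asarray(w_row, dtype=float)
    defined = ~np.isnan(w_row)
    total = w_row[defined].sum()
    out = np.full_like(w_row, UNDEFINED)
    if not defined.any() or total <= 0:
        if defined.any():
            log.warning("all-zero affinity row: focal never associates")
        return out
    out[defined] = w_row[defined] / total
    return out


@dataclass(frozen=True)
class AffinityResult:
    """Pairwise affinity matrices for one ecological condition.

    ``W`` is symmetric with NaN on the diagonal and for unmeasurable dyads;
    ``S`` holds the row-wise standardized index (row A is S_A(.)); ``support``
    holds the per-dyad number of shared units g.
    """

    condition: str
    species: tuple[str, ...]
    W: np.ndarray
    S: np.ndarray
    support: np.ndarray

    def index(self, sp: str) -> int:
        try:
            return self.species.index(sp)
        except ValueError:
            raise KeyError(f"species {sp!r} not in result") from None

    def w(self, a: str, b: str) -> float:
        return float(self.W[self.index(a), self.index(b)])

    def s(self, a: str, b: str) -> float:
        """Standardized affinity of focal a toward partner b."""
        return float(self.S[self.index(a), self.index(b)])

    def g(self, a: str, b: str) -> int:
        return int(self.support[self.index(a), self.index(b)])

    @property
    def n_dyads(self) -> int:
        """Number of unordered dyads with a defined W entry."""
        iu = np.triu_indices(len(self.species), k=1)
        return int((~np.isnan(self.W[iu])).sum())

    def dyads(self) -> list[tuple[str, str]]:
        """All unordered species pairs, defined or not."""
        return [
            (self.species[i], self.species[j])
            for i in range(len(self.species))
            for j in range(i + 1, len(self.species))
        ]

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered dyad."""
        rows = []
        for a, b in self.dyads():
            i, j = self.index(a), self.index(b)
            rows.append(
                {
                    "condition": self.condition,
                    "species_a": a,
                    "species_b": b,
                    "w": self.W[i, j],
                    "s_a_b": self.S[i, j],
                    "s_b_a": self.S[j, i],
                    "support_g": int(self.support[i, j]),
                }
            )
        return pd.DataFrame(rows)

    def to_matrix_frame(self, which: str = "w") -> pd.DataFrame:
        M = {"w": self.W, "s": self.S}[which]
        return pd.DataFrame(M, index=self.species, columns=self.species)


def affinity_matrix(
    dataset: ConditionDataset,
    species: Sequence[str] | None = None,
    min_support: int = 0,
) -> AffinityResult:
    """Compute W, S and dyad support for all species pairs in a condition.

    Species listed but absent from the condition yield sentinel entries (with a
    warning).  ``min_support`` optionally masks dyads seen together in fewer
    than that many units (0 keeps every dyad).
    """
    if species is None:
        species = dataset.species
    species = tuple(species)
    if not species:
        raise ConfigurationError("species list must be non-empty")
    if len(set(species)) != len(species):
        raise ConfigurationError("species list contains duplicates")
    missing = [sp for sp in species if dataset.species_totals.get(sp, 0) == 0]
    if missing:
        log.warning(
            "condition %s: species absent, affinity undefined: %s",
            dataset.label, ", ".join(missing),
        )
    U = unit_species_matrix(dataset, species)
    totals = np.array([dataset.species_totals.get(sp, 0) for sp in species])
    W = affinity_from_counts(U, totals, dataset.community_total)
    support = dyad_support(dataset, species)
    if min_support > 0:
        mask = (support < min_support) & ~np.eye(len(species), dtype=bool)
        W = W.copy()
        W[mask] = UNDEFINED
    S = np.vstack([standardize_affinity(W[i]) for i in range(len(species))])
    return AffinityResult(dataset.label, species, W, S, support)


def require_defined(value: float, what: str) -> float:
    if np.isnan(value):
        raise UndefinedStatisticError(f"{what} is not measurable (sentinel)")
    return value
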