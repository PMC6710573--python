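"""Census data model: social units, count sessions, ecological conditions.

A census consists of repeated count *sessions*; each session records a set of
*social units* (a solitary individual, a single-species group, or a
mixed-species group, MSG) with the number of individuals of each species in the
unit.  Sessions carry a per-session NDVI value (a satellite greenness proxy)
and a flag for the presence of migratory species; sessions are partitioned
into ecological conditions by binning NDVI.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyDatasetError,
    FormatError,
    ReferentialError,
    ValidationError,
)

log = logging.getLogger(__name__)

UNITS_COLUMNS = ("session_id", "unit_id", "species_id", "count")
SESSIONS_COLUMNS = ("session_id", "date", "ndvi", "migrants_present")


class UnitType(str, Enum):
    SOLITARY = "solitary"
    SINGLE_SPECIES = "single_species_group"
    MIXED_SPECIES = "mixed_species_group"


@dataclass(frozen=True)
class SocialUnit:
    """One observed social unit: species -> number of individuals (all >= 1)."""

    unit_id: str
    composition: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.composition:
            raise ValidationError(f"unit {self.unit_id!r}: empty composition")
        for sp, n in self.composition.items():
            if not isinstance(n, int) or isinstance(n, bool) or n < 1:
                raise ValidationError(
                    f"unit {self.unit_id!r}: count for {sp!r} must be a positive "
                    f"integer, got {n!r}"
                )
        object.__setattr__(self, "composition", dict(self.composition))

    @property
    def size(self) -> int:
        """Total number of individuals N_i in the unit."""
        return sum(self.composition.values())

    @property
    def richness(self) -> int:
        """Number of distinct species present."""
        return len(self.composition)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.composition)

    def count(self, species: str) -> int:
        """Individuals of *species* in the unit (0 if absent)."""
        return self.composition.get(species, 0)


def classify_unit_type(unit: SocialUnit) -> UnitType:
    """Classify a unit as solitary, single-species group, or MSG.

    Solitary iff one individual; single-species iff >= 2 individuals of a single
    species; mixed iff at least two species are present.
    """
    if unit.richness >= 2:
        return UnitType.MIXED_SPECIES
    if unit.size == 1:
        return UnitType.SOLITARY
    return UnitType.SINGLE_SPECIES


@dataclass(frozen=True)
class CensusSession:
    """One count session with its social units."""

    session_id: str
    date: _dt.date
    ndvi: float
    migrants_present: bool
    units: tuple[SocialUnit, ...]

    NDVI_RANGE = (0.0, 10000.0)

    def __post_init__(self) -> None:
        lo, hi = self.NDVI_RANGE
        if not lo <= self.ndvi <= hi:
            raise ValidationError(
                f"session {self.session_id!r}: NDVI {self.ndvi} outside "
                f"plausible range [{lo}, {hi}]"
            )
        object.__setattr__(self, "units", tuple(self.units))

    @property
    def total_individuals(self) -> int:
        return sum(u.size for u in self.units)


def _species_totals(units: Iterable[SocialUnit]) -> dict[str, int]:
    totals: dict[str, int] = {}
    for u in units:
        for sp, n in u.composition.items():
            totals[sp] = totals.get(sp, 0) + n
    return totals


@dataclass(frozen=True)
class ConditionDataset:
    """All sessions (and their pooled units) within one ecological condition."""

    label: str
    sessions: tuple[CensusSession, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sessions", tuple(self.sessions))

    @cached_property
    def units(self) -> tuple[SocialUnit, ...]:
        return tuple(u for s in self.sessions for u in s.units)

    @cached_property
    def species_totals(self) -> dict[str, int]:
        """Per-species total individual counts N_A within the condition."""
        return _species_totals(self.units)

    @property
    def community_total(self) -> int:
        """Total individuals N_tot across all units in the condition."""
        return sum(self.species_totals.values())

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.species_totals))

    def n_units(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class NdviBin:
    label: str
    lower: float
    upper: float
    closed_upper: bool = False

    def contains(self, x: float) -> bool:
        if self.closed_upper:
            return self.lower <= x <= self.upper
        return self.lower <= x < self.upper


#: Half-open NDVI bins [lower, upper); the last bin is closed at its upper edge.
DEFAULT_BINS: tuple[NdviBin, ...] = (
    NdviBin("low", 2500.0, 5000.0),
    NdviBin("intermediate", 5000.0, 5500.0),
    NdviBin("high", 5500.0, 7500.0, closed_upper=True),
)


def _validate_bins(bins: Sequence[NdviBin]) -> None:
    if not bins:
        raise ConfigurationError("at least one NDVI bin is required")
    for b in bins:
        if not b.lower < b.upper:
            raise ConfigurationError(f"bin {b.label!r}: lower must be < upper")
    ordered = sorted(bins, key=lambda b: b.lower)
    for a, b in zip(ordered, ordered[1:]):
        if b.lower < a.upper:
            raise ConfigurationError(
                f"bins {a.label!r} and {b.label!r} overlap "
                f"([{a.lower}, {a.upper}) vs [{b.lower}, {b.upper}))"
            )


def assign_condition(
    sessions: Iterable[CensusSession],
    bins: Sequence[NdviBin] = DEFAULT_BINS,
    migrant_rule: Mapping[bool, str] | None = None,
) -> dict[str, ConditionDataset]:
    """Partition sessions into ecological conditions by NDVI.

    Each session falls into the unique bin whose half-open interval contains its
    NDVI value.  ``migrant_rule`` optionally forces sessions to a named
    condition by their migrant flag (e.g. ``{True: "low"}``), overriding NDVI.
    Sessions outside every bin are excluded and reported via the log.
    """
    _validate_bins(bins)
    by_label: dict[str, list[CensusSession]] = {b.label: [] for b in bins}
    unassigned: list[str] = []
    for s in sessions:
        label = None
        if migrant_rule is not None and s.migrants_present in migrant_rule:
            label = migrant_rule[s.migrants_present]
            if label not in by_label:
                raise ConfigurationError(f"migrant_rule labels unknown bin {label!r}")
        else:
            for b in bins:
                if b.contains(s.ndvi):
                    label = b.label
                    break
        if label is None:
            unassigned.append(s.session_id)
        else:
            by_label[label].append(s)
    if unassigned:
        log.warning(
            "%d session(s) outside all NDVI bins, excluded: %s",
            len(unassigned),
            ", ".join(unassigned),
        )
    return {
        label: ConditionDataset(label, tuple(sess))
        for label, sess in by_label.items()
        if sess
    }


def condition_report(conditions: Mapping[str, ConditionDataset]) -> pd.DataFrame:
    """One row per condition: sessions, units, individuals, species richness."""
    rows = []
    for label, ds in conditions.items():
        rows.append(
            {
                "condition": label,
                "n_sessions": len(ds.sessions),
                "n_units": ds.n_units(),
                "n_individuals": ds.community_total,
                "n_species": len(ds.species_totals),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FilterPolicy:
    """Unit-level filters applied before analysis.

    ``max_unit_size`` drops super-herd aggregations larger than the threshold
    (default 2000 individuals; units of exactly the threshold size are kept).
    ``excluded_species`` are removed from unit compositions; with
    ``drop_units_containing_excluded`` the whole unit is dropped instead.
    """

    max_unit_size: int | None = 2000
    excluded_species: frozenset[str] = frozenset()
    drop_units_containing_excluded: bool = False

    def __post_init__(self) -> None:
        if self.max_unit_size is not None and self.max_unit_size <= 0:
            raise ConfigurationError("max_unit_size must be positive when set")
        object.__setattr__(
            self, "excluded_species", frozenset(self.excluded_species)
        )


@dataclass
class FilterReport:
    condition: str
    units_dropped: list[tuple[str, str, str]] = field(default_factory=list)
    individuals_removed: dict[str, int] = field(default_factory=dict)

    def note_drop(self, session_id: str, unit: SocialUnit, reason: str) -> None:
        self.units_dropped.append((session_id, unit.unit_id, reason))
        for sp, n in unit.composition.items():
            self.individuals_removed[sp] = self.individuals_removed.get(sp, 0) + n
        log.info("dropped unit %s (%s): %s", unit.unit_id, session_id, reason)

    def note_removed(self, session_id: str, unit_id: str, sp: str, n: int) -> None:
        self.individuals_removed[sp] = self.individuals_removed.get(sp, 0) + n
        log.info("removed %d %s from unit %s (%s)", n, sp, unit_id, session_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": self.condition, "kind": "unit_dropped",
             "session_id": s, "unit_id": u, "detail": r}
            for s, u, r in self.units_dropped
        ] + [
            {"condition": self.condition, "kind": "individuals_removed",
             "session_id": "", "unit_id": "", "detail": f"{sp}:{n}"}
            for sp, n in sorted(self.individuals_removed.items())
        ]
        return pd.DataFrame(
            rows, columns=["condition", "kind", "session_id", "unit_id", "detail"]
        )


def apply_filters(
    dataset: ConditionDataset, policy: FilterPolicy
) -> tuple[ConditionDataset, FilterReport]:
    """Apply a :class:`FilterPolicy`; totals are recomputed on the result.

    Returns the filtered dataset and a report of dropped units and removed
    individuals.  Raises :class:`EmptyDatasetError` if nothing survives.
    """
    report = FilterReport(dataset.label)
    new_sessions: list[CensusSession] = []
    for sess in dataset.sessions:
        kept: list[SocialUnit] = []
        for unit in sess.units:
            if policy.max_unit_size is not None and unit.size > policy.max_unit_size:
                report.note_drop(
                    sess.session_id, unit,
                    f"size {unit.size} > max_unit_size {policy.max_unit_size}",
                )
                continue
            excluded_here = policy.excluded_species & unit.species
            if excluded_here:
                if policy.drop_units_containing_excluded:
                    report.note_drop(
                        sess.session_id, unit,
                        "contains excluded species " + ",".join(sorted(excluded_here)),
                    )
                    continue
                remainder = {
                    sp: n for sp, n in unit.composition.items()
                    if sp not in policy.excluded_species
                }
                for sp in sorted(excluded_here):
                    report.note_removed(
                        sess.session_id, unit.unit_id, sp, unit.count(sp)
                    )
                if not remainder:
                    report.units_dropped.append(
                        (sess.session_id, unit.unit_id, "emptied by species exclusion")
                    )
                    continue
                unit = SocialUnit(unit.unit_id, remainder)
            kept.append(unit)
        if kept:
            new_sessions.append(replace(sess, units=tuple(kept)))
    if not new_sessions:
        raise EmptyDatasetError(
            f"condition {dataset.label!r}: filtering removed every unit"
        )
    return ConditionDataset(dataset.label, tuple(new_sessions)), report


def _parse_bool(value: object, context: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "t"}:
        return True
    if text in {"false", "0", "no", "f"}:
        return False
    raise ValidationError(f"{context}: cannot interpret {value!r} as a boolean")


def parse_census(units_path, sessions_path) -> list[CensusSession]:
    """Read the two-table census format (UTF-8 CSV, header required).

    The units table has one row per (session, unit, species) with an individual
    count; the sessions table has one row per count session with date, NDVI and
    a migrant-presence flag.  Every units row must reference a known session and
    every session must have at least one unit.
    """
    units_df = pd.read_csv(units_path, dtype=str)
    sessions_df = pd.read_csv(sessions_path, dtype=str)
    for col in UNITS_COLUMNS:
        if col not in units_df.columns:
            raise FormatError(f"units table is missing column {col!r}")
    for col in SESSIONS_COLUMNS:
        if col not in sessions_df.columns:
            raise FormatError(f"sessions table is missing column {col!r}")

    known_sessions = set(sessions_df["session_id"])
    compositions: dict[str, dict[str, dict[str, int]]] = {}
    for i, row in enumerate(units_df.itertuples(index=False), start=2):
        if row.session_id not in known_sessions:
            raise ReferentialError(
                f"units row {i}: unknown session_id {row.session_id!r}"
            )
        try:
            count = int(row.count)
        except (TypeError, ValueError):
            raise ValidationError(
                f"units row {i}: count {row.count!r} is not an integer"
            ) from None
        if count < 1:
            raise ValidationError(f"units row {i}: non-positive count {count}")
        unit_map = compositions.setdefault(row.session_id, {})
        comp = unit_map.setdefault(row.unit_id, {})
        comp[row.species_id] = comp.get(row.species_id, 0) + count

    sessions: list[CensusSession] = []
    for i, row in enumerate(sessions_df.itertuples(index=False), start=2):
        if row.session_id not in compositions:
            raise ValidationError(
                f"sessions row {i}: session {row.session_id!r} has no units"
            )
        try:
            ndvi = float(row.ndvi)
        except (TypeError, ValueError):
            raise ValidationError(
                f"sessions row {i}: NDVI {row.ndvi!r} is not numeric"
            ) from None
        date = _dt.date.fromisoformat(str(row.date))
        units = tuple(
            SocialUnit(uid, comp)
            for uid, comp in compositions[row.session_id].items()
        )
        sessions.append(
            CensusSession(
                session_id=row.session_id,
                date=date,
                ndvi=ndvi,
                migrants_present=_parse_bool(
                    row.migrants_present, f"sessions row {i}"
                ),
                units=units,
            )
        )
    return sessions


def write_census(
    sessions: Iterable[CensusSession], units_path, sessions_path
) -> None:
    """Write sessions back to the two-table CSV format (round-trip of parse)."""
    unit_rows = []
    sess_rows = []
    for s in sessions:
        sess_rows.append(
            {
                "session_id": s.session_id,
                "date": s.date.isoformat(),
                "ndvi": s.ndvi,
                "migrants_present": s.migrants_present,
            }
        )
        for u in s.units:
            for sp in sorted(u.composition):
                unit_rows.append(
                    {
                        "session_id": s.session_id,
                        "unit_id": u.unit_id,
                        "species_id": sp,
                        "count": u.composition[sp],
                    }
                )
    pd.DataFrame(unit_rows, columns=list(UNITS_COLUMNS)).to_csv(
        units_path, index=False
    )
    pd.DataFrame(sess_rows, columns=list(SESSIONS_COLUMNS)).to_csv(
        sessions_path, index=False
    )


def load_analysis_config(path) -> tuple[tuple[NdviBin, ...], FilterPolicy]:
    """Read NDVI bins and a filter policy from a YAML file.

    Expected structure::

        bins:
          - {label: low, lower: 2500, upper: 5000}
          - {label: intermediate, lower: 5000, upper: 5500}
          - {label: high, lower: 5500, upper: 7500, closed_upper: true}
        filter:
          max_unit_size: 2000
          excluded_species: [Wil]
          drop_units_containing_excluded: false

    Missing sections fall back to the defaults.
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if "bins" in doc:
        bins = tuple(
            NdviBin(
                label=str(b["label"]),
                lower=float(b["lower"]),
                upper=float(b["upper"]),
                closed_upper=bool(b.get("closed_upper", False)),
            )
            for b in doc["bins"]
        )
        _validate_bins(bins)
    else:
        bins = DEFAULT_BINS
    filt = doc.get("filter", {})
    policy = FilterPolicy(
        max_unit_size=filt.get("max_unit_size", 2000),
        excluded_species=frozenset(filt.get("excluded_species", ())),
        drop_units_containing_excluded=bool(
            filt.get("drop_units_containing_excluded", False)
        ),
    )
    return bins, policy
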