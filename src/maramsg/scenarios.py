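"""Six-scenario classification of seasonal affinity change.

A dyad's response to ecological conditions is summarized by three coded
change tests on the standardized affinity index — low vs intermediate NDVI,
low vs high NDVI, and intermediate vs high NDVI — each coded ``up``, ``down``
or ``ns``.  The triplet is mapped to one of six canonical scenarios:

1. affinity rises with NDVI (rainfall promotes affinity),
2. affinity falls with NDVI (rainfall reduces affinity),
3. affinity is depressed only under low NDVI, when migratory wildebeest are
   present (wildebeest presence or severe drought reduces affinity),
4. affinity is elevated only under low NDVI (wildebeest presence or drought
   promotes affinity),
5. affinity is lowest at intermediate NDVI (both wildebeest and heavy rain
   promote affinity),
6. affinity is highest at intermediate NDVI (both reduce affinity).

Rules are applied in priority order, V-shaped patterns (5, 6) first: a
significant reversal between adjacent conditions is their defining feature
and must not be absorbed by the monotone rules.  Scenarios 3 and 4 generalize
to any pattern with no intermediate-vs-high change and at least one
significant departure from the low condition in a consistent direction
(partial patterns such as (ns, up, ns) are a tie-broken interpretation and
are flagged).  Triplets with conflicting directions that no scenario explains
are labelled ``ambiguous``; a triplet with no significant change is ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .errors import ValidationError

DIRECTIONS = ("up", "down", "ns")

SCENARIO_INTERPRETATION = {
    1: "rainfall promotes social affinity",
    2: "rainfall reduces social affinity",
    3: "wildebeest presence or very low rainfall reduces social affinity",
    4: "wildebeest presence or very low rainfall promotes social affinity",
    5: "both wildebeest presence and high rainfall promote social affinity",
    6: "both wildebeest presence and high rainfall reduce social affinity",
}


@dataclass(frozen=True)
class ChangeTriplet:
    """Coded change-test outcomes for one dyad.

    ``d_li``, ``d_lh``, ``d_ih``: direction of the standardized-affinity
    change for low->intermediate, low->high and intermediate->high NDVI
    (``up`` = higher in the later/greener condition).
    """

    d_li: str
    d_lh: str
    d_ih: str
    valence_by_condition: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        for name in ("d_li", "d_lh", "d_ih"):
            if getattr(self, name) not in DIRECTIONS:
                raise ValidationError(
                    f"{name} must be one of {DIRECTIONS}, got {getattr(self, name)!r}"
                )

    def mirrored(self) -> "ChangeTriplet":
        flip = {"up": "down", "down": "up", "ns": "ns"}
        return ChangeTriplet(
            flip[self.d_li], flip[self.d_lh], flip[self.d_ih],
            self.valence_by_condition,
        )


@dataclass(frozen=True)
class ScenarioAssignment:
    dyad: tuple[str, str] | None
    scenario: int | str  # 1..6, "none" or "ambiguous"
    rule_fired: str
    tiebreak_used: bool

    @property
    def interpretation(self) -> str:
        return SCENARIO_INTERPRETATION.get(self.scenario, "")


def classify_scenario(
    t: ChangeTriplet, dyad: tuple[str, str] | None = None
) -> ScenarioAssignment:
    """Assign a change triplet to a scenario (see module docstring for rules)."""
    li, lh, ih = t.d_li, t.d_lh, t.d_ih
    if (li, lh, ih) == ("ns", "ns", "ns"):
        return ScenarioAssignment(dyad, "none", "R0", False)
    if li == "down" and ih == "up":
        return ScenarioAssignment(dyad, 5, "R5", False)
    if li == "up" and ih == "down":
        return ScenarioAssignment(dyad, 6, "R6", False)
    if ih == "up":
        if li != "down" and lh != "down":
            return ScenarioAssignment(dyad, 1, "R1", False)
        return ScenarioAssignment(dyad, "ambiguous", "R1-conflict", False)
    if ih == "down":
        if li != "up" and lh != "up":
            return ScenarioAssignment(dyad, 2, "R2", False)
        return ScenarioAssignment(dyad, "ambiguous", "R2-conflict", False)
    # ih is ns from here on
    ups = [d for d in (li, lh) if d == "up"]
    downs = [d for d in (li, lh) if d == "down"]
    if ups and not downs:
        partial = (li, lh) != ("up", "up")
        return ScenarioAssignment(dyad, 3, "R3", partial)
    if downs and not ups:
        partial = (li, lh) != ("down", "down")
        return ScenarioAssignment(dyad, 4, "R4", partial)
    return ScenarioAssignment(dyad, "ambiguous", "R-mixed", False)


def all_triplets() -> list[ChangeTriplet]:
    """All 27 possible change triplets."""
    return [
        ChangeTriplet(a, b, c)
        for a in DIRECTIONS for b in DIRECTIONS for c in DIRECTIONS
    ]


# ---------------------------------------------------------------------------
# Fixture table of published dyad outcomes


def load_reference_dyads() -> pd.DataFrame:
    """The packaged reference table of dyads with significant seasonal change.

    Hand-encoded from the published study's results table: one row per dyad
    with its per-condition valence codes, the three change directions, and the
    scenario label assigned in print.
    """
    path = resources.files("maramsg.data").joinpath("reference_dyads.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, dtype=str)


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a coded change table.

    Expects columns species_a, species_b, d_li, d_lh, d_ih (and optionally the
    per-condition valence columns valence_low, valence_intermediate,
    valence_high).  Returns the table with scenario, rule_fired and
    tiebreak_used columns appended.
    """
    out = table.copy()
    scenarios, rules, ties = [], [], []
    for row in table.itertuples(index=False):
        valence = None
        if hasattr(row, "valence_low"):
            valence = {
                "low": row.valence_low,
                "intermediate": row.valence_intermediate,
                "high": row.valence_high,
            }
        t = ChangeTriplet(row.d_li, row.d_lh, row.d_ih, valence)
        a = classify_scenario(t, dyad=(row.species_a, row.species_b))
        scenarios.append(str(a.scenario))
        rules.append(a.rule_fired)
        ties.append(a.tiebreak_used)
    out["scenario"] = scenarios
    out["rule_fired"] = rules
    out["tiebreak_used"] = ties
    return out


def scenario_counts(classified: pd.DataFrame) -> dict[str, int]:
    """Dyad counts per scenario label (keys '1'..'6', 'none', 'ambiguous')."""
    counts = {str(k): 0 for k in (1, 2, 3, 4, 5, 6)}
    counts["none"] = 0
    counts["ambiguous"] = 0
    for s in classified["scenario"]:
        counts[str(s)] = counts.get(str(s), 0) + 1
    return counts


def change_tests_to_triplets(changes: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long change-test table into one coded triplet row per dyad.

    Expects the output of :func:`maramsg.nullmodels.change_table` concatenated
    over the three condition pairs (low/intermediate, low/high,
    intermediate/high).
    """
    key_for = {
        ("low", "intermediate"): "d_li",
        ("low", "high"): "d_lh",
        ("intermediate", "high"): "d_ih",
    }
    rows: dict[tuple[str, str], dict[str, str]] = {}
    for r in changes.itertuples(index=False):
        pair = (r.condition_1, r.condition_2)
        if pair not in key_for:
            raise ValidationError(f"unexpected condition pair {pair}")
        dyad = (r.species_a, r.species_b)
        rows.setdefault(dyad, {"d_li": "ns", "d_lh": "ns", "d_ih": "ns"})[
            key_for[pair]
        ] = r.direction
    return pd.DataFrame(
        [
            {"species_a": a, "species_b": b, **codes}
            for (a, b), codes in sorted(rows.items())
        ]
    )
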