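#!/usr/bin/env python
"""Build per-condition social affinity networks from the generated census.

Reads results/data, bins sessions into ecological conditions by NDVI,
removes super-herds and the migratory species (resident branch), and computes
the abundance-controlled affinity matrix W and its standardized form S for
each condition.

Outputs: results/affinity_long.csv and per-condition matrix CSVs.
"""

from pathlib import Path

import pandas as pd

from maramsg.affinity import affinity_matrix
from maramsg.census import FilterPolicy, apply_filters, assign_condition, parse_census

ROOT = Path(__file__).resolve().parent.parent / "results"
ORDER = ("low", "intermediate", "high")


def main() -> None:
    sessions = parse_census(ROOT / "data" / "units.csv", ROOT / "data" / "sessions.csv")
    conditions = assign_condition(sessions)
    policy = FilterPolicy(excluded_species={"Wil"})
    residents = {}
    for label in ORDER:
        residents[label], report = apply_filters(conditions[label], policy)
        dropped = len(report.units_dropped)
        removed = report.individuals_removed.get("Wil", 0)
        print(
            f"{label}: {len(residents[label].units)} units kept "
            f"({dropped} units dropped, {removed} wildebeest removed)"
        )
    species = tuple(sorted(set().union(*(d.species for d in residents.values()))))
    frames = []
    for label in ORDER:
        res = affinity_matrix(residents[label], species=species)
        frames.append(res.to_long_frame())
        res.to_matrix_frame("w").reset_index(names="species").to_csv(
            ROOT / f"affinity_W_{label}.csv", index=False
        )
        top = (
            frames[-1].dropna(subset=["w"])
            .sort_values("w", ascending=False)
            .head(3)
        )
        pairs = ", ".join(
            f"{r.species_a}-{r.species_b} (W={r.w:.2f})" for r in top.itertuples()
        )
        print(f"  strongest affinities under {label} NDVI: {pairs}")
    pd.concat(frames, ignore_index=True).to_csv(
        ROOT / "affinity_long.csv", index=False
    )
    print(f"{len(species)} resident species, {len(species)*(len(species)-1)//2} dyads")


if __name__ == "__main__":
    main()
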