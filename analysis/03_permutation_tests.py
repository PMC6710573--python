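#!/usr/bin/env python
"""Permutation tests: dyadic valence, seasonal change, and centrality.

Randomizes group membership within each ecological condition (holding species
abundances, conspecific block-size distributions, unit counts and richness
structure fixed) and tests, per dyad, whether the standardized affinity is
higher or lower than expected by chance ("preference"/"avoidance"), whether
it changes between conditions, and whether each species' weighted degree
departs from the null.  A separate low-NDVI analysis keeps the wildebeest to
identify its preferred partners.

Reduced-replicate mode: 500 membership randomizations per condition (999 are
used for nothing heavier here; the library default is 5000).

Outputs: results/{valence_tests.csv, change_tests.csv, centrality_tests.csv,
migrant_partner_tests.csv}.
"""

import itertools
from pathlib import Path

import pandas as pd

from maramsg.census import FilterPolicy, apply_filters, assign_condition, parse_census
from maramsg.nullmodels import (
    AffinityNull,
    centrality_table,
    change_table,
    valence_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
ORDER = ("low", "intermediate", "high")
N_PERM = 500
SEED = 20160901


def main() -> None:
    sessions = parse_census(ROOT / "data" / "units.csv", ROOT / "data" / "sessions.csv")
    conditions = assign_condition(sessions)
    residents = {
        label: apply_filters(
            conditions[label], FilterPolicy(excluded_species={"Wil"})
        )[0]
        for label in ORDER
    }
    species = tuple(sorted(set().union(*(d.species for d in residents.values()))))
    nulls = {
        label: AffinityNull(
            residents[label], species=species, n_perm=N_PERM, seed=SEED
        )
        for label in ORDER
    }

    frames = []
    for label in ORDER:
        frame, skipped = valence_table(nulls[label])
        frames.append(frame)
        sig = frame[frame["valence"] != "none"]
        print(f"{label}: {len(sig)}/{len(frame)} dyads with significant valence")
    valence = pd.concat(frames, ignore_index=True)
    valence.to_csv(ROOT / "valence_tests.csv", index=False)

    frames = []
    for c1, c2 in itertools.combinations(ORDER, 2):
        frame, _ = change_table(nulls[c1], nulls[c2], seed=SEED)
        frames.append(frame)
        n_sig = (frame["direction"] != "ns").sum()
        print(f"{c1} vs {c2}: {n_sig}/{len(frame)} dyads changed significantly")
    changes = pd.concat(frames, ignore_index=True)
    changes.to_csv(ROOT / "change_tests.csv", index=False)

    cent = pd.concat(
        [centrality_table(nulls[label]) for label in ORDER], ignore_index=True
    )
    cent.to_csv(ROOT / "centrality_tests.csv", index=False)
    sig = cent[cent["p"] < 0.05]
    print(f"centrality: {len(sig)} significant species-condition deviations")

    # wildebeest partners: low condition with the migrant retained
    low_with_mig, _ = apply_filters(conditions["low"], FilterPolicy())
    mig_null = AffinityNull(low_with_mig, n_perm=N_PERM, seed=SEED)
    mig_frame, _ = valence_table(mig_null)
    mig_frame.to_csv(ROOT / "migrant_partner_tests.csv", index=False)
    wil = mig_frame[
        (
            (mig_frame["species_a"] == "Wil") | (mig_frame["species_b"] == "Wil")
        )
        & (mig_frame["valence"] == "preference")
    ]
    partners = [
        r.species_a if r.species_b == "Wil" else r.species_b
        for r in wil.itertuples()
    ]
    print(f"wildebeest preferred partners (low NDVI): {', '.join(partners) or 'none'}")


if __name__ == "__main__":
    main()
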