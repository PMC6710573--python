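#!/usr/bin/env python
"""Generate the synthetic savannah census the downstream analyses consume.

Emulates a year of group-composition counts over 11 resident herbivore
species plus a migratory wildebeest-like species: 27 low-NDVI sessions (with
migrants), 12 intermediate and 27 high, ~134 social units per session.  The
pairwise attraction structure used by the assembly model is written alongside
as ground truth.

Outputs: results/data/{units.csv, sessions.csv, ground_truth.csv,
generator_config.yaml}.
"""

from pathlib import Path

from maramsg.census import write_census
from maramsg.synthetic import config_to_yaml, default_mara_config, generate_census

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20160901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = default_mara_config(seed=SEED)
    sessions, truth = generate_census(config)
    write_census(sessions, OUT / "units.csv", OUT / "sessions.csv")
    truth.to_frame().to_csv(OUT / "ground_truth.csv", index=False)
    (OUT / "generator_config.yaml").write_text(config_to_yaml(config))
    n_units = sum(len(s.units) for s in sessions)
    n_ind = sum(s.total_individuals for s in sessions)
    print(
        f"wrote {len(sessions)} sessions, {n_units} social units, "
        f"{n_ind} individuals to {OUT}"
    )
    by_cond = {}
    for s in sessions:
        by_cond.setdefault(s.session_id.split("-")[0], []).append(s)
    for label, group in by_cond.items():
        mean_units = sum(len(s.units) for s in group) / len(group)
        print(f"  {label}: {len(group)} sessions, {mean_units:.1f} units/session")


if __name__ == "__main__":
    main()
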