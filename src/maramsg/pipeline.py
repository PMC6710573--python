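"""End-to-end analysis pipeline.

Sequences the full analysis from a single configuration: load (or generate)
census data, bin sessions into ecological conditions, filter super-herds,
compute affinity matrices, run dyadic valence and between-condition change
tests, classify seasonal scenarios, and summarize the network (weighted
degree and centrality tests, Mantel correlations, unit-type profiles with
Kruskal-Wallis comparisons).

Migratory species are handled on two strictly separate branches: the change
analyses use residents only (migrants removed from unit compositions before
any totals are computed), while a separate low-condition analysis keeps the
migrant to identify its preferred partners.  The two branches never share a
filtered dataset.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .affinity import affinity_matrix
from .census import (
    DEFAULT_BINS,
    ConditionDataset,
    FilterPolicy,
    NdviBin,
    apply_filters,
    assign_condition,
    condition_report,
    parse_census,
    write_census,
)
from .errors import ConfigurationError, MaramsgError
from .netstats import (
    degree_frame,
    edge_list,
    kruskal_table,
    mantel_affinity,
    unit_type_profile,
)
from .nullmodels import (
    AffinityNull,
    centrality_table,
    change_table,
    valence_table,
)
from .scenarios import (
    change_tests_to_triplets,
    classify_table,
    scenario_counts,
)
from .synthetic import GeneratorConfig, config_to_yaml, generate_census

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; the manifest reproduces it exactly."""

    output_dir: str | Path
    units_path: str | Path | None = None
    sessions_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    bins: Sequence[NdviBin] = DEFAULT_BINS
    filter_policy: FilterPolicy = FilterPolicy()
    migrant_species: frozenset[str] = frozenset({"Wil"})
    n_perm_dyads: int = 5000
    n_perm_mantel: int = 9999
    alpha: float = 0.05
    seed: int = 0
    sampler_mode: str = "auto"
    min_support: int = 0
    include_migrant_analysis: bool = True
    bh_correction: bool = False
    condition_order: tuple[str, ...] = ("low", "intermediate", "high")

    def __post_init__(self) -> None:
        if self.n_perm_dyads < 1 or self.n_perm_mantel < 1:
            raise ConfigurationError("permutation counts must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        synthetic = self.generator is not None
        files = self.units_path is not None and self.sessions_path is not None
        if synthetic == files:
            raise ConfigurationError(
                "provide either a generator config or both input paths"
            )
        object.__setattr__(self, "migrant_species", frozenset(self.migrant_species))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict[str, list[str]] = field(default_factory=dict)
    notes: dict[str, object] = field(default_factory=dict)

    def record(self, stage: str, *outputs: Path) -> None:
        self.stages.setdefault(stage, []).extend(p.name for p in outputs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "package_version": __version__,
                "python": platform.python_version(),
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stages": self.stages,
                "notes": self.notes,
            },
            indent=2,
            sort_keys=True,
        )


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis; every stage's outputs land in ``output_dir``.

    Returns the run manifest (also written as ``manifest.json``).  A failing
    stage aborts with its name; outputs of completed stages are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_repr = repr(config) + (
        config_to_yaml(config.generator) if config.generator else ""
    )
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_repr.encode()).hexdigest()[:16],
        seed=config.seed,
    )
    stage = "load"
    try:
        # 1 -- load or generate ------------------------------------------
        if config.generator is not None:
            sessions, truth = generate_census(config.generator)
            units_path, sessions_path = out / "units.csv", out / "sessions.csv"
            write_census(sessions, units_path, sessions_path)
            _write(truth.to_frame(), out / "ground_truth.csv")
            (out / "generator_config.yaml").write_text(
                config_to_yaml(config.generator)
            )
            manifest.record(
                stage, units_path, sessions_path,
                out / "ground_truth.csv", out / "generator_config.yaml",
            )
        else:
            sessions = parse_census(config.units_path, config.sessions_path)
            manifest.record(stage)
        manifest.notes["n_sessions"] = len(sessions)

        # 2 -- condition assignment --------------------------------------
        stage = "conditions"
        conditions = assign_condition(sessions, bins=config.bins)
        manifest.record(stage, _write(condition_report(conditions), out / "condition_report.csv"))

        # 3 -- filters: resident and migrant-included branches -----------
        stage = "filters"
        resident_policy = FilterPolicy(
            max_unit_size=config.filter_policy.max_unit_size,
            excluded_species=config.filter_policy.excluded_species
            | config.migrant_species,
            drop_units_containing_excluded=config.filter_policy.drop_units_containing_excluded,
        )
        residents: dict[str, ConditionDataset] = {}
        reports = []
        for label, ds in conditions.items():
            filtered, report = apply_filters(ds, resident_policy)
            residents[label] = filtered
            reports.append(report.to_frame())
        migrant_branch: dict[str, ConditionDataset] = {}
        if config.include_migrant_analysis:
            for label, ds in conditions.items():
                if not any(s.migrants_present for s in ds.sessions):
                    continue
                filtered, report = apply_filters(ds, config.filter_policy)
                migrant_branch[label] = filtered
                reports.append(report.to_frame())
        manifest.record(
            stage, _write(pd.concat(reports, ignore_index=True), out / "filter_report.csv")
        )

        # 4 -- affinity matrices -----------------------------------------
        stage = "affinity"
        order = [c for c in config.condition_order if c in residents]
        order += [c for c in residents if c not in order]
        # one shared species ordering across conditions, so change tests and
        # Mantel comparisons line up; absentees carry the sentinel
        species_union = tuple(
            sorted(set().union(*(residents[c].species for c in order)))
        )
        affinities = {
            label: affinity_matrix(
                residents[label], species=species_union,
                min_support=config.min_support,
            )
            for label in order
        }
        long = pd.concat(
            [a.to_long_frame() for a in affinities.values()], ignore_index=True
        )
        outputs = [_write(long, out / "affinity_long.csv")]
        for label, a in affinities.items():
            outputs.append(
                _write(
                    a.to_matrix_frame("w").reset_index(names="species"),
                    out / f"affinity_W_{label}.csv",
                )
            )
        manifest.record(stage, *outputs)

        # 5 -- valence tests ---------------------------------------------
        stage = "valence"
        nulls = {
            label: AffinityNull(
                residents[label], species=species_union,
                n_perm=config.n_perm_dyads,
                seed=config.seed, mode=config.sampler_mode,
            )
            for label in order
        }
        valence_frames, skipped = [], {}
        for label in order:
            frame, sk = valence_table(nulls[label], alpha=config.alpha)
            valence_frames.append(frame)
            if sk:
                skipped[label] = sk
        valence = pd.concat(valence_frames, ignore_index=True)
        if config.bh_correction:
            from .nullmodels import benjamini_hochberg

            valence["p_upper_adj"] = benjamini_hochberg(valence["p_upper"])
            valence["p_lower_adj"] = benjamini_hochberg(valence["p_lower"])
        outputs = [_write(valence, out / "valence_tests.csv")]
        if migrant_branch:
            mig_frames = []
            for label, ds in migrant_branch.items():
                null = AffinityNull(
                    ds, n_perm=config.n_perm_dyads,
                    seed=config.seed, mode=config.sampler_mode,
                )
                frame, _ = valence_table(null, alpha=config.alpha)
                mig_frames.append(frame)
            outputs.append(
                _write(
                    pd.concat(mig_frames, ignore_index=True),
                    out / "migrant_partner_tests.csv",
                )
            )
        manifest.notes["valence_skipped"] = {
            k: [list(d) for d in v] for k, v in skipped.items()
        }
        manifest.record(stage, *outputs)

        # 6 -- change tests ----------------------------------------------
        stage = "change"
        pairs = [
            (a, b)
            for a, b in itertools.combinations(order, 2)
        ]
        change_frames = []
        for c1, c2 in pairs:
            frame, sk = change_table(
                nulls[c1], nulls[c2], alpha=config.alpha, seed=config.seed
            )
            change_frames.append(frame)
        changes = pd.concat(change_frames, ignore_index=True)
        if config.bh_correction:
            from .nullmodels import benjamini_hochberg

            changes["p_adj"] = benjamini_hochberg(changes["p"])
        manifest.record(stage, _write(changes, out / "change_tests.csv"))

        # 7 -- scenario classification -----------------------------------
        stage = "scenarios"
        outputs = []
        if len(order) >= 3:
            triplets = change_tests_to_triplets(changes)
            classified = classify_table(triplets)
            counts = scenario_counts(classified)
            outputs.append(_write(classified, out / "scenarios.csv"))
            outputs.append(
                _write(
                    pd.DataFrame(
                        [{"scenario": k, "n_dyads": v} for k, v in counts.items()]
                    ),
                    out / "scenario_summary.csv",
                )
            )
            manifest.notes["scenario_counts"] = counts
        manifest.record(stage, *outputs)

        # 8 -- degree + centrality ---------------------------------------
        stage = "network"
        degree_frames = [degree_frame(a) for a in affinities.values()]
        centrality_frames = [
            centrality_table(nulls[label], alpha=config.alpha) for label in order
        ]
        edges = []
        for label, a in affinities.items():
            e = edge_list(a)
            e.insert(0, "condition", label)
            edges.append(e)
        manifest.record(
            stage,
            _write(pd.concat(degree_frames, ignore_index=True), out / "degrees.csv"),
            _write(
                pd.concat(centrality_frames, ignore_index=True),
                out / "centrality_tests.csv",
            ),
            _write(pd.concat(edges, ignore_index=True), out / "edges.csv"),
        )

        # 9 -- Mantel + unit-type profiles -------------------------------
        stage = "structure"
        mantel_rows = []
        for c1, c2 in pairs:
            for mode in ("standardized", "absolute"):
                res = mantel_affinity(
                    affinities[c1], affinities[c2],
                    n_perm=config.n_perm_mantel, seed=config.seed, mode=mode,
                )
                mantel_rows.append(
                    {
                        "condition_1": c1, "condition_2": c2, "mode": mode,
                        "r": res.r, "p": res.p, "n_dyads": res.n_dyads,
                        "n_perm": res.n_perm,
                    }
                )
        profiles = pd.concat(
            [unit_type_profile(residents[label]) for label in order],
            ignore_index=True,
        )
        manifest.record(
            stage,
            _write(pd.DataFrame(mantel_rows), out / "mantel.csv"),
            _write(profiles, out / "unit_type_profiles.csv"),
            _write(kruskal_table(profiles), out / "kruskal.csv"),
        )
    except MaramsgError as err:
        raise MaramsgError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(manifest.to_json())
    _write_summary(out, manifest)
    return manifest


def _write_summary(out: Path, manifest: RunManifest) -> None:
    lines = [
        f"maramsg {__version__} run (seed {manifest.seed}, "
        f"config {manifest.config_hash})",
        f"sessions analysed: {manifest.notes.get('n_sessions')}",
    ]
    counts = manifest.notes.get("scenario_counts")
    if counts:
        lines.append(
            "scenario counts: "
            + ", ".join(f"{k}: {v}" for k, v in counts.items() if v)
        )
    lines.append("stages: " + ", ".join(manifest.stages))
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
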