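"""Census parsing, condition binning, filtering and unit classification."""

import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maramsg.census import (
    DEFAULT_BINS,
    CensusSession,
    ConditionDataset,
    FilterPolicy,
    NdviBin,
    SocialUnit,
    UnitType,
    apply_filters,
    assign_condition,
    classify_unit_type,
    parse_census,
    write_census,
)
from maramsg.errors import (
    ConfigurationError,
    EmptyDatasetError,
    FormatError,
    ReferentialError,
    ValidationError,
)
from maramsg.synthetic import generate_census, small_test_config

from conftest import make_dataset


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


UNITS_MIN = "session_id,unit_id,species_id,count\ns1,u1,A,2\ns1,u1,B,1\n"
SESSIONS_MIN = "session_id,date,ndvi,migrants_present\ns1,2020-01-01,3000,true\n"


class TestParseCensus:
    def test_smallest_valid_input(self, tmp_path):
        sessions = parse_census(
            _write(tmp_path, "u.csv", UNITS_MIN),
            _write(tmp_path, "s.csv", SESSIONS_MIN),
        )
        assert len(sessions) == 1
        (sess,) = sessions
        assert sess.ndvi == 3000 and sess.migrants_present
        assert sess.date == datetime.date(2020, 1, 1)
        (unit,) = sess.units
        assert unit.composition == {"A": 2, "B": 1}

    @pytest.mark.parametrize(
        "units_text,sessions_text,err,match",
        [
            (UNITS_MIN.replace("count", "n"), SESSIONS_MIN, FormatError, "count"),
            (UNITS_MIN, SESSIONS_MIN.replace("ndvi", "x"), FormatError, "ndvi"),
            (UNITS_MIN.replace("s1,u1,B,1", "s2,u1,B,1"), SESSIONS_MIN,
             ReferentialError, "s2"),
            (UNITS_MIN.replace("B,1", "B,0"), SESSIONS_MIN, ValidationError, "row 3"),
            (UNITS_MIN.replace("B,1", "B,-2"), SESSIONS_MIN, ValidationError, "row"),
            (UNITS_MIN,
             SESSIONS_MIN + "s9,2020-02-02,3100,false\n", ValidationError, "s9"),
        ],
    )
    def test_malformed_input_raises(self, tmp_path, units_text, sessions_text, err, match):
        with pytest.raises(err, match=match):
            parse_census(
                _write(tmp_path, "u.csv", units_text),
                _write(tmp_path, "s.csv", sessions_text),
            )

    def test_synthetic_roundtrip_preserves_compositions(self, tmp_path):
        sessions, _ = generate_census(
            small_test_config(n_sessions=5, units_per_session=8, seed=3)
        )
        write_census(sessions, tmp_path / "u.csv", tmp_path / "s.csv")
        back = parse_census(tmp_path / "u.csv", tmp_path / "s.csv")
        assert len(back) == len(sessions)
        for a, b in zip(sessions, back):
            assert a.session_id == b.session_id
            assert sorted(u.composition.items() for u in a.units) == sorted(
                u.composition.items() for u in b.units
            )


class TestConditionAssignment:
    def _session(self, sid, ndvi):
        return CensusSession(
            sid, datetime.date(2020, 1, 1), ndvi, False,
            (SocialUnit(f"{sid}-u", {"A": 1}),),
        )

    def test_condition_means_fall_in_their_bins(self):
        sessions = [self._session(s, v) for s, v in
                    [("a", 3670), ("b", 5155), ("c", 6627)]]
        out = assign_condition(sessions)
        assert {k: [s.session_id for s in v.sessions] for k, v in out.items()} == {
            "low": ["a"], "intermediate": ["b"], "high": ["c"]
        }

    def test_half_open_boundary(self):
        out = assign_condition([self._session("edge", 5000)])
        assert list(out) == ["intermediate"]

    def test_one_session_per_condition(self):
        sessions = [self._session(s, v) for s, v in
                    [("a", 4800), ("b", 5155), ("c", 6627)]]
        out = assign_condition(sessions)
        assert all(len(ds.sessions) == 1 for ds in out.values())

    def test_out_of_range_sessions_excluded(self):
        out = assign_condition([self._session("lost", 800), self._session("a", 3000)])
        assert [s.session_id for s in out["low"].sessions] == ["a"]

    def test_overlapping_bins_rejected(self):
        bad = (NdviBin("x", 0, 100), NdviBin("y", 50, 200))
        with pytest.raises(ConfigurationError, match="overlap"):
            assign_condition([], bins=bad)

    def test_migrant_rule_overrides_ndvi(self):
        sess = CensusSession(
            "m", datetime.date(2020, 1, 1), 6000, True,
            (SocialUnit("m-u", {"A": 1}),),
        )
        out = assign_condition([sess], migrant_rule={True: "low"})
        assert [s.session_id for s in out["low"].sessions] == ["m"]

    def test_individuals_conserved_across_conditions(self):
        sessions, _ = generate_census(
            small_test_config(
                n_sessions=4, units_per_session=6, seed=11,
                conditions=("low", "intermediate", "high"),
            )
        )
        out = assign_condition(sessions)
        total = sum(ds.community_total for ds in out.values())
        assert total == sum(s.total_individuals for s in sessions)


class TestFilters:
    def test_super_herd_threshold_is_strict(self):
        ds = make_dataset([{"A": 2001}, {"A": 2000}, {"B": 5}])
        filtered, report = apply_filters(ds, FilterPolicy())
        sizes = sorted(u.size for u in filtered.units)
        assert sizes == [5, 2000]
        assert len(report.units_dropped) == 1

    def test_excluded_species_removed_from_composition(self):
        ds = make_dataset([{"Wil": 50, "Zeb": 10}])
        filtered, report = apply_filters(
            ds, FilterPolicy(excluded_species={"Wil"})
        )
        assert [u.composition for u in filtered.units] == [{"Zeb": 10}]
        assert report.individuals_removed == {"Wil": 50}
        assert "Wil" not in filtered.species_totals

    def test_drop_whole_unit_mode(self):
        ds = make_dataset([{"Wil": 50, "Zeb": 10}, {"Zeb": 3}])
        filtered, _ = apply_filters(
            ds,
            FilterPolicy(
                excluded_species={"Wil"}, drop_units_containing_excluded=True
            ),
        )
        assert [u.composition for u in filtered.units] == [{"Zeb": 3}]

    def test_empty_policy_is_identity(self, toy3):
        filtered, report = apply_filters(
            toy3, FilterPolicy(max_unit_size=None)
        )
        assert [u.composition for u in filtered.units] == [
            u.composition for u in toy3.units
        ]
        assert not report.units_dropped and not report.individuals_removed

    def test_filtering_is_idempotent(self):
        ds = make_dataset([{"A": 2001}, {"Wil": 2, "B": 4}, {"B": 1}])
        policy = FilterPolicy(excluded_species={"Wil"})
        once, _ = apply_filters(ds, policy)
        twice, _ = apply_filters(once, policy)
        assert [u.composition for u in once.units] == [
            u.composition for u in twice.units
        ]

    def test_emptying_the_dataset_raises(self):
        ds = make_dataset([{"Wil": 3}])
        with pytest.raises(EmptyDatasetError):
            apply_filters(ds, FilterPolicy(excluded_species={"Wil"}))

    def test_totals_recomputed_after_filtering(self):
        ds = make_dataset([{"A": 2500, "B": 10}, {"A": 3, "B": 2}])
        filtered, _ = apply_filters(ds, FilterPolicy())
        assert filtered.species_totals == {"A": 3, "B": 2}


class TestUnitTypes:
    @pytest.mark.parametrize(
        "comp,expected",
        [
            ({"A": 1}, UnitType.SOLITARY),
            ({"A": 5}, UnitType.SINGLE_SPECIES),
            ({"A": 2, "B": 1}, UnitType.MIXED_SPECIES),
            ({"A": 1, "B": 1}, UnitType.MIXED_SPECIES),
        ],
    )
    def test_definitions(self, comp, expected):
        assert classify_unit_type(SocialUnit("u", comp)) is expected

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.dictionaries(
                st.sampled_from("ABCDE"), st.integers(1, 9),
                min_size=1, max_size=4,
            ),
            min_size=1, max_size=12,
        )
    )
    def test_classification_partitions_any_unit_set(self, comps):
        units = [SocialUnit(f"u{i}", c) for i, c in enumerate(comps)]
        labels = [classify_unit_type(u) for u in units]
        assert len(labels) == len(units)
        counts = {t: labels.count(t) for t in UnitType}
        assert sum(counts.values()) == len(units)
        # each class obeys its defining predicate
        for u, lab in zip(units, labels):
            if lab is UnitType.SOLITARY:
                assert u.size == 1
            elif lab is UnitType.SINGLE_SPECIES:
                assert u.size >= 2 and u.richness == 1
            else:
                assert u.richness >= 2


class TestInvariants:
    def test_zero_count_rejected(self):
        with pytest.raises(ValidationError):
            SocialUnit("u", {"A": 0})

    def test_ndvi_range_enforced(self):
        with pytest.raises(ValidationError):
            CensusSession(
                "s", datetime.date(2020, 1, 1), 10001, False,
                (SocialUnit("u", {"A": 1}),),
            )

    def test_condition_totals_identities(self, toy3):
        assert toy3.community_total == sum(toy3.species_totals.values())
        assert toy3.community_total == sum(u.size for u in toy3.units)

    def test_default_bins_cover_study_range(self):
        labels = [b.label for b in DEFAULT_BINS]
        assert labels == ["low", "intermediate", "high"]


class TestAnalysisConfig:
    def test_yaml_config_round_trip(self, tmp_path):
        from maramsg.census import load_analysis_config

        path = tmp_path / "cfg.yaml"
        path.write_text(
            "bins:\n"
            "  - {label: dry, lower: 0, upper: 4000}\n"
            "  - {label: wet, lower: 4000, upper: 9000, closed_upper: true}\n"
            "filter:\n"
            "  max_unit_size: 500\n"
            "  excluded_species: [Wil]\n"
        )
        bins, policy = load_analysis_config(path)
        assert [b.label for b in bins] == ["dry", "wet"]
        assert bins[1].closed_upper
        assert policy.max_unit_size == 500
        assert policy.excluded_species == frozenset({"Wil"})

    def test_empty_config_gives_defaults(self, tmp_path):
        from maramsg.census import load_analysis_config

        path = tmp_path / "cfg.yaml"
        path.write_text("")
        bins, policy = load_analysis_config(path)
        assert bins == DEFAULT_BINS
        assert policy == FilterPolicy()
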