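"""Constrained randomization: constraints, uniformity, and permutation tests."""

import numpy as np
import pytest

from maramsg.affinity import pairwise_affinity
from maramsg.census import ConditionDataset
from maramsg.errors import (
    ConfigurationError,
    EnumerationCapError,
    UndefinedStatisticError,
)
from maramsg.nullmodels import (
    AffinityNull,
    ConditionSampler,
    build_null_ensemble,
    centrality_test,
    change_test,
    check_constraints,
    count_arrangements,
    dyad_valence_test,
    exact_null_oracle,
    randomize_condition,
    substream,
)
from maramsg.synthetic import generate_census, small_test_config
from maramsg.validation import gof_toy_dataset, neutral_null_consistency, sampler_gof

from conftest import make_dataset


def _small_synthetic(seed=0, **kw):
    cfg = small_test_config(
        n_sessions=kw.pop("n_sessions", 4),
        units_per_session=kw.pop("units_per_session", 10),
        seed=seed, **kw,
    )
    sessions, _ = generate_census(cfg)
    return ConditionDataset("low", tuple(sessions))


class TestConstraints:
    @pytest.mark.parametrize("mode", ["rejection", "mcmc"])
    def test_every_draw_satisfies_all_four_constraints(self, mode):
        ds = gof_toy_dataset() if mode == "rejection" else _small_synthetic(1)
        sampler = ConditionSampler(ds, mode=mode)
        rng = np.random.default_rng(0)
        for _ in range(200):
            rd = sampler.to_dataset(sampler.sample_assignment(rng))
            assert all(check_constraints(ds, rd).values())

    def test_single_unit_randomizes_to_itself(self):
        ds = make_dataset([{"A": 2, "B": 1}])
        rd = randomize_condition(ds, rng=0)
        assert [u.composition for u in rd.units] == [{"A": 2, "B": 1}]

    def test_units_keep_their_sessions_and_ids(self):
        ds = _small_synthetic(2)
        rd = randomize_condition(ds, rng=1)
        assert [s.session_id for s in rd.sessions] == [
            s.session_id for s in ds.sessions
        ]
        assert [u.unit_id for u in rd.units] == [u.unit_id for u in ds.units]


class TestExactOracle:
    def test_singleton_space_is_a_point_mass(self):
        ds = make_dataset([{"A": 2, "B": 1}])
        dist = exact_null_oracle(ds, lambda d: pairwise_affinity(d, "A", "B"))
        assert dist == {round(pairwise_affinity(ds, "A", "B"), 12): 1.0}

    def test_three_block_space_enumerates_three_arrangements(self):
        # blocks A1, B1, C1 over skeletons of richness 2 and 1: the lone
        # block is A, B or C with equal probability; W_AB = 2 iff A,B paired
        ds = make_dataset([{"A": 1, "B": 1}, {"C": 1}])
        assert count_arrangements(ds) == 3
        dist = exact_null_oracle(ds, lambda d: pairwise_affinity(d, "A", "B"))
        assert dist[2.0] == pytest.approx(1 / 3)
        assert dist[0.0] == pytest.approx(2 / 3)

    def test_cap_refuses_large_spaces(self):
        ds = _small_synthetic(3, n_sessions=6, units_per_session=12)
        with pytest.raises(EnumerationCapError):
            count_arrangements(ds, cap=1000)

    def test_sampler_mean_matches_exact_expectation(self):
        exact_mean, sampled_mean, se = neutral_null_consistency(seed=1, n_draws=3000)
        assert abs(sampled_mean - exact_mean) < 3 * se


class TestSamplerUniformity:
    def test_mcmc_draws_match_enumeration(self):
        res = sampler_gof(n_draws=8000, seed=2, mode="mcmc")
        assert res.mode == "mcmc"
        assert res.p > 0.01

    def test_auto_mode_picks_rejection_on_small_instance(self):
        res = sampler_gof(n_draws=4000, seed=3)
        assert res.mode == "rejection"
        assert res.p > 0.01


class TestEnsembles:
    def test_zero_permutations_rejected(self, toy3):
        with pytest.raises(ConfigurationError):
            build_null_ensemble(toy3, lambda d: 0.0, n_perm=0)

    def test_same_seed_gives_identical_draws(self, toy3):
        kw = dict(n_perm=50, seed=9, statistic_name="w_ab")
        e1 = build_null_ensemble(
            toy3, lambda d: pairwise_affinity(d, "A", "B"), **kw
        )
        e2 = build_null_ensemble(
            toy3, lambda d: pairwise_affinity(d, "A", "B"), **kw
        )
        np.testing.assert_array_equal(e1.draws, e2.draws)

    def test_constant_statistic_gives_p_one(self, toy3):
        e = build_null_ensemble(toy3, lambda d: 7.0, n_perm=40, seed=0)
        assert (e.draws == 7.0).all()
        assert e.p_upper() == 1.0 and e.p_lower() == 1.0

    def test_p_values_never_zero(self, toy3):
        e = build_null_ensemble(
            toy3, lambda d: pairwise_affinity(d, "A", "B"), n_perm=99, seed=4
        )
        assert e.p_upper() >= 1 / 100 and e.p_lower() >= 1 / 100

    def test_substream_is_stable_and_key_sensitive(self):
        a = substream(1, "low", "affinity").integers(0, 2**31, 5)
        b = substream(1, "low", "affinity").integers(0, 2**31, 5)
        c = substream(1, "high", "affinity").integers(0, 2**31, 5)
        np.testing.assert_array_equal(a, b)
        assert (a != c).any()


class TestDyadValence:
    def test_point_mass_null_is_never_significant(self):
        ds = make_dataset([{"A": 2, "B": 1}])
        t = dyad_valence_test(ds, "A", "B", n_perm=99, seed=0)
        assert t.p_upper == 1.0 and t.p_lower == 1.0 and t.valence == "none"

    def test_unmeasurable_dyad_raises(self, toy3):
        with pytest.raises(UndefinedStatisticError):
            dyad_valence_test(toy3, "A", "Z", n_perm=9, seed=0)

    def test_strong_attraction_flagged_as_preference(self):
        from maramsg.validation import preference_power_experiment

        res = preference_power_experiment(n_replicates=12, n_perm=299, seed=1)
        assert res.n_success >= 11


class TestChangeTest:
    def test_identical_conditions_are_ns(self, toy3):
        other = ConditionDataset("high", toy3.sessions)
        t = change_test(toy3, other, "A", "B", n_perm=99, seed=0)
        assert t.delta_reported == pytest.approx(0.0)
        assert t.direction == "ns"

    def test_swapping_conditions_flips_direction_keeps_p(self):
        th = {"S00": 1.0}
        ds1 = _small_synthetic(20, n_sessions=10, units_per_session=15)
        ds2 = ConditionDataset(
            "high",
            _small_synthetic(21, n_sessions=10, units_per_session=15).sessions,
        )
        a, b = "S00", "S01"
        fwd = change_test(ds1, ds2, a, b, n_perm=199, seed=3)
        rev = change_test(ds2, ds1, a, b, n_perm=199, seed=3)
        assert fwd.p == rev.p
        assert fwd.delta_reported == pytest.approx(-rev.delta_reported)
        flip = {"up": "down", "down": "up", "ns": "ns"}
        assert rev.direction == flip[fwd.direction]


class TestCentrality:
    def test_solitary_only_species_has_zero_degree(self):
        ds = make_dataset([{"A": 1}, {"A": 2}, {"B": 1, "C": 2}, {"B": 2, "C": 1}])
        t = centrality_test(ds, "A", n_perm=199, seed=0)
        assert t.observed == 0.0
        assert t.deviation <= 0.0

    def test_two_tailed_p_in_unit_interval(self):
        ds = _small_synthetic(5)
        null = AffinityNull(ds, n_perm=99, seed=1)
        for sp in null.species:
            t = centrality_test(ds, sp, null=null)
            assert 0 < t.p <= 1.0


class TestWithinSessionMode:
    @pytest.mark.parametrize("mode", ["rejection", "mcmc"])
    def test_blocks_stay_in_their_session(self, mode):
        ds = _small_synthetic(3, n_sessions=4)
        sampler = ConditionSampler(ds, mode=mode, within_sessions=True)
        rng = np.random.default_rng(1)

        def per_session_totals(d):
            return [
                {sp: sum(u.count(sp) for u in s.units) for sp in d.species}
                for s in d.sessions
            ]

        for _ in range(30):
            rd = sampler.to_dataset(sampler.sample_assignment(rng))
            assert all(check_constraints(ds, rd).values())
            assert per_session_totals(rd) == per_session_totals(ds)


class TestSensitivityModes:
    def test_raw_w_statistic_is_focal_independent(self):
        ds = _small_synthetic(7, n_sessions=6, units_per_session=12)
        t = dyad_valence_test(ds, "S00", "S01", n_perm=99, seed=2,
                              statistic="raw_w")
        vals = list(t.observed.values())
        assert len(vals) == 2 and vals[0] == vals[1]
        assert t.p_upper <= 1.0 and t.p_lower <= 1.0

    def test_unknown_statistic_rejected(self, toy3):
        with pytest.raises(ConfigurationError):
            dyad_valence_test(toy3, "A", "B", n_perm=9, statistic="zscore")

    def test_bh_adjustment_handles_sentinels(self):
        from maramsg.nullmodels import benjamini_hochberg

        adj = benjamini_hochberg([0.01, 0.02, np.nan, 0.5])
        assert np.isnan(adj[2])
        assert (adj[~np.isnan(adj)] >= [0.01, 0.02, 0.5]).all()
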