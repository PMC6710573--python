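"""Weighted degree, Mantel correlation, unit-type profiles, Kruskal-Wallis."""

import numpy as np
import pytest
from scipy import stats as sps

from maramsg.affinity import affinity_matrix
from maramsg.census import ConditionDataset, UnitType
from maramsg.errors import ConfigurationError, UndefinedStatisticError
from maramsg.netstats import (
    degree_vector,
    edge_list,
    kruskal_table,
    mantel_affinity,
    mantel_correlation,
    to_networkx,
    unit_type_kruskal,
    unit_type_profile,
    weighted_degree,
)
from maramsg.synthetic import generate_census, small_test_config

from conftest import make_dataset


def _random_symmetric(rng, n=5):
    M = rng.random((n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, np.nan)
    return M


def _naive_mantel(Wx, Wy, n_perm, seed, alternative="greater"):
    """Independent loop-based Mantel implementation (the oracle)."""
    n = Wx.shape[0]

    def r_of(Y):
        xs, ys = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if not (np.isnan(Wx[i, j]) or np.isnan(Y[i, j])):
                    xs.append(Wx[i, j])
                    ys.append(Y[i, j])
        return sps.pearsonr(xs, ys)[0]

    r_obs = r_of(Wy)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += r_of(Wy[np.ix_(perm, perm)]) >= r_obs
    return r_obs, (1 + count) / (1 + n_perm)


class TestWeightedDegree:
    def test_degree_is_the_row_sum(self, toy3):
        res = affinity_matrix(toy3)
        assert weighted_degree(res, "A") == pytest.approx(5 / 6 + 5 / 3, abs=1e-12)

    def test_species_without_heterospecific_contact_has_zero_degree(self):
        ds = make_dataset([{"A": 3}, {"B": 1, "C": 2}, {"B": 2, "C": 1}])
        res = affinity_matrix(ds)
        assert weighted_degree(res, "A") == 0.0

    def test_absent_species_raises(self, toy3):
        res = affinity_matrix(toy3, species=("A", "B", "C", "Z"))
        with pytest.raises(UndefinedStatisticError):
            weighted_degree(res, "Z")

    def test_degree_sum_identity(self):
        sessions, _ = generate_census(
            small_test_config(n_sessions=5, units_per_session=12, seed=8)
        )
        res = affinity_matrix(ConditionDataset("low", tuple(sessions)))
        degrees = degree_vector(res)
        iu = np.triu_indices(len(res.species), k=1)
        assert sum(degrees.values()) == pytest.approx(
            2 * np.nansum(res.W[iu]), abs=1e-9
        )

    def test_edge_list_and_graph_export(self, toy3):
        res = affinity_matrix(toy3)
        edges = edge_list(res)
        assert set(edges.columns) == {"species_a", "species_b", "weight"}
        g = to_networkx(res)
        assert g["A"]["B"]["weight"] == pytest.approx(5 / 6)


class TestMantel:
    def test_identical_matrices_correlate_perfectly(self):
        M = _random_symmetric(np.random.default_rng(0))
        res = mantel_correlation(M, M.copy(), n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        M = _random_symmetric(np.random.default_rng(1))
        res = mantel_correlation(M, 3.5 * M + 2.0, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_naive_implementation(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            Wx = _random_symmetric(rng)
            Wy = _random_symmetric(rng)
            ours = mantel_correlation(Wx, Wy, n_perm=200, seed=trial)
            r_ref, p_ref = _naive_mantel(Wx, Wy, n_perm=200, seed=trial)
            assert ours.r == pytest.approx(r_ref, abs=1e-12)
            assert ours.p == pytest.approx(p_ref, abs=1e-12)

    def test_agrees_with_skbio_statistic(self):
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(7)
        Wx = _random_symmetric(rng)
        Wy = _random_symmetric(rng)
        ours = mantel_correlation(Wx, Wy, n_perm=99, seed=0)
        dx = Wx.copy()
        dy = Wy.copy()
        np.fill_diagonal(dx, 0.0)
        np.fill_diagonal(dy, 0.0)
        result = mantel(DistanceMatrix(dx), DistanceMatrix(dy), permutations=0)
        assert ours.r == pytest.approx(float(result[0]), abs=1e-12)

    def test_symmetric_in_matrix_arguments(self):
        rng = np.random.default_rng(3)
        Wx, Wy = _random_symmetric(rng), _random_symmetric(rng)
        assert mantel_correlation(Wx, Wy, n_perm=49, seed=0).r == pytest.approx(
            mantel_correlation(Wy, Wx, n_perm=49, seed=0).r, abs=1e-12
        )

    def test_handles_missing_dyads_by_pairwise_exclusion(self):
        rng = np.random.default_rng(4)
        Wx, Wy = _random_symmetric(rng), _random_symmetric(rng)
        Wx[0, 1] = Wx[1, 0] = np.nan
        res = mantel_correlation(Wx, Wy, n_perm=49, seed=0)
        assert res.n_dyads == 9
        assert np.isfinite(res.r)

    def test_standardized_mode_symmetrizes_directions(self):
        sessions, _ = generate_census(
            small_test_config(n_sessions=6, units_per_session=12, seed=9)
        )
        ds = ConditionDataset("low", tuple(sessions))
        res = affinity_matrix(ds)
        m = mantel_affinity(res, res, n_perm=49, seed=0, mode="standardized")
        assert m.r == pytest.approx(1.0, abs=1e-12)
        assert m.mode == "standardized"

    def test_too_few_species_rejected(self):
        M = np.ones((3, 3))
        with pytest.raises(ConfigurationError):
            mantel_correlation(M, M, n_perm=9, seed=0)


class TestUnitTypeProfiles:
    def test_worked_proportions(self):
        ds = make_dataset([{"A": 1}, {"A": 3}, {"A": 1, "B": 2}])
        prof = unit_type_profile(ds)
        row_a = prof[prof["species"] == "A"].iloc[0]
        assert row_a["prop_solitary"] == pytest.approx(0.2)
        assert row_a["prop_single_species"] == pytest.approx(0.6)
        assert row_a["prop_mixed_species"] == pytest.approx(0.2)
        row_b = prof[prof["species"] == "B"].iloc[0]
        assert row_b["prop_mixed_species"] == 1.0

    def test_absent_species_rows_omitted_and_rows_sum_to_one(self):
        sessions, _ = generate_census(
            small_test_config(n_sessions=6, units_per_session=10, seed=10)
        )
        prof = unit_type_profile(ConditionDataset("low", tuple(sessions)))
        assert (prof["n_individuals"] >= 1).all()
        sums = prof[
            ["prop_solitary", "prop_single_species", "prop_mixed_species"]
        ].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestKruskal:
    def _profiles(self, values_by_condition, species="A"):
        import pandas as pd

        rows = []
        for cond, values in values_by_condition.items():
            for k, v in enumerate(values):
                rows.append(
                    {
                        "condition": cond, "session_id": f"{cond}-{k}",
                        "species": species, "n_individuals": 10,
                        "prop_solitary": v, "prop_single_species": 0.0,
                        "prop_mixed_species": 1 - v,
                    }
                )
        return pd.DataFrame(rows)

    def test_fully_tied_data_has_h_zero(self):
        prof = self._profiles({"low": [0.4, 0.4, 0.4], "high": [0.4, 0.4, 0.4]})
        h, p = unit_type_kruskal(prof, "A", UnitType.SOLITARY)
        assert h == 0.0 and p == 1.0

    def test_textbook_two_group_value(self):
        # ranks 1..6 in two clean groups: H = 12/42 * (3*2.25 + 3*2.25) = 27/7
        prof = self._profiles(
            {"low": [0.1, 0.2, 0.3], "high": [0.7, 0.8, 0.9]}
        )
        h, _ = unit_type_kruskal(prof, "A", UnitType.SOLITARY)
        assert h == pytest.approx(27 / 7, abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        base = {"low": [0.1, 0.25, 0.3], "high": [0.5, 0.66, 0.9]}
        squared = {c: [v**2 for v in vs] for c, vs in base.items()}
        h1, _ = unit_type_kruskal(self._profiles(base), "A", UnitType.SOLITARY)
        h2, _ = unit_type_kruskal(self._profiles(squared), "A", UnitType.SOLITARY)
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_insufficient_sessions_skipped(self):
        prof = self._profiles({"low": [0.1], "high": [0.5]})
        with pytest.raises(UndefinedStatisticError):
            unit_type_kruskal(prof, "A", UnitType.SOLITARY)

    def test_table_covers_species_and_types(self):
        prof = self._profiles({"low": [0.1, 0.2], "high": [0.7, 0.8]})
        table = kruskal_table(prof)
        assert set(table["unit_type"]) == {t.value for t in UnitType}
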