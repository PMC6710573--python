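"""Community-level network summaries.

Weighted degree (the sum of a species' affinity indices) measures centrality
in the interspecific network; Mantel tests measure how strongly the dyadic
affinity structure is correlated between two ecological conditions; unit-type
profiles describe, per count session, what fraction of each species'
individuals were solitary, in single-species groups, or in mixed-species
groups, compared across conditions with Kruskal-Wallis tests.

The Mantel implementation recomputes the set of complete dyads under every
label permutation, so matrices with unmeasurable (NaN) entries are handled by
pairwise exclusion rather than imputation; off-the-shelf Mantel routines
require complete distance matrices and cannot do this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .affinity import AffinityResult
from .census import ConditionDataset, UnitType, classify_unit_type
from .errors import ConfigurationError, UndefinedStatisticError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weighted degree


def weighted_degree(affinity: AffinityResult, species: str) -> float:
    """Sum of the species' defined affinity indices (NaN entries skipped).

    Raises if every entry of the row is the sentinel (species absent from the
    condition): a degree of a present-but-never-mixing species is 0, which is
    different from unmeasurable.
    """
    i = affinity.index(species)
    row = affinity.W[i]
    if np.isnan(row).all():
        raise UndefinedStatisticError(
            f"species {species!r}: all affinity entries are sentinel"
        )
    n_skipped = int(np.isnan(row).sum()) - 1  # diagonal is always sentinel
    if n_skipped:
        log.debug("degree(%s): skipped %d sentinel entries", species, n_skipped)
    return float(np.nansum(row))


def degree_vector(affinity: AffinityResult) -> dict[str, float]:
    """Weighted degree for every species with a measurable row."""
    out = {}
    for sp in affinity.species:
        try:
            out[sp] = weighted_degree(affinity, sp)
        except UndefinedStatisticError:
            continue
    return out


def degree_frame(affinity: AffinityResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"condition": affinity.condition, "species": sp, "weighted_degree": d}
            for sp, d in degree_vector(affinity).items()
        ]
    )


def edge_list(affinity: AffinityResult, valence: dict | None = None) -> pd.DataFrame:
    """Long edge list (species_a, species_b, weight[, valence]) for graph tools."""
    rows = []
    for a, b in affinity.dyads():
        w = affinity.w(a, b)
        if np.isnan(w):
            continue
        row = {"species_a": a, "species_b": b, "weight": w}
        if valence is not None:
            row["valence"] = valence.get((a, b), valence.get((b, a), "none"))
        rows.append(row)
    return pd.DataFrame(rows)


def to_networkx(affinity: AffinityResult):
    """The affinity network as a weighted undirected networkx graph."""
    import networkx as nx

    g = nx.Graph(condition=affinity.condition)
    g.add_nodes_from(affinity.species)
    for _, row in edge_list(affinity).iterrows():
        g.add_edge(row["species_a"], row["species_b"], weight=row["weight"])
    return g


# ---------------------------------------------------------------------------
# Mantel


@dataclass(frozen=True)
class MantelResult:
    labels: tuple[str, str]
    r: float
    p: float
    n_perm: int
    n_dyads: int
    mode: str  # absolute | standardized
    method: str  # pearson | spearman
    alternative: str  # greater | two-sided


def _symmetrize(M: np.ndarray) -> np.ndarray:
    """Mean of M and its transpose; used for asymmetric standardized matrices."""
    with np.errstate(invalid="ignore"):
        out = np.where(
            np.isnan(M), M.T, np.where(np.isnan(M.T), M, 0.5 * (M + M.T))
        )
    return out


def _pair_r(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return np.nan
    return float((x * y).sum() / denom)


def mantel_correlation(
    Wx: np.ndarray,
    Wy: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    mode: str = "absolute",
    method: str = "pearson",
    alternative: str = "greater",
    labels: tuple[str, str] = ("x", "y"),
) -> MantelResult:
    """Mantel test between two dyadic matrices on the same species set.

    The correlation is computed over unordered off-diagonal dyads with both
    entries defined; the permutation null relabels the species of the second
    matrix (simultaneous row/column permutation), recomputing the defined-dyad
    mask each time.  p uses the add-one convention.  Asymmetric input (the
    standardized index) is first symmetrized by averaging the two directions.
    """
    Wx = np.asarray(Wx, dtype=float)
    Wy = np.asarray(Wy, dtype=float)
    if Wx.shape != Wy.shape or Wx.ndim != 2 or Wx.shape[0] != Wx.shape[1]:
        raise ConfigurationError("matrices must be square and of equal shape")
    n = Wx.shape[0]
    if n < 4:
        raise ConfigurationError("Mantel test needs at least 4 species")
    if alternative not in {"greater", "two-sided"}:
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    Wx = _symmetrize(Wx)
    Wy = _symmetrize(Wy)
    iu = np.triu_indices(n, k=1)

    def corr(perm: np.ndarray) -> float:
        Yp = Wy[np.ix_(perm, perm)]
        x = Wx[iu]
        y = Yp[iu]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            return np.nan
        return _pair_r(x[ok], y[ok], method)

    identity = np.arange(n)
    r_obs = corr(identity)
    if np.isnan(r_obs):
        raise ConfigurationError("fewer than 3 complete dyads shared by matrices")
    rng = np.random.default_rng(seed)
    r_null = np.empty(n_perm)
    for t in range(n_perm):
        r_null[t] = corr(rng.permutation(n))
    valid = r_null[~np.isnan(r_null)]
    if alternative == "greater":
        p = (1.0 + (valid >= r_obs).sum()) / (1.0 + valid.size)
    else:
        p_up = (1.0 + (valid >= r_obs).sum()) / (1.0 + valid.size)
        p_lo = (1.0 + (valid <= r_obs).sum()) / (1.0 + valid.size)
        p = min(1.0, 2.0 * min(p_up, p_lo))
    x, y = Wx[iu], Wy[iu]
    n_dyads = int((~(np.isnan(x) | np.isnan(y))).sum())
    return MantelResult(
        labels=labels, r=r_obs, p=float(p), n_perm=n_perm,
        n_dyads=n_dyads, mode=mode, method=method, alternative=alternative,
    )


def mantel_affinity(
    res_x: AffinityResult,
    res_y: AffinityResult,
    n_perm: int = 9999,
    seed: int = 0,
    mode: str = "absolute",
    method: str = "pearson",
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two conditions' affinity structures.

    ``mode="absolute"`` compares the raw symmetric W matrices;
    ``mode="standardized"`` compares the standardized matrices, where each
    dyad's value is the mean of the two focal directions S_A(B) and S_B(A).
    """
    if res_x.species != res_y.species:
        raise ConfigurationError("results must share one species ordering")
    if mode == "absolute":
        Mx, My = res_x.W, res_y.W
    elif mode == "standardized":
        Mx, My = res_x.S, res_y.S
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    return mantel_correlation(
        Mx, My, n_perm=n_perm, seed=seed, mode=mode, method=method,
        alternative=alternative, labels=(res_x.condition, res_y.condition),
    )


# ---------------------------------------------------------------------------
# Unit-type profiles and Kruskal-Wallis


def unit_type_profile(condition: ConditionDataset) -> pd.DataFrame:
    """Per (session, species): proportion of individuals by social unit type.

    The three proportions sum to 1 for every species with at least one
    individual in the session; species absent from a session are omitted.
    """
    if not condition.sessions:
        raise ConfigurationError("condition has no sessions")
    rows = []
    for sess in condition.sessions:
        counts: dict[str, dict[UnitType, int]] = {}
        for unit in sess.units:
            ut = classify_unit_type(unit)
            for sp, n in unit.composition.items():
                counts.setdefault(sp, {t: 0 for t in UnitType})[ut] += n
        for sp in sorted(counts):
            total = sum(counts[sp].values())
            rows.append(
                {
                    "condition": condition.label,
                    "session_id": sess.session_id,
                    "species": sp,
                    "n_individuals": total,
                    "prop_solitary": counts[sp][UnitType.SOLITARY] / total,
                    "prop_single_species": counts[sp][UnitType.SINGLE_SPECIES] / total,
                    "prop_mixed_species": counts[sp][UnitType.MIXED_SPECIES] / total,
                }
            )
    return pd.DataFrame(rows)


_PROFILE_COLUMNS = {
    UnitType.SOLITARY: "prop_solitary",
    UnitType.SINGLE_SPECIES: "prop_single_species",
    UnitType.MIXED_SPECIES: "prop_mixed_species",
}


def unit_type_kruskal(
    profiles: pd.DataFrame, species: str, unit_type: UnitType | str
) -> tuple[float, float]:
    """Kruskal-Wallis H and p comparing a species' per-session proportions
    of one unit type across ecological conditions.

    Requires at least two conditions with two or more sessions each; fully
    tied samples are defined to give H = 0, p = 1.
    """
    col = _PROFILE_COLUMNS[UnitType(unit_type)]
    sub = profiles[profiles["species"] == species]
    groups = [
        g[col].to_numpy()
        for _, g in sub.groupby("condition", sort=True)
        if len(g) >= 2
    ]
    if len(groups) < 2:
        raise UndefinedStatisticError(
            f"{species}/{unit_type}: fewer than 2 conditions with >= 2 sessions"
        )
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def kruskal_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Kruskal-Wallis comparisons for every species x unit type."""
    rows = []
    for sp in sorted(profiles["species"].unique()):
        for ut in UnitType:
            try:
                h, p = unit_type_kruskal(profiles, sp, ut)
            except UndefinedStatisticError:
                continue
            rows.append(
                {"species": sp, "unit_type": ut.value, "H": h, "p": p}
            )
    return pd.DataFrame(rows)
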