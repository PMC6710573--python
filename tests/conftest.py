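"""Shared fixtures: tiny hand-checkable censuses."""

import datetime

import pytest

from maramsg.census import CensusSession, ConditionDataset, SocialUnit


def make_dataset(unit_specs, label="low", ndvi=3000.0, migrants=False):
    """Build a one-session condition dataset from composition dicts."""
    units = tuple(
        SocialUnit(f"u{i}", comp) for i, comp in enumerate(unit_specs, start=1)
    )
    sess = CensusSession(
        f"{label}-s1", datetime.date(2020, 1, 1), ndvi, migrants, units
    )
    return ConditionDataset(label, (sess,))


@pytest.fixture
def toy3():
    """Worked three-species dataset: units {A:2,B:1}, {A:1,C:1}, {B:1}.

    Totals N_A=3, N_B=2, N_C=1, N_tot=6.  By direct evaluation of the index:
    W_AB = (2*1/2) * 5/(3*2) = 5/6, W_AC = (1*1/1) * 5/(3*1) = 5/3,
    W_BC = 0 (never together).
    """
    return make_dataset([{"A": 2, "B": 1}, {"A": 1, "C": 1}, {"B": 1}])


@pytest.fixture
def pair_unit():
    """Single unit of one A and one B: the index's neutral boundary case."""
    return make_dataset([{"A": 1, "B": 1}])
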