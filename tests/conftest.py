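import dataclasses

import numpy as np
import pytest

from cricketnets.network_build import DyadicMatrix
from cricketnets.records_io import (
    FightEvent,
    Individual,
    MatingEvent,
    ObservationSet,
    OccupancyRecord,
)
from cricketnets.synthetic_data import PRESETS, generate


@pytest.fixture
def tiny_obs() -> ObservationSet:
    """Two males sharing a burrow, one female; one fight, two matings."""
    roster = [
        Individual("m1", "male", 0, 20),
        Individual("m2", "male", 5, 25),
        Individual("f1", "female", 0, 30),
    ]
    occupancy = [
        OccupancyRecord("m1", "b1", 4.0),
        OccupancyRecord("m2", "b1", 9.0),
        OccupancyRecord("f1", "b1", 2.0),
        OccupancyRecord("f1", "b2", 1.0),
    ]
    fights = [FightEvent(6, "m2", "m1", "b1")]
    matings = [
        MatingEvent(7, "m1", "f1", True),
        MatingEvent(8, "m2", "f1", False),
    ]
    return ObservationSet(roster, occupancy, fights, matings)


@pytest.fixture(scope="session")
def demo_obs() -> ObservationSet:
    """A small synthetic season (32 individuals) shared across tests."""
    return generate(dataclasses.replace(PRESETS["demo-small"], seed=11))


def make_sym(rng: np.random.Generator, n: int, base=None, mix: float = 0.0) -> DyadicMatrix:
    """Random symmetric zero-diagonal matrix, optionally correlated with base."""
    a = rng.standard_normal((n, n))
    a = (a + a.T) / 2
    if base is not None:
        a = mix * base.values + np.sqrt(1.0 - mix**2) * a
    np.fill_diagonal(a, 0.0)
    return DyadicMatrix([f"n{i}" for i in range(n)], a, symmetric=True)
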