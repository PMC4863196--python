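import dataclasses
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cricketnets.exceptions import AlignmentError, DegenerateInputError
from cricketnets.network_build import (
    BipartiteMatrix,
    DyadicMatrix,
    build_fighting_network,
    build_mating_bipartite,
    build_spatial_overlap,
    build_temporal_overlap,
    elementwise_product,
    filter_isolates,
    project_sperm_competition,
    spatial_intermediate,
    standardize_offdiag,
    symmetrize_geometric,
)
from cricketnets.records_io import (
    FightEvent,
    Individual,
    MatingEvent,
    ObservationSet,
    OccupancyRecord,
)
from cricketnets.synthetic_data import PRESETS, generate


def _mk(node_ids, rows, symmetric=False):
    return DyadicMatrix(node_ids, np.array(rows, dtype=float), symmetric=symmetric)


# ---------------------------------------------------------------------------
# fighting network
# ---------------------------------------------------------------------------

def test_fight_counts_are_directed():
    roster = [Individual(i, "male", 0, 30) for i in ("A", "B")]
    fights = [
        FightEvent(1, "A", "B", "b1"),
        FightEvent(2, "A", "B", "b2"),
        FightEvent(3, "B", "A", "b1"),
    ]
    d = build_fighting_network(ObservationSet(roster, [], fights, []))
    assert d.values[d.index_of("A"), d.index_of("B")] == 2
    assert d.values[d.index_of("B"), d.index_of("A")] == 1
    assert not d.symmetric


def test_no_fights_gives_zero_matrix(demo_obs):
    obs = ObservationSet(demo_obs.roster, demo_obs.occupancy, [], [])
    assert not build_fighting_network(obs).values.any()


def test_fighting_matches_bruteforce_tally(demo_obs):
    d = build_fighting_network(demo_obs)
    for i, a in enumerate(d.node_ids):
        for j, b in enumerate(d.node_ids):
            expected = sum(
                1 for e in demo_obs.fights
                if e.arriving_male_id == a and e.resident_male_id == b
            )
            assert d.values[i, j] == expected


# ---------------------------------------------------------------------------
# mating bipartite + sperm-competition projection
# ---------------------------------------------------------------------------

def test_mating_bipartite_counts_transfers_only(tiny_obs):
    m = build_mating_bipartite(tiny_obs)
    assert m.values[m.row_ids.index("m1"), 0] == 1
    assert m.values[m.row_ids.index("m2"), 0] == 0  # flag false


def test_mating_bipartite_matches_bruteforce(demo_obs):
    m = build_mating_bipartite(demo_obs)
    for i, male in enumerate(m.row_ids):
        for j, fem in enumerate(m.col_ids):
            expected = sum(
                1 for e in demo_obs.matings
                if e.male_id == male and e.female_id == fem
                and e.spermatophore_transferred
            )
            assert m.values[i, j] == expected


def test_projection_equal_investment_scenarios():
    """One mating with each of two shared females carries the same strength
    as two matings with a single shared female (each spermatophore is one
    unit of investment)."""
    two_females = BipartiteMatrix(
        ("i", "j"), ("f1", "f2"), np.array([[1.0, 1.0], [1.0, 1.0]])
    )
    one_female = BipartiteMatrix(
        ("i", "j"), ("f1", "f2"), np.array([[2.0, 0.0], [2.0, 0.0]])
    )
    for m in (two_females, one_female):
        w = project_sperm_competition(m)
        assert w.values[0, 1] == 2 and w.values[1, 0] == 2


def test_projection_no_shared_females_is_zero():
    m = BipartiteMatrix(("i", "j"), ("f1", "f2"), np.array([[3.0, 0.0], [0.0, 2.0]]))
    assert not project_sperm_competition(m).values.any()


def test_projection_matches_definition_bruteforce(demo_obs):
    m = build_mating_bipartite(demo_obs)
    w = project_sperm_competition(m)
    n = len(m.row_ids)
    for i in range(n):
        for j in range(n):
            expected = 0.0 if i == j else sum(
                m.values[i, f] for f in range(len(m.col_ids)) if m.values[j, f] > 0
            )
            assert w.values[i, j] == pytest.approx(expected)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_projection_invariant_under_female_relabeling(seed):
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, 3, size=(5, 6)).astype(float)
    males = tuple(f"m{i}" for i in range(5))
    females = tuple(f"f{i}" for i in range(6))
    base = project_sperm_competition(BipartiteMatrix(males, females, vals))
    perm = rng.permutation(6)
    permuted = project_sperm_competition(
        BipartiteMatrix(males, tuple(females[k] for k in perm), vals[:, perm])
    )
    assert np.allclose(base.values, permuted.values)
    # a female mated by a single male contributes nothing
    extra = np.zeros((5, 1)); extra[2, 0] = 4.0
    widened = project_sperm_competition(
        BipartiteMatrix(males, females + ("fx",), np.hstack([vals, extra]))
    )
    assert np.allclose(base.values, widened.values)


# ---------------------------------------------------------------------------
# temporal and spatial overlap
# ---------------------------------------------------------------------------

def test_temporal_overlap_inclusive_days():
    roster = [Individual("i", "male", 10, 20), Individual("j", "male", 15, 30)]
    t = build_temporal_overlap(ObservationSet(roster, [], [], []))
    assert t.values[0, 1] == 6  # days 15..20 inclusive
    assert t.values[0, 0] == 0


def test_temporal_overlap_disjoint_lifespans():
    roster = [Individual("i", "male", 0, 5), Individual("j", "male", 10, 12)]
    t = build_temporal_overlap(ObservationSet(roster, [], [], []))
    assert t.values[0, 1] == 0


def test_temporal_overlap_matches_day_enumeration(demo_obs):
    nodes = tuple(i.id for i in demo_obs.roster)  # 32 individuals, exhaustive
    t = build_temporal_overlap(demo_obs, nodes)
    by_id = demo_obs.individuals
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if i == j:
                continue
            expected = sum(
                1 for day in range(0, 200)
                if by_id[a].alive_on(day) and by_id[b].alive_on(day)
            )
            assert t.values[i, j] == expected


def test_spatial_overlap_worked_example(tiny_obs):
    inter = spatial_intermediate(tiny_obs, ("m1", "m2"))
    assert inter.values[0, 1] == 4 and inter.values[1, 0] == 9
    s = build_spatial_overlap(tiny_obs, ("m1", "m2"))
    assert s.values[0, 1] == pytest.approx(6.0)  # sqrt(4 * 9)


def test_spatial_overlap_no_shared_burrows():
    roster = [Individual(i, "male", 0, 10) for i in ("i", "j")]
    occ = [OccupancyRecord("i", "b1", 5.0), OccupancyRecord("j", "b2", 5.0)]
    s = build_spatial_overlap(ObservationSet(roster, occ, [], []))
    assert s.values[0, 1] == 0


def test_spatial_intermediate_matches_double_loop(demo_obs):
    nodes = tuple(demo_obs.male_ids)
    inter = spatial_intermediate(demo_obs, nodes)
    time_at = {(r.individual_id, r.burrow_id): 0.0 for r in demo_obs.occupancy}
    for r in demo_obs.occupancy:
        time_at[(r.individual_id, r.burrow_id)] += r.duration
    burrows = {r.burrow_id for r in demo_obs.occupancy}
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if i == j:
                continue
            expected = sum(
                time_at.get((a, bur), 0.0)
                for bur in burrows
                if time_at.get((a, bur), 0.0) > 0 and time_at.get((b, bur), 0.0) > 0
            )
            assert inter.values[i, j] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# symmetrization and standardization
# ---------------------------------------------------------------------------

def test_geometric_symmetrization_worked_pairs():
    d = _mk(("a", "b"), [[0, 5], [5, 0]])
    assert symmetrize_geometric(d).values[0, 1] == pytest.approx(5.0)
    d = _mk(("a", "b"), [[0, 1], [9, 0]])
    assert symmetrize_geometric(d).values[0, 1] == pytest.approx(3.0)
    d = _mk(("a", "b"), [[0, 7], [0, 0]])
    assert symmetrize_geometric(d).values[0, 1] == 0.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_geometric_mean_never_exceeds_arithmetic(seed):
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, 6, size=(6, 6)).astype(float)
    np.fill_diagonal(vals, 0)
    d = DyadicMatrix([f"n{i}" for i in range(6)], vals)
    g = symmetrize_geometric(d).values
    am = (vals + vals.T) / 2
    assert (g <= am + 1e-12).all()
    equal = np.isclose(g, am)
    np.fill_diagonal(equal, True)
    assert (equal == np.isclose(vals, vals.T)).all()  # equality iff balanced


def test_standardize_closed_form():
    """Equal counts of 0s and 2s over the unordered dyad set map to +/-1
    exactly (mean 1, population SD 1), as with the dyad multiset {0,0,2,2}."""
    vals = np.array([
        [0, 2, 2, 0],
        [2, 0, 0, 2],
        [2, 0, 0, 0],
        [0, 2, 0, 0],
    ], dtype=float)
    d = DyadicMatrix(list("abcd"), vals, symmetric=True)
    z = standardize_offdiag(d)
    got = sorted(z.values[np.triu_indices(4, 1)])
    assert got == pytest.approx([-1, -1, -1, 1, 1, 1])


def test_standardize_is_idempotent(demo_obs):
    s = build_spatial_overlap(demo_obs)
    z1 = standardize_offdiag(s)
    z2 = standardize_offdiag(z1)
    assert np.allclose(z1.values, z2.values)


def test_standardize_constant_matrix_errors():
    vals = np.full((4, 4), 3.0); np.fill_diagonal(vals, 0)
    with pytest.raises(DegenerateInputError):
        standardize_offdiag(DyadicMatrix(list("abcd"), vals, symmetric=True))


# ---------------------------------------------------------------------------
# isolate filtering and elementwise product
# ---------------------------------------------------------------------------

def test_filter_isolates_definition():
    roster = [Individual(i, "male", 0, 10) for i in ("a", "b", "c")]
    occ = [
        OccupancyRecord("a", "b1", 3.0),
        OccupancyRecord("b", "b1", 2.0),
        OccupancyRecord("c", "b9", 5.0),  # nobody else uses b9
    ]
    assert filter_isolates(ObservationSet(roster, occ, [], [])) == ["a", "b"]


def test_filter_isolates_matches_bruteforce_scan():
    obs = generate(dataclasses.replace(PRESETS["y2006-like"], seed=4))
    retained = set(filter_isolates(obs))
    used = {}
    for r in obs.occupancy:
        if r.duration > 0:
            used.setdefault(r.individual_id, set()).add(r.burrow_id)
    males = obs.male_ids
    expected = {
        m for m in males
        if any(used.get(m, set()) & used.get(o, set()) for o in males if o != m)
    }
    assert retained == expected


def test_filter_isolates_is_monotone(tiny_obs):
    base = set(filter_isolates(tiny_obs))
    grown = ObservationSet(
        tiny_obs.roster,
        tiny_obs.occupancy + [OccupancyRecord("m1", "b7", 1.0)],
        tiny_obs.fights, tiny_obs.matings,
    )
    assert base <= set(filter_isolates(grown))


def test_elementwise_product_and_alignment():
    a = _mk(("x", "y"), [[0, 6], [6, 0]], symmetric=True)
    b = _mk(("x", "y"), [[0, 4], [4, 0]], symmetric=True)
    assert elementwise_product(a, b).values[0, 1] == 24
    zero = _mk(("x", "y"), [[0, 0], [0, 0]], symmetric=True)
    assert not elementwise_product(a, zero).values.any()
    other = _mk(("x", "z"), [[0, 1], [1, 0]], symmetric=True)
    with pytest.raises(AlignmentError):
        elementwise_product(a, other)


def test_elementwise_product_matches_loop(demo_obs):
    nodes = tuple(demo_obs.male_ids)
    s = build_spatial_overlap(demo_obs, nodes)
    t = build_temporal_overlap(demo_obs, nodes)
    prod = elementwise_product(s, t)
    for i in range(len(nodes)):
        for j in range(len(nodes)):
            assert prod.values[i, j] == pytest.approx(s.values[i, j] * t.values[i, j])


def test_constructed_matrices_have_zero_diagonal_nonnegative(demo_obs):
    retained = filter_isolates(demo_obs)
    mats = [
        build_fighting_network(demo_obs, retained),
        project_sperm_competition(build_mating_bipartite(demo_obs, male_ids=retained)),
        build_spatial_overlap(demo_obs, retained),
        build_temporal_overlap(demo_obs, retained),
    ]
    for m in mats:
        assert (np.diag(m.values) == 0).all()
        assert (m.values >= 0).all()


def test_graph_and_csv_exports(demo_obs, tmp_path):
    d = build_spatial_overlap(demo_obs)
    d.to_csv(tmp_path / "adj.csv")
    d.to_graphml(tmp_path / "net.graphml")
    g = d.to_graph()
    assert g.number_of_nodes() == d.n
    assert (tmp_path / "net.graphml").stat().st_size > 0
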