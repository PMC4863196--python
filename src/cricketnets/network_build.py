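"""Construction of the dyadic and bipartite competition networks.

Four male-male matrices are built from an :class:`~cricketnets.records_io.ObservationSet`:

fighting
    Directed count matrix: ``w(i -> j)`` is the number of times male *i*
    arrived at a burrow and fought resident male *j*.
sperm competition
    Directed projection of the male x female mating matrix (spermatophore
    transfers only): ``w(i -> j)`` is the total number of times *i* mated
    with any female also mated by *j*. Each spermatophore is a unit of
    male investment, so mating once with each of two shared females and
    mating twice with one shared female carry the same strength.
temporal overlap
    Symmetric: number of days both members of a pair were adult at the
    same time (inclusive of both endpoint days).
spatial overlap
    Males are linked through burrows. The directed intermediate
    ``w(i -> j)`` sums *i*'s own time at every burrow both males used;
    the pair's two totals are then symmetrized by their geometric mean,
    which down-weights unbalanced pairs (the geometric mean of 5 and 5
    is 5, of 1 and 9 is 3, while both pairs average 5 arithmetically).

Plus the male x female mating bipartite matrix and helpers: geometric-mean
symmetrization, off-diagonal standardization, isolate filtering and the
elementwise (space x time) possibility product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DegenerateInputError
from .records_io import ObservationSet

__all__ = [
    "DyadicMatrix",
    "BipartiteMatrix",
    "build_fighting_network",
    "build_mating_bipartite",
    "project_sperm_competition",
    "build_temporal_overlap",
    "build_spatial_overlap",
    "spatial_intermediate",
    "symmetrize_geometric",
    "standardize_offdiag",
    "filter_isolates",
    "elementwise_product",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DyadicMatrix:
    """Labeled square matrix of pairwise interaction strengths.

    The diagonal is structurally zero (no self-ties). ``symmetric`` is a
    contract flag: when set, ``values[i, j] == values[j, i]`` exactly.
    """

    node_ids: tuple[str, ...]
    values: np.ndarray
    symmetric: bool = False

    def __post_init__(self):
        self.node_ids = tuple(self.node_ids)
        self.values = np.asarray(self.values, dtype=float).copy()
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValueError("node_ids must be unique")
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        np.fill_diagonal(self.values, 0.0)
        if self.symmetric and not np.array_equal(self.values, self.values.T):
            raise ValueError("matrix flagged symmetric but values are asymmetric")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def offdiag_values(self) -> np.ndarray:
        """Off-diagonal entries: each unordered dyad once for symmetric
        matrices (upper triangle), every ordered dyad for directed ones."""
        iu = np.triu_indices(self.n, k=1)
        if self.symmetric:
            return self.values[iu]
        il = np.tril_indices(self.n, k=-1)
        return np.concatenate([self.values[iu], self.values[il]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.node_ids),
                            columns=list(self.node_ids))

    def to_csv(self, path: str | Path):
        self.to_frame().to_csv(path, index_label="id", lineterminator="\n")

    def to_graph(self, sexes: dict[str, str] | None = None):
        """Export as a networkx (Di)Graph with weight edge attributes."""
        import networkx as nx

        g = nx.Graph() if self.symmetric else nx.DiGraph()
        for nid in self.node_ids:
            g.add_node(nid, sex=(sexes or {}).get(nid, "male"))
        rows, cols = np.nonzero(self.values)
        for i, j in zip(rows, cols):
            if self.symmetric and i > j:
                continue
            g.add_edge(self.node_ids[i], self.node_ids[j],
                       weight=float(self.values[i, j]))
        return g

    def to_graphml(self, path: str | Path, sexes: dict[str, str] | None = None):
        import networkx as nx

        nx.write_graphml(self.to_graph(sexes), str(path))


@dataclass
class BipartiteMatrix:
    """Labeled rectangular nonnegative matrix (males x females, or
    individuals x burrows)."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.row_ids = tuple(self.row_ids)
        self.col_ids = tuple(self.col_ids)
        self.values = np.asarray(self.values, dtype=float).copy()
        if set(self.row_ids) & set(self.col_ids):
            raise ValueError("row_ids and col_ids must be disjoint")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row_ids must be unique")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("col_ids must be unique")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("values shape does not match labels")
        if (self.values < 0).any():
            raise ValueError("bipartite values must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids),
                            columns=list(self.col_ids))

    def to_csv(self, path: str | Path):
        self.to_frame().to_csv(path, index_label="id", lineterminator="\n")

    def edges(self) -> list[tuple[str, str]]:
        """Unique (row, col) pairs with positive weight, in label order."""
        rr, cc = np.nonzero(self.values > 0)
        return [(self.row_ids[i], self.col_ids[j]) for i, j in zip(rr, cc)]


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------

def _resolve_nodes(obs: ObservationSet, node_ids: Sequence[str] | None,
                   sex: str | None = "male") -> tuple[str, ...]:
    if node_ids is not None:
        return tuple(node_ids)
    if sex == "male":
        return tuple(obs.male_ids)
    if sex == "female":
        return tuple(obs.female_ids)
    return tuple(ind.id for ind in obs.roster)


def build_fighting_network(
    obs: ObservationSet, node_ids: Sequence[str] | None = None
) -> DyadicMatrix:
    """Directed fight-count matrix: arriving male -> resident male."""
    nodes = _resolve_nodes(obs, node_ids)
    idx = {nid: k for k, nid in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for ev in obs.fights:
        i = idx.get(ev.arriving_male_id)
        j = idx.get(ev.resident_male_id)
        if i is not None and j is not None:
            w[i, j] += 1
    return DyadicMatrix(nodes, w, symmetric=False)


def build_mating_bipartite(
    obs: ObservationSet,
    male_ids: Sequence[str] | None = None,
    female_ids: Sequence[str] | None = None,
) -> BipartiteMatrix:
    """Male x female counts of matings with a successful spermatophore
    transfer. Events with the transfer flag false are excluded here."""
    males = _resolve_nodes(obs, male_ids, "male")
    females = _resolve_nodes(obs, female_ids, "female")
    mi = {m: k for k, m in enumerate(males)}
    fi = {f: k for k, f in enumerate(females)}
    m = np.zeros((len(males), len(females)))
    for ev in obs.matings:
        if not ev.spermatophore_transferred:
            continue
        i, j = mi.get(ev.male_id), fi.get(ev.female_id)
        if i is not None and j is not None:
            m[i, j] += 1
    return BipartiteMatrix(males, females, m)


def project_sperm_competition(mating: BipartiteMatrix) -> DyadicMatrix:
    """One-mode projection of the mating matrix onto males.

    ``w(i -> j) = sum over females f mated by j of M[i, f]``: the total
    number of times *i* mated with any female also mated by *j*.
    """
    m = mating.values
    w = m @ (m > 0).T.astype(float)
    np.fill_diagonal(w, 0.0)
    return DyadicMatrix(mating.row_ids, w, symmetric=False)


def build_temporal_overlap(
    obs: ObservationSet, node_ids: Sequence[str] | None = None
) -> DyadicMatrix:
    """Days each pair was adult at the same time (inclusive endpoints)."""
    nodes = _resolve_nodes(obs, node_ids)
    by_id = obs.individuals
    em = np.array([by_id[n].emergence_day for n in nodes], dtype=float)
    de = np.array([by_id[n].death_day for n in nodes], dtype=float)
    lo = np.maximum.outer(em, em)
    hi = np.minimum.outer(de, de)
    t = np.maximum(0.0, hi - lo + 1.0)
    np.fill_diagonal(t, 0.0)
    return DyadicMatrix(nodes, t, symmetric=True)


def _occupancy_matrix(
    obs: ObservationSet, nodes: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    burrows = sorted({r.burrow_id for r in obs.occupancy})
    bi = {b: k for k, b in enumerate(burrows)}
    ni = {n: k for k, n in enumerate(nodes)}
    occ = np.zeros((len(nodes), len(burrows)))
    for rec in obs.occupancy:
        i = ni.get(rec.individual_id)
        if i is not None:
            occ[i, bi[rec.burrow_id]] += rec.duration
    return occ, burrows


def spatial_intermediate(
    obs: ObservationSet, node_ids: Sequence[str] | None = None
) -> DyadicMatrix:
    """Directed burrow-sharing weights before symmetrization.

    ``w(i -> j)`` is *i*'s own total time at burrows that *j* also used
    (*j*'s use gates which burrows count, but does not weight them).
    """
    nodes = _resolve_nodes(obs, node_ids)
    occ, _ = _occupancy_matrix(obs, nodes)
    used = (occ > 0).astype(float)
    w = occ @ used.T
    np.fill_diagonal(w, 0.0)
    return DyadicMatrix(nodes, w, symmetric=False)


def build_spatial_overlap(
    obs: ObservationSet, node_ids: Sequence[str] | None = None
) -> DyadicMatrix:
    """Geometric-mean-symmetrized burrow-sharing overlap."""
    return symmetrize_geometric(spatial_intermediate(obs, node_ids))


# ---------------------------------------------------------------------------
# matrix transforms
# ---------------------------------------------------------------------------

def symmetrize_geometric(d: DyadicMatrix) -> DyadicMatrix:
    """Replace each reciprocal pair of directed weights by the square root
    of their product. A zero in either direction yields zero; by AM-GM the
    result never exceeds the arithmetic mean of the pair."""
    if (d.values < 0).any():
        raise ValueError("geometric-mean symmetrization requires nonnegative weights")
    out = np.sqrt(d.values * d.values.T)
    return DyadicMatrix(d.node_ids, out, symmetric=True)


def standardize_offdiag(d: DyadicMatrix) -> DyadicMatrix:
    """Center and scale the off-diagonal entries to mean 0, SD 1.

    Statistics use each unordered dyad once for symmetric matrices and
    every ordered dyad for directed ones, with the population (divide-by-n)
    standard deviation; the diagonal stays zero and is excluded.
    """
    vals = d.offdiag_values()
    if vals.size < 2:
        raise DegenerateInputError("need at least two off-diagonal dyads")
    mu, sd = float(np.mean(vals)), float(np.std(vals))
    if sd == 0.0:
        raise DegenerateInputError(
            "off-diagonal values are constant; cannot standardize"
        )
    out = (d.values - mu) / sd
    np.fill_diagonal(out, 0.0)
    return DyadicMatrix(d.node_ids, out, symmetric=d.symmetric)


def filter_isolates(obs: ObservationSet) -> list[str]:
    """Males retained for the competitive analyses: those who used at least
    one burrow that another male also used (at any time). Males who never
    shared a burrow with another male cannot fight over residency and are
    unlikely to meet in sperm competition, so they are dropped."""
    males = tuple(obs.male_ids)
    inter = spatial_intermediate(obs, males)
    shared = (inter.values > 0) | (inter.values.T > 0)
    keep = shared.any(axis=1)
    return [m for m, k in zip(males, keep) if k]


def elementwise_product(a: DyadicMatrix, b: DyadicMatrix) -> DyadicMatrix:
    """Entrywise product, e.g. space x time -> the 'possible pairs' matrix
    (nonzero only for pairs alive at the same time that shared a burrow)."""
    if a.node_ids != b.node_ids:
        raise AlignmentError("matrices do not share node ids/ordering")
    return DyadicMatrix(a.node_ids, a.values * b.values,
                        symmetric=a.symmetric and b.symmetric)
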