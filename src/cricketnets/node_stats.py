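"""Node-level analyses: degree, strength, paired comparisons, and the
bipartite degree correlation with its constrained random-subsample null.

Degree counts unique partners (an edge exists iff the weight is positive;
repeated interactions do not raise degree). Strength is the total weight of
interactions a node instigates — row sums of the *directed* matrix.

The mating network's degree correlation ("assortativity by promiscuity")
is the Spearman correlation, over the network's edges, of the degrees of
the two endpoints. Its null model subsamples the "possible pairs" network
(space x time overlap restricted to male-female pairs) so that simulated
networks have, on average, the observed density; this controls for purely
spatio-temporal sources of degree correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .exceptions import AlignmentError, DegenerateInputError
from .network_build import BipartiteMatrix, DyadicMatrix

__all__ = [
    "NodeStatVector",
    "NullDistributionResult",
    "degree_vector",
    "strength_vector",
    "paired_signed_rank",
    "rank_correlation",
    "bipartite_degree_correlation",
    "degree_correlation_null",
]


@dataclass
class NodeStatVector:
    node_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.node_ids = tuple(self.node_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids and values length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.node_ids, self.values.tolist()))


@dataclass
class NullDistributionResult:
    observed: float
    simulated: np.ndarray
    p: float
    n_sim: int
    seed: int | None
    density_matched: bool = True
    tail: str = "upper"
    n_redraws: int = 0
    simulated_edge_counts: np.ndarray | None = None

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.simulated, q))


# ---------------------------------------------------------------------------
# degree and strength
# ---------------------------------------------------------------------------

def degree_vector(
    m: DyadicMatrix | BipartiteMatrix,
    direction: Literal["in", "out", "all"] = "all",
) -> NodeStatVector:
    """Unique-partner counts.

    For a dyadic matrix, ``out`` counts partners the node has positive
    weight *to*, ``in`` counts partners with positive weight to the node,
    and ``all`` counts the union; the three coincide for symmetric
    matrices. For a bipartite matrix the vector covers rows then columns
    (direction is ignored; edges are unordered male-female pairs).
    """
    if isinstance(m, BipartiteMatrix):
        pos = m.values > 0
        return NodeStatVector(
            m.row_ids + m.col_ids,
            np.concatenate([pos.sum(axis=1), pos.sum(axis=0)]).astype(float),
        )
    pos = m.values > 0
    if direction == "out":
        deg = pos.sum(axis=1)
    elif direction == "in":
        deg = pos.sum(axis=0)
    else:
        deg = (pos | pos.T).sum(axis=1)
    return NodeStatVector(m.node_ids, deg.astype(float))


def strength_vector(d: DyadicMatrix, direction: Literal["out"] = "out") -> NodeStatVector:
    """Total interaction weight instigated per node (directed row sums).

    The source matrix must be the original directed network; passing a
    symmetrized matrix is a contract error because 'instigated' is
    undefined there.
    """
    if d.symmetric:
        raise ValueError(
            "strength is defined on the original directed network; "
            "got a symmetric-flagged matrix"
        )
    if direction != "out":
        raise ValueError("only out-strength is defined")
    return NodeStatVector(d.node_ids, d.values.sum(axis=1))


# ---------------------------------------------------------------------------
# paired comparisons
# ---------------------------------------------------------------------------

def _align(x: NodeStatVector, y: NodeStatVector) -> tuple[np.ndarray, np.ndarray]:
    if x.node_ids != y.node_ids:
        if set(x.node_ids) != set(y.node_ids):
            raise AlignmentError("node sets differ")
        order = {n: k for k, n in enumerate(y.node_ids)}
        yv = y.values[[order[n] for n in x.node_ids]]
        return x.values, yv
    return x.values, y.values


def paired_signed_rank(x: NodeStatVector, y: NodeStatVector) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on per-node differences.

    Zero differences are dropped; tied absolute differences get average
    ranks. Returns ``(W, p)`` where ``W`` is the sum of ranks of positive
    differences (the R ``wilcox.test`` V statistic). The p-value uses the
    exact null distribution for small samples without ties and the normal
    approximation otherwise (scipy's default policy).
    """
    xv, yv = _align(x, y)
    if xv.shape[0] < 5:
        raise DegenerateInputError("need at least 5 paired nodes")
    diff = xv - yv
    nz = diff[diff != 0]
    if nz.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    res = stats.wilcoxon(xv, yv, zero_method="wilcox", alternative="two-sided")
    return w_plus, float(res.pvalue)


def rank_correlation(
    x: NodeStatVector,
    y: NodeStatVector,
    n_perm: int | None = None,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    Default p-value is the large-sample approximation; pass ``n_perm`` for
    a permutation p (add-one convention) instead.
    """
    xv, yv = _align(x, y)
    if xv.shape[0] < 4:
        raise DegenerateInputError("need at least 4 paired nodes")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise DegenerateInputError("constant vector in rank correlation")
    rs, p = stats.spearmanr(xv, yv)
    if n_perm is not None:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            r_star = stats.spearmanr(xv, rng.permutation(yv)).statistic
            if abs(r_star) >= abs(rs) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return float(rs), float(p)


# ---------------------------------------------------------------------------
# bipartite degree correlation and its null
# ---------------------------------------------------------------------------

def _edge_degree_pairs(edge_rows: np.ndarray, edge_cols: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge endpoint degrees from an edge index list (unique pairs)."""
    row_deg = np.bincount(edge_rows)
    col_deg = np.bincount(edge_cols)
    return row_deg[edge_rows].astype(float), col_deg[edge_cols].astype(float)


def _degree_corr_from_edges(edge_rows, edge_cols) -> float:
    dm, df = _edge_degree_pairs(edge_rows, edge_cols)
    if np.std(dm) == 0 or np.std(df) == 0:
        raise DegenerateInputError(
            "endpoint degrees constant on one side; degree correlation undefined"
        )
    return float(stats.spearmanr(dm, df).statistic)


def bipartite_degree_correlation(m: BipartiteMatrix) -> float:
    """Spearman correlation of endpoint degrees over the network's edges.

    Each unique positive-weight (male, female) pair is one edge; its data
    point is (degree of the male, degree of the female), where degree is
    the number of unique partners. Positive values mean promiscuous
    individuals tend to mate with promiscuous partners.
    """
    rr, cc = np.nonzero(m.values > 0)
    if rr.size < 3:
        raise DegenerateInputError("need at least 3 edges")
    return _degree_corr_from_edges(rr, cc)


def degree_correlation_null(
    m: BipartiteMatrix,
    possibility: BipartiteMatrix,
    n_sim: int = 1000,
    seed: int | None = None,
    tail: Literal["upper", "two"] = "upper",
    max_redraw_factor: int = 50,
) -> NullDistributionResult:
    """Test the observed degree correlation against density-matched random
    subsamples of the possible-pairs network.

    ``possibility`` must be positive wherever ``m`` is (every observed
    mating pair must have been possible). Each simulated network includes
    each possible edge independently with probability
    ``E_obs / E_poss``, so the expected simulated edge count equals the
    observed count. Simulations whose degree correlation is undefined
    (too few edges or constant endpoint degrees) are redrawn, up to
    ``max_redraw_factor * n_sim`` total draws.
    """
    if n_sim < 99:
        raise ValueError("n_sim must be >= 99")
    if m.row_ids != possibility.row_ids or m.col_ids != possibility.col_ids:
        raise AlignmentError("mating and possibility matrices are not aligned")
    obs_mask = m.values > 0
    poss_mask = possibility.values > 0
    uncovered = obs_mask & ~poss_mask
    if uncovered.any():
        rr, cc = np.nonzero(uncovered)
        pairs = [(m.row_ids[i], m.col_ids[j]) for i, j in zip(rr, cc)]
        raise ValueError(
            f"observed mating pairs outside the possibility set: {pairs[:10]}"
            + ("..." if len(pairs) > 10 else "")
        )
    e_obs = int(obs_mask.sum())
    e_poss = int(poss_mask.sum())
    p_edge = e_obs / e_poss
    observed = bipartite_degree_correlation(m)

    poss_rows, poss_cols = np.nonzero(poss_mask)
    rng = np.random.default_rng(seed)
    simulated = np.empty(n_sim)
    edge_counts = np.empty(n_sim, dtype=int)
    draws = 0
    filled = 0
    max_draws = max_redraw_factor * n_sim
    while filled < n_sim:
        if draws >= max_draws:
            raise DegenerateInputError(
                f"exceeded {max_draws} draws while redrawing degenerate "
                f"null networks ({filled}/{n_sim} valid)"
            )
        draws += 1
        keep = rng.random(e_poss) < p_edge
        if keep.sum() < 3:
            continue
        try:
            simulated[filled] = _degree_corr_from_edges(
                poss_rows[keep], poss_cols[keep]
            )
        except DegenerateInputError:
            continue
        edge_counts[filled] = int(keep.sum())
        filled += 1

    if tail == "upper":
        p = float((np.sum(simulated >= observed - 1e-12) + 1) / (n_sim + 1))
    else:
        p_up = (np.sum(simulated >= observed - 1e-12) + 1) / (n_sim + 1)
        p_lo = (np.sum(simulated <= observed + 1e-12) + 1) / (n_sim + 1)
        p = float(min(1.0, 2.0 * min(p_up, p_lo)))
    return NullDistributionResult(
        observed=observed,
        simulated=simulated,
        p=p,
        n_sim=n_sim,
        seed=seed,
        density_matched=True,
        tail=tail,
        n_redraws=draws - n_sim,
        simulated_edge_counts=edge_counts,
    )
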