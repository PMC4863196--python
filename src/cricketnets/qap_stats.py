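"""Matrix-permutation inference for dyadic data.

Dyadic observations are not independent: every dyad involving the same
individual shares that individual's attributes. Quadratic assignment
procedure (QAP) tests respect this by permuting node labels — rows and
columns of a matrix simultaneously — which preserves the network's
dependence structure under the null.

This module provides:

* :func:`permute_matrix` — the simultaneous row/column permutation primitive;
* :func:`mantel_test` — permutation test of the correlation between two
  labeled matrices;
* :func:`ols_network_fit` — OLS over the dyad vectorization (the observed
  fit reported by either MRQAP variant);
* :func:`mrqap_dsp` — multiple-regression QAP with Dekker double
  semipartialling: each predictor is residualized on the others, the
  residual matrix is node-permuted, and the refitted t-value of the
  permuted term is the pivotal statistic. Robust to correlated predictors.
* :func:`mrqap_y_permute` — the naive variant permuting the response; valid
  when predictors are uncorrelated, biased otherwise (kept as a
  cross-check and to exhibit the motivation for semipartialling).

All permutation p-values use the add-one convention
``p = (b + 1) / (m + 1)`` so that p is never zero; with
``exhaustive=True`` every one of the n! node permutations is enumerated
instead (the identity is included, so p >= 1/n!).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import AlignmentError, DegenerateInputError, RankDeficiencyError
from .network_build import DyadicMatrix

__all__ = [
    "MantelResult",
    "OLSNetworkFit",
    "MRQAPResult",
    "permute_matrix",
    "mantel_test",
    "ols_network_fit",
    "mrqap_dsp",
    "mrqap_y_permute",
]

DyadSet = Literal["unordered", "ordered"]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None = None


@dataclass
class OLSNetworkFit:
    predictor_names: list[str]
    coefficients: np.ndarray          # slope per predictor (intercept separate)
    intercept: float
    t_values: np.ndarray
    r_squared: float
    residual_standard_error: float
    degrees_of_freedom: int
    n_dyads: int


@dataclass
class MRQAPResult:
    predictor_names: list[str]
    coefficients: np.ndarray
    permutation_p: np.ndarray
    t_values: np.ndarray
    intercept: float
    r_squared: float
    residual_standard_error: float
    degrees_of_freedom: int
    n_permutations: int
    seed: int | None
    method: str = "dekker-semipartialling"
    statistic: str = "t"

    def to_table(self) -> "pd.DataFrame":  # noqa: F821 - optional import
        import pandas as pd

        return pd.DataFrame(
            {
                "predictor": self.predictor_names,
                "coefficient": np.asarray(self.coefficients),
                "p": np.asarray(self.permutation_p),
                "residual_standard_error": self.residual_standard_error,
                "degrees_of_freedom": self.degrees_of_freedom,
                "r_squared": self.r_squared,
            }
        )


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def permute_matrix(d: DyadicMatrix, perm: Sequence[int]) -> DyadicMatrix:
    """Simultaneous row/column permutation: ``out[i, j] = D[perm[i], perm[j]]``.

    This relabels nodes while preserving the network structure (degree
    sequence, value multiset, everything up to relabeling).
    """
    perm = np.asarray(perm)
    n = d.n
    if perm.shape != (n,) or sorted(perm.tolist()) != list(range(n)):
        raise ValueError("perm must be a bijection on node indices")
    return DyadicMatrix(d.node_ids, d.values[np.ix_(perm, perm)],
                        symmetric=d.symmetric)


def _dyad_indices(n: int, dyad_set: DyadSet) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    if dyad_set == "unordered":
        return iu
    il = np.tril_indices(n, k=-1)
    return (np.concatenate([iu[0], il[0]]), np.concatenate([iu[1], il[1]]))


def _auto_dyad_set(mats: Iterable[DyadicMatrix]) -> DyadSet:
    return "unordered" if all(m.symmetric for m in mats) else "ordered"


def _check_aligned(mats: Sequence[DyadicMatrix]):
    ids = mats[0].node_ids
    for m in mats[1:]:
        if m.node_ids != ids:
            raise AlignmentError("matrices do not share node ids/ordering")


def _matrix_from_dyads(template: DyadicMatrix, vec: np.ndarray,
                       idx: tuple[np.ndarray, np.ndarray],
                       dyad_set: DyadSet) -> DyadicMatrix:
    out = np.zeros_like(template.values)
    out[idx] = vec
    if dyad_set == "unordered":
        out = out + out.T
        return DyadicMatrix(template.node_ids, out, symmetric=True)
    return DyadicMatrix(template.node_ids, out, symmetric=False)


def _permutations(n: int, n_perm: int, seed, exhaustive: bool):
    if exhaustive:
        if math.factorial(n) > 500_000:
            raise ValueError("exhaustive enumeration only supported for small n")
        return [np.array(p) for p in itertools.permutations(range(n))]
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_perm)]


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel_test(
    a: DyadicMatrix,
    b: DyadicMatrix,
    n_perm: int = 2000,
    seed: int | None = None,
    exhaustive: bool = False,
    dyad_set: DyadSet | None = None,
) -> MantelResult:
    """Two-sided permutation test of the Pearson correlation between the
    dyad vectorizations of two matrices, permuting node labels of ``b``."""
    _check_aligned([a, b])
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ds = dyad_set or _auto_dyad_set([a, b])
    idx = _dyad_indices(a.n, ds)
    va = a.values[idx]

    def corr(vb: np.ndarray) -> float:
        if np.std(va) == 0 or np.std(vb) == 0:
            raise DegenerateInputError("constant matrix in Mantel test")
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr(b.values[idx])
    perms = _permutations(a.n, n_perm, seed, exhaustive)
    r_star = np.array([corr(b.values[np.ix_(p, p)][idx]) for p in perms])
    if exhaustive:
        p = float(np.sum(np.abs(r_star) >= abs(r_obs) - 1e-12) / len(perms))
    else:
        p = float((np.sum(np.abs(r_star) >= abs(r_obs) - 1e-12) + 1) / (n_perm + 1))
    return MantelResult(r=r_obs, p=p, n_permutations=len(perms), seed=seed)


# ---------------------------------------------------------------------------
# OLS network regression
# ---------------------------------------------------------------------------

def _design(xs: Sequence[np.ndarray]) -> np.ndarray:
    return np.column_stack([np.ones(xs[0].shape[0])] + list(xs))


def _check_rank(x_vecs: Sequence[np.ndarray], names: Sequence[str]):
    X = _design(x_vecs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending pair when it is a simple pairwise collinearity
        for i in range(len(x_vecs)):
            for j in range(i + 1, len(x_vecs)):
                si, sj = np.std(x_vecs[i]), np.std(x_vecs[j])
                if si == 0 or sj == 0:
                    continue
                c = np.corrcoef(x_vecs[i], x_vecs[j])[0, 1]
                if abs(c) > 1 - 1e-10:
                    raise RankDeficiencyError(
                        f"predictors {names[i]!r} and {names[j]!r} are collinear"
                    )
        raise RankDeficiencyError("design matrix is rank deficient")


def _fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Return (beta, t, r_squared, rse) for design X (intercept first)."""
    xtx = X.T @ X
    xtx_inv = np.linalg.pinv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = y.shape[0] - X.shape[1]
    sigma2 = rss / df if df > 0 else np.nan
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    rse = math.sqrt(sigma2) if df > 0 else np.nan
    return beta, t, r2, rse


def ols_network_fit(
    y: DyadicMatrix,
    xs: Sequence[DyadicMatrix],
    predictor_names: Sequence[str] | None = None,
    dyad_set: DyadSet | None = None,
) -> OLSNetworkFit:
    """OLS over the dyad vectorization, intercept included.

    ``degrees_of_freedom = n_dyads - n_predictors - 1``;
    ``residual_standard_error = sqrt(RSS / df)``.
    """
    _check_aligned([y, *xs])
    names = list(predictor_names or [f"x{k + 1}" for k in range(len(xs))])
    ds = dyad_set or _auto_dyad_set([y, *xs])
    idx = _dyad_indices(y.n, ds)
    yv = y.values[idx]
    xv = [x.values[idx] for x in xs]
    if yv.shape[0] <= len(xs) + 1:
        raise DegenerateInputError("need more dyads than predictors + 1")
    _check_rank(xv, names)
    X = _design(xv)
    beta, t, r2, rse = _fit(yv, X)
    return OLSNetworkFit(
        predictor_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        t_values=t[1:],
        r_squared=r2,
        residual_standard_error=rse,
        degrees_of_freedom=yv.shape[0] - len(xs) - 1,
        n_dyads=yv.shape[0],
    )


# ---------------------------------------------------------------------------
# MRQAP
# ---------------------------------------------------------------------------

def _prepare(y, xs, predictor_names, dyad_set):
    _check_aligned([y, *xs])
    names = list(predictor_names or [f"x{k + 1}" for k in range(len(xs))])
    ds = dyad_set or _auto_dyad_set([y, *xs])
    fit = ols_network_fit(y, xs, names, ds)
    idx = _dyad_indices(y.n, ds)
    return names, ds, idx, fit


def mrqap_dsp(
    y: DyadicMatrix,
    xs: Sequence[DyadicMatrix],
    n_perm: int = 2000,
    seed: int | None = None,
    predictor_names: Sequence[str] | None = None,
    statistic: Literal["t", "coef"] = "t",
    exhaustive: bool = False,
    dyad_set: DyadSet | None = None,
) -> MRQAPResult:
    """MRQAP with Dekker double semipartialling.

    For each predictor ``x_k``: regress ``x_k`` on the remaining predictors
    at the dyad level, reshape the residuals into a matrix, node-permute
    it, refit ``y`` on the other predictors plus the permuted residual, and
    record the pivotal statistic of the permuted term. The coefficients and
    fit statistics are those of the observed full fit; permutation affects
    only the p-values.
    """
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be >= 99 for MRQAP")
    if len(xs) == 0:
        raise ValueError("at least one predictor is required")
    names, ds, idx, fit = _prepare(y, xs, predictor_names, dyad_set)
    yv = y.values[idx]
    xv = [x.values[idx] for x in xs]

    # observed pivotal statistic per predictor; by Frisch-Waugh-Lovell the
    # t (and coefficient) of the residualized predictor in the reduced fit
    # equals its value in the full fit
    obs_stat = np.asarray(fit.coefficients if statistic == "coef" else fit.t_values)

    rng_seeds = np.random.SeedSequence(seed).spawn(len(xs))
    p_values = np.empty(len(xs))
    for k in range(len(xs)):
        others = [xv[m] for m in range(len(xs)) if m != k]
        Xo = _design(others)
        # residualize x_k on intercept + other predictors
        beta_k = np.linalg.pinv(Xo.T @ Xo) @ (Xo.T @ xv[k])
        resid_k = xv[k] - Xo @ beta_k
        e_mat = _matrix_from_dyads(y, resid_k, idx, ds)
        perms = _permutations(y.n, n_perm, rng_seeds[k], exhaustive)
        count = 0
        for p in perms:
            e_perm = e_mat.values[np.ix_(p, p)][idx]
            Xp = np.column_stack([Xo, e_perm])
            beta_p, t_p, _, _ = _fit(yv, Xp)
            stat = beta_p[-1] if statistic == "coef" else t_p[-1]
            if abs(stat) >= abs(obs_stat[k]) - 1e-12:
                count += 1
        if exhaustive:
            p_values[k] = count / len(perms)
        else:
            p_values[k] = (count + 1) / (n_perm + 1)
    return MRQAPResult(
        predictor_names=names,
        coefficients=np.asarray(fit.coefficients),
        permutation_p=p_values,
        t_values=np.asarray(fit.t_values),
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        residual_standard_error=fit.residual_standard_error,
        degrees_of_freedom=fit.degrees_of_freedom,
        n_permutations=len(perms),
        seed=seed,
        method="dekker-semipartialling",
        statistic=statistic,
    )


def mrqap_y_permute(
    y: DyadicMatrix,
    xs: Sequence[DyadicMatrix],
    n_perm: int = 2000,
    seed: int | None = None,
    predictor_names: Sequence[str] | None = None,
    statistic: Literal["t", "coef"] = "t",
    exhaustive: bool = False,
    dyad_set: DyadSet | None = None,
) -> MRQAPResult:
    """Naive MRQAP permuting the response matrix.

    Exchangeable only when predictors are mutually uncorrelated; with
    correlated predictors its per-predictor p-values are distorted, which
    is the motivation for the semipartialling variant.
    """
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be >= 99 for MRQAP")
    names, ds, idx, fit = _prepare(y, xs, predictor_names, dyad_set)
    xv = [x.values[idx] for x in xs]
    X = _design(xv)
    obs_stat = np.asarray(fit.coefficients if statistic == "coef" else fit.t_values)
    perms = _permutations(y.n, n_perm, seed, exhaustive)
    counts = np.zeros(len(xs), dtype=int)
    for p in perms:
        yp = y.values[np.ix_(p, p)][idx]
        beta, t, _, _ = _fit(yp, X)
        stat = beta[1:] if statistic == "coef" else t[1:]
        counts += (np.abs(stat) >= np.abs(obs_stat) - 1e-12).astype(int)
    if exhaustive:
        p_values = counts / len(perms)
    else:
        p_values = (counts + 1) / (n_perm + 1)
    return MRQAPResult(
        predictor_names=names,
        coefficients=np.asarray(fit.coefficients),
        permutation_p=np.asarray(p_values, dtype=float),
        t_values=np.asarray(fit.t_values),
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        residual_standard_error=fit.residual_standard_error,
        degrees_of_freedom=fit.degrees_of_freedom,
        n_permutations=len(perms),
        seed=seed,
        method="y-permutation",
        statistic=statistic,
    )
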