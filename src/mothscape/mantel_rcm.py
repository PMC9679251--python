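"""Mantel and partial Mantel permutation tests; reciprocal causal modelling.

The Mantel statistic is the Pearson correlation of the strictly-lower
triangles of two distance matrices; its null distribution comes from
jointly permuting the rows and columns of the second matrix.  The partial
Mantel statistic conditions on a third matrix through the first-order
partial correlation, with the null generated by permuting the focal
predictor matrix and recomputing the partial statistic.

Reciprocal causal modelling (RCM) compares every unordered pair of
candidate predictor matrices {X, Y}: partial Mantel of the response on X
given Y (R_PM-A) and on Y given X (R_PM-B).  The support index
R_PM-A - R_PM-B is positive when X carries more independent signal, and
the index matrix is antisymmetric by construction.  Twelve candidate
matrices (3 geographic + 8 environmental + 1 host) give 66 reciprocal
models, i.e. 132 partial Mantel tests.

Tests are one-tailed (upper) by default, matching the directional
isolation hypotheses; p-values use the add-one rule and are never zero.
Missing pairs (e.g. disconnected resistance distances) are deleted
pairwise across all matrices of a test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._core import DegenerateResultError, DistanceMatrix, MothscapeError

__all__ = [
    "MantelResult",
    "RCMIndexMatrix",
    "mantel",
    "partial_mantel",
    "rcm",
]


@dataclass
class MantelResult:
    """Outcome of a (partial) Mantel permutation test."""

    r: float
    p: float
    n_perm: int
    focal: str = ""
    alternative: str = ""
    conditioning: str = ""
    tail: str = "greater"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise MothscapeError("permutation p must lie in (0, 1]")


@dataclass
class RCMIndexMatrix:
    """Support-index matrix (rows = focal variable) with the full test table."""

    matrix: pd.DataFrame
    table: pd.DataFrame  # focal, alternative, R_PM_A, p_A, R_PM_B, p_B, index
    n_models: int = 0
    n_tests: int = 0

    def to_csv(self, matrix_path, table_path) -> None:
        self.matrix.to_csv(matrix_path)
        self.table.to_csv(table_path, index=False)


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def _tri(values: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(values.shape[0], k=-1)
    return values[i, j]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0 or not (np.isfinite(sa) and np.isfinite(sb)):
        raise DegenerateResultError("constant distance matrix: r undefined")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _check_commensurate(*mats: DistanceMatrix) -> None:
    ids = mats[0].ids
    for m in mats[1:]:
        if m.ids != ids:
            raise MothscapeError("distance matrices have different sample ids")


def _clean(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, float).copy()
    v[~np.isfinite(v)] = np.nan
    return v


def _masked_r(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise DegenerateResultError("fewer than 3 complete pairs")
    return _pearson(a[ok], b[ok])


def _perm_indices(n: int, n_perm: int, rng: np.random.Generator,
                  exhaustive: bool):
    if exhaustive:
        return [np.array(p) for p in itertools.permutations(range(n))]
    return [rng.permutation(n) for _ in range(n_perm)]


def _pvalue(obs: float, null: np.ndarray, tail: str) -> float:
    if tail == "greater":
        hits = int(np.sum(null >= obs - 1e-12))
    elif tail == "two-sided":
        hits = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
    else:
        raise MothscapeError(f"unknown tail '{tail}'")
    return (1 + hits) / (1 + null.size)


def mantel(A: DistanceMatrix, B: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, tail: str = "greater",
           exhaustive: bool = False) -> MantelResult:
    """Simple Mantel test of A against B.

    ``exhaustive=True`` enumerates all n! relabelings instead of sampling
    (small matrices only); the sampled and exhaustive p-values agree exactly
    when the sample covers all permutations.
    """
    _check_commensurate(A, B)
    a = _tri(_clean(A.values))
    bmat = _clean(B.values)
    r_obs = _masked_r(a, _tri(bmat))
    rng = np.random.default_rng(seed)
    perms = _perm_indices(A.n, n_perm, rng, exhaustive)
    null = np.array([
        _masked_r(a, _tri(bmat[np.ix_(p, p)])) for p in perms
    ])
    if exhaustive:
        # the identity permutation is part of the enumeration; drop it from
        # the null so the add-one rule counts it exactly once
        null = np.delete(null, 0)
    return MantelResult(r=r_obs, p=_pvalue(r_obs, null, tail),
                        n_perm=len(null), focal=B.label,
                        alternative="", conditioning="", tail=tail, seed=seed)


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    denom = (1 - r_ac ** 2) * (1 - r_bc ** 2)
    if denom <= 0:
        raise DegenerateResultError(
            "conditioning matrix perfectly correlated with A or B")
    return (r_ab - r_ac * r_bc) / math.sqrt(denom)


def partial_mantel(A: DistanceMatrix, B: DistanceMatrix, C: DistanceMatrix,
                   n_perm: int = 999, seed: int = 0, tail: str = "greater",
                   scheme: str = "focal") -> MantelResult:
    """Partial Mantel test of A against focal predictor B, conditioned on C.

    The statistic is the first-order partial correlation
    r(A, B | C) = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2)) over
    lower-triangle entries.  ``scheme='focal'`` permutes B's rows/columns
    jointly and recomputes the statistic; ``scheme='residual'`` permutes the
    residuals of A on C.
    """
    _check_commensurate(A, B, C)
    a = _tri(_clean(A.values))
    bmat = _clean(B.values)
    c = _tri(_clean(C.values))
    b = _tri(bmat)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    if ok.sum() < 3:
        raise DegenerateResultError("fewer than 3 complete triples")
    r_obs = _partial_r(_pearson(a[ok], b[ok]), _pearson(a[ok], c[ok]),
                       _pearson(b[ok], c[ok]))
    rng = np.random.default_rng(seed)

    if scheme == "focal":
        null = np.empty(n_perm)
        for k in range(n_perm):
            p = rng.permutation(A.n)
            bp = _tri(bmat[np.ix_(p, p)])
            okp = np.isfinite(a) & np.isfinite(bp) & np.isfinite(c)
            null[k] = _partial_r(_pearson(a[okp], bp[okp]),
                                 _pearson(a[okp], c[okp]),
                                 _pearson(bp[okp], c[okp]))
    elif scheme == "residual":
        av, bv, cv = a[ok], b[ok], c[ok]
        beta = np.polyfit(cv, av, 1)
        resid = av - np.polyval(beta, cv)
        null = np.empty(n_perm)
        for k in range(n_perm):
            a_star = np.polyval(beta, cv) + rng.permutation(resid)
            null[k] = _partial_r(_pearson(a_star, bv), _pearson(a_star, cv),
                                 _pearson(bv, cv))
    else:
        raise MothscapeError(f"unknown permutation scheme '{scheme}'")
    return MantelResult(r=r_obs, p=_pvalue(r_obs, null, tail),
                        n_perm=n_perm, focal=B.label, alternative="",
                        conditioning=C.label, tail=tail, seed=seed)


# ---------------------------------------------------------------------------
# Reciprocal causal modelling
# ---------------------------------------------------------------------------

def rcm(response: DistanceMatrix, predictors: list[DistanceMatrix],
        n_perm: int = 999, seed: int = 0) -> RCMIndexMatrix:
    """All-pairs reciprocal causal modelling against the response matrix.

    For each unordered predictor pair {X, Y}: R_PM-A = partial Mantel r of
    the response on X given Y, R_PM-B the reverse; the support index is
    R_PM-A - R_PM-B, stored antisymmetrically with rows as focal variables.
    """
    if len(predictors) < 2:
        raise MothscapeError("rcm needs at least two predictors")
    labels = [p.label for p in predictors]
    if len(set(labels)) != len(labels):
        raise MothscapeError("duplicate predictor labels")
    V = len(predictors)
    index = pd.DataFrame(np.full((V, V), np.nan), index=labels, columns=labels)
    rows = []
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(V), 2):
        X, Y = predictors[i], predictors[j]
        s1, s2 = int(rng.integers(2 ** 31)), int(rng.integers(2 ** 31))
        res_a = partial_mantel(response, X, Y, n_perm=n_perm, seed=s1)
        res_b = partial_mantel(response, Y, X, n_perm=n_perm, seed=s2)
        idx = res_a.r - res_b.r
        index.iloc[i, j] = idx
        index.iloc[j, i] = -idx
        rows.append({"focal": X.label, "alternative": Y.label,
                     "R_PM_A": res_a.r, "p_A": res_a.p,
                     "R_PM_B": res_b.r, "p_B": res_b.p, "index": idx})
    table = pd.DataFrame(rows)
    return RCMIndexMatrix(matrix=index, table=table,
                          n_models=len(rows), n_tests=2 * len(rows))
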