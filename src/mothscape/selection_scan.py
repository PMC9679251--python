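"""Selection scans: Weir-Cockerham FST, permutation outliers, latent-factor GEA.

Per-locus FST uses the Weir & Cockerham (1984) variance components: *a*
(among groups), *b* (among individuals within groups), and *c* (within
individuals), estimated from group allele frequencies and observed
heterozygosities; theta = a / (a + b + c) per locus and the multilocus
estimate is the ratio of sums.  The outlier scan replaces a Bayesian
reversible-jump machinery with a permutation null: group labels are
shuffled once per replicate, all loci are rescored, and the pooled null
yields add-one upper-tail p-values and Benjamini-Hochberg q-values.

The genotype-environment association scan is a least-squares latent-factor
regression: each locus's dosage is regressed on the (standardized)
environmental variable plus K latent factors (top-K left singular vectors
of the centered dosage matrix, controlling for background structure); the
environmental t-statistic is the z-score.  z-scores are recalibrated with
the genomic inflation factor lambda = median(z^2) / median(chi2_1), and
significance is assessed on Bonferroni- and BH-corrected adjusted p-values.
Loci significant for several collinear variables are assigned to the
variable with the largest median |z| across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._core import GenotypeMatrix, MothscapeError, logger

__all__ = [
    "FSTResult",
    "wc_fst",
    "pairwise_host_fst",
    "fst_outlier_scan",
    "LatentFactors",
    "latent_factors",
    "GEAResult",
    "gea_scan",
    "gif_calibrate",
    "multi_test_correct",
    "assign_strongest",
]

CHI2_1_MEDIAN = 0.4549364231195724  # median of the chi-square(1) distribution


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

@dataclass
class FSTResult:
    """Per-locus and multilocus Weir-Cockerham theta for one comparison."""

    pair: str
    theta: np.ndarray           # per-locus a/(a+b+c), NaN where undefined
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    overall: float              # ratio of sums
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    outliers: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"theta": self.theta, "a": self.a, "b": self.b,
                            "c": self.c})
        if self.p is not None:
            out["p"] = self.p
        if self.q is not None:
            out["q"] = self.q
        return out


def _wc_components(dosage: np.ndarray, groups: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized W&C (1984) a, b, c per locus for r groups.

    Loci with fewer than 2 non-missing calls in any group are NaN.
    """
    labels = np.unique(groups)
    r = labels.size
    if r < 2:
        raise MothscapeError("need at least two groups")
    L = dosage.shape[1]
    n_i = np.zeros((r, L))
    p_i = np.zeros((r, L))
    h_i = np.zeros((r, L))
    for k, lab in enumerate(labels):
        sub = dosage[groups == lab]
        obs = np.isfinite(sub)
        n_i[k] = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.nansum(sub, axis=0) / (2 * n_i[k])
            h_i[k] = np.nansum(sub == 1, axis=0) / n_i[k]

    valid = (n_i >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.mean(axis=0)
        nc = (r * n_bar - (n_i ** 2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

        a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                  - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                     - (r - 1) / r * s2
                                     - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
    for arr in (a, b, c):
        arr[~valid] = np.nan
    return a, b, c


def wc_fst(g: GenotypeMatrix | np.ndarray, groups: np.ndarray,
           pair: str = "") -> FSTResult:
    """Weir-Cockerham theta per locus and overall (ratio of sums).

    Loci monomorphic across all groups have undefined theta and are
    excluded from the multilocus sums.
    """
    dosage = g.dosage if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    a, b, c = _wc_components(dosage, np.asarray(groups))
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(np.abs(denom) > 1e-300, a / denom, np.nan)
    usable = np.isfinite(denom) & (np.abs(denom) > 1e-300)
    overall = float(np.sum(a[usable]) / np.sum(denom[usable])) if usable.any() \
        else np.nan
    return FSTResult(pair=pair, theta=theta, a=a, b=b, c=c, overall=overall)


def pairwise_host_fst(g: GenotypeMatrix, hosts: np.ndarray) -> list[FSTResult]:
    """All pairwise host-group comparisons (6 pairs for 4 hosts)."""
    import itertools

    hosts = np.asarray(hosts)
    labels = sorted(np.unique(hosts))
    out = []
    for h1, h2 in itertools.combinations(labels, 2):
        sel = np.nonzero((hosts == h1) | (hosts == h2))[0]
        sub = g.take_samples(sel)
        out.append(wc_fst(sub, hosts[sel], pair=f"{h1}-{h2}"))
    return out


def fst_outlier_scan(g: GenotypeMatrix | np.ndarray, groups: np.ndarray,
                     n_perm: int = 1000, fdr: float = 0.05, seed: int = 0,
                     null: str = "pooled") -> FSTResult:
    """Permutation FST outlier scan with BH q-values.

    Group labels are permuted once per replicate and every locus rescored;
    ``null='pooled'`` pools all replicate x locus theta values into one null
    distribution (``'per_locus'`` keeps each locus's own null).  p-values
    follow the add-one upper-tail rule; outliers satisfy q <= fdr.
    """
    dosage = g.dosage if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    groups = np.asarray(groups)
    res = wc_fst(dosage, groups)
    rng = np.random.default_rng(seed)
    L = dosage.shape[1]
    nulls = np.empty((n_perm, L))
    for k in range(n_perm):
        perm = rng.permutation(groups.size)
        a, b, c = _wc_components(dosage, groups[perm])
        denom = a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            nulls[k] = np.where(np.abs(denom) > 1e-300, a / denom, np.nan)

    theta = res.theta
    p = np.full(L, np.nan)
    if null == "pooled":
        pool = np.sort(nulls[np.isfinite(nulls)])
        N = pool.size
        ok = np.isfinite(theta)
        ge = N - np.searchsorted(pool, theta[ok] - 1e-12, side="left")
        p[ok] = (1 + ge) / (1 + N)
    elif null == "per_locus":
        for l in range(L):
            col = nulls[:, l]
            col = col[np.isfinite(col)]
            if np.isfinite(theta[l]) and col.size:
                p[l] = (1 + np.sum(col >= theta[l] - 1e-12)) / (1 + col.size)
    else:
        raise MothscapeError(f"unknown null '{null}'")
    q = np.full(L, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multi_test_correct(p[ok], "bh")[0]
    res.p, res.q = p, q
    res.outliers = ok & (q <= fdr)
    return res


# ---------------------------------------------------------------------------
# Latent factors and GEA
# ---------------------------------------------------------------------------

@dataclass
class LatentFactors:
    """Orthonormal background-structure factors (top-K left singular vectors)."""

    K: int
    scores: np.ndarray          # n x K, orthonormal columns


def latent_factors(g: GenotypeMatrix | np.ndarray, K: int) -> LatentFactors:
    X = g.imputed() if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    X = X - X.mean(axis=0)
    max_k = min(X.shape) - 1
    if K < 0 or K > max_k:
        raise MothscapeError(f"K={K} outside [0, {max_k}]")
    if K == 0:
        return LatentFactors(K=0, scores=np.empty((X.shape[0], 0)))
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    return LatentFactors(K=K, scores=U[:, :K])


@dataclass
class GEAResult:
    """Latent-factor genotype-environment scan over one or more variables."""

    variables: list[str]
    z: np.ndarray               # L x V median |z|-signed scores (median over runs)
    lam: np.ndarray             # genomic inflation factor per variable
    p_adj: np.ndarray           # L x V lambda-adjusted p-values
    bonferroni: np.ndarray      # L x V boolean
    bh: np.ndarray              # L x V boolean
    K: int
    runs: int
    strongest: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, name in enumerate(self.variables):
            for l in range(self.z.shape[0]):
                rows.append({"locus": l, "variable": name,
                             "z": self.z[l, v], "p_adj": self.p_adj[l, v],
                             "bonferroni": bool(self.bonferroni[l, v]),
                             "bh": bool(self.bh[l, v])})
        return pd.DataFrame(rows)


def _env_zscores(X: np.ndarray, env: np.ndarray, U: np.ndarray) -> np.ndarray:
    """z-scores of the environmental coefficient, per locus.

    The per-locus t-statistic is mapped through its Student-t null CDF to a
    standard-normal quantile, so tail probabilities are correct at modest
    sample sizes.
    """
    n = X.shape[0]
    env = (env - env.mean()) / env.std()
    D = np.column_stack([np.ones(n), env] + ([U] if U.size else []))
    q = D.shape[1]
    DtD_inv = np.linalg.inv(D.T @ D)
    coef = DtD_inv @ (D.T @ X)               # q x L
    resid = X - D @ coef
    dof = n - q
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(DtD_inv[1, 1] * sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, coef[1] / se, 0.0)
    z = np.sign(t) * stats.norm.isf(np.minimum(stats.t.sf(np.abs(t), dof),
                                               0.5))
    return np.clip(np.nan_to_num(z), -40, 40)


def gea_scan(g: GenotypeMatrix, env: pd.DataFrame, K: int = 2, runs: int = 5,
             seed: int = 0, alpha: float = 0.05) -> GEAResult:
    """Least-squares latent-factor GEA over the supplied variables.

    Each run re-imputes missing genotypes by binomial draws from the locus
    allele frequency and re-estimates the latent factors, so the median
    |z| across runs integrates over imputation noise.  With no missing data
    the solver is deterministic and the runs collapse to identical values
    (logged as degenerate).  Significance flags use Bonferroni and BH on the
    lambda-adjusted p-values at ``alpha``.
    """
    X0 = g.dosage
    has_missing = np.isnan(X0).any()
    if not has_missing and runs > 1:
        logger.info("gea_scan: no missing data; %d runs are identical "
                    "(deterministic solver)", runs)
    rng = np.random.default_rng(seed)
    variables = list(env.columns)
    L, V = g.n_loci, len(variables)
    zs = np.zeros((runs, L, V))
    p_freq = g.allele_freq()
    for run in range(runs):
        if has_missing:
            X = X0.copy()
            nan_r, nan_c = np.nonzero(np.isnan(X))
            X[nan_r, nan_c] = rng.binomial(2, np.clip(p_freq[nan_c], 0, 1))
        else:
            X = g.imputed()
        Xc = X - X.mean(axis=0)
        if K > 0:
            U, _, _ = np.linalg.svd(Xc, full_matrices=False)
            U = U[:, :K]
        else:
            U = np.empty((Xc.shape[0], 0))
        for v, name in enumerate(variables):
            zs[run, :, v] = _env_zscores(X, env[name].to_numpy(float), U)
        if not has_missing:
            zs[run + 1:] = zs[run]
            break

    sign = np.sign(np.median(zs, axis=0))
    z_med = sign * np.median(np.abs(zs), axis=0)   # median |z|, signed

    lam = np.zeros(V)
    p_adj = np.zeros((L, V))
    bonf = np.zeros((L, V), bool)
    bh = np.zeros((L, V), bool)
    for v in range(V):
        lam[v], p_adj[:, v] = gif_calibrate(z_med[:, v])
        p_b, sig_b = multi_test_correct(p_adj[:, v], "bonferroni")
        q, sig_q = multi_test_correct(p_adj[:, v], "bh")
        bonf[:, v] = p_b <= alpha
        bh[:, v] = q <= alpha
    result = GEAResult(variables=variables, z=z_med, lam=lam, p_adj=p_adj,
                       bonferroni=bonf, bh=bh, K=K, runs=runs)
    result.strongest = assign_strongest(result)
    return result


def gif_calibrate(z: np.ndarray) -> tuple[float, np.ndarray]:
    """Genomic-inflation-factor recalibration of z-scores.

    lambda = median(z^2) / median(chi-square_1); adjusted p is the upper
    tail of chi-square_1 at z^2 / lambda.
    """
    z = np.asarray(z, float)
    if not np.isfinite(z).all():
        raise MothscapeError("z-scores must be finite")
    lam = float(np.median(z ** 2) / CHI2_1_MEDIAN)
    if lam <= 0:
        raise MothscapeError("all z-scores are zero; lambda undefined")
    p_adj = stats.chi2.sf(z ** 2 / lam, df=1)
    return lam, np.maximum(p_adj, np.finfo(float).tiny)


def multi_test_correct(p: np.ndarray, method: str,
                       alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni or Benjamini-Hochberg correction.

    Returns (corrected values, significance flags at ``alpha``).  BH values
    are step-up q-values, monotone non-decreasing in rank order.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, float)
    if method == "bonferroni":
        corrected = np.minimum(p * p.size, 1.0)
        return corrected, corrected <= alpha
    if method in ("bh", "fdr_bh"):
        reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
        return q, reject
    raise MothscapeError(f"unknown correction '{method}'")


def assign_strongest(result: GEAResult, flag: str = "bonferroni",
                     ) -> pd.DataFrame:
    """Per-locus strongest variable among significant associations.

    For every locus significant for at least one variable, the variable
    with the largest median |z| is reported; exact ties report all tied
    variables.
    """
    flags = result.bonferroni if flag == "bonferroni" else result.bh
    rows = []
    absz = np.abs(result.z)
    for l in np.nonzero(flags.any(axis=1))[0]:
        best = absz[l].max()
        tied = [result.variables[v] for v in np.nonzero(absz[l] >= best - 1e-12)[0]]
        rows.append({"locus": int(l), "variable": ";".join(tied),
                     "median_abs_z": float(best)})
    return pd.DataFrame(rows, columns=["locus", "variable", "median_abs_z"])
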