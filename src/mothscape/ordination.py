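"""Ordination machinery: PCoA, spatial eigenvectors, dbRDA, variance partition.

The constrained-ordination path runs: principal coordinates of the genetic
distance matrix (Gower double-centering), distance-based Moran's eigenvector
maps (dbMEM/PCNM) as geographic predictors, PCA of the environmental rasters
as composite environmental predictors, and distance-based redundancy
analysis (dbRDA) of the coordinates on the standardized predictor block with
marginal permutational ANOVA per term.  Adjusted-R2 variance partitioning
(Ezekiel correction) decomposes the explained variance into unique and
shared fractions of the geographic, environmental, and host predictor sets
by inclusion-exclusion over the seven non-empty set unions.

dbMEM follows the PCNM convention: minimum spanning distance = largest edge
of the minimum spanning tree of the Euclidean distances, truncation
threshold = 4 x that distance, super-threshold distances replaced by 4 x the
threshold (a "paper-literal" mode replaces them with the threshold itself),
then PCoA keeping positive-eigenvalue eigenvectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from ._core import (
    EIG_TOL,
    DistanceMatrix,
    GenotypeMatrix,
    MothscapeError,
    RasterStack,
    logger,
)

__all__ = [
    "PCoAResult",
    "pcoa",
    "DbMEMBasis",
    "dbmem",
    "select_mems",
    "EnvPCARasters",
    "env_raster_pca",
    "pca_genotypes",
    "DAPCResult",
    "dapc_xval",
    "DbRDAResult",
    "dbrda_fit",
    "permutation_anova",
    "VarPartResult",
    "varpart3",
    "morans_i",
]


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    """Principal coordinates of a distance matrix."""

    coordinates: np.ndarray     # n x k, axes scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray     # all eigenvalues, descending
    n_negative: int


def pcoa(D: np.ndarray | DistanceMatrix) -> PCoAResult:
    """Gower double-centering + eigendecomposition of a distance matrix.

    Axes with positive eigenvalues are returned scaled by the square root
    of their eigenvalue, so their pairwise Euclidean distances reproduce the
    input when the input is metric.  Negative eigenvalues are counted and
    their axes excluded.
    """
    values = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise MothscapeError("pcoa needs a symmetric square matrix")
    n = values.shape[0]
    A = -0.5 * values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), abs(eigval[-1]), 1.0)
    tol = EIG_TOL * scale
    pos = eigval > tol
    neg = int((eigval < -tol).sum())
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if neg:
        logger.info("pcoa: %d negative eigenvalues (largest magnitude %.3g) "
                    "excluded", neg, float(-eigval.min()))
    return PCoAResult(coordinates=coords, eigenvalues=eigval, n_negative=neg)


# ---------------------------------------------------------------------------
# dbMEM / PCNM
# ---------------------------------------------------------------------------

@dataclass
class DbMEMBasis:
    """Spatial eigenvector basis from truncated geographic distances."""

    msd: float                  # minimum spanning distance (largest MST edge)
    threshold: float            # 4 x msd, exact
    replacement: float          # value substituted for super-threshold pairs
    vectors: np.ndarray         # orthonormal columns, positive eigenvalues
    eigenvalues: np.ndarray
    truncation: str = "pcnm4t"


def dbmem(samples: pd.DataFrame | np.ndarray,
          truncation: str = "pcnm4t") -> DbMEMBasis:
    """Distance-based Moran's eigenvector maps from planar coordinates."""
    if isinstance(samples, pd.DataFrame):
        coords = samples[["x_km", "y_km"]].to_numpy(float)
    else:
        coords = np.asarray(samples, float)
    if coords.shape[0] < 3:
        raise MothscapeError("dbmem needs at least 3 samples")
    D = squareform(pdist(coords))
    mst = minimum_spanning_tree(D).toarray()
    msd = float(mst.max())
    if msd <= 0:
        raise MothscapeError("coincident points: minimum spanning distance is 0")
    threshold = 4.0 * msd
    if truncation == "pcnm4t":
        replacement = 4.0 * threshold
    elif truncation == "paper-literal":
        replacement = threshold
    else:
        raise MothscapeError(f"unknown truncation mode '{truncation}'")
    Dt = np.where(D > threshold, replacement, D)
    res = pcoa(Dt)
    ev = res.eigenvalues
    scale = max(abs(ev[0]), abs(ev[-1]), 1.0)  # same rule as pcoa
    pos = ev > EIG_TOL * scale
    # orthonormal eigenvectors (unscale the PCoA axes)
    vectors = res.coordinates / np.sqrt(ev[pos])
    return DbMEMBasis(msd=msd, threshold=threshold, replacement=replacement,
                      vectors=vectors, eigenvalues=res.eigenvalues[pos],
                      truncation=truncation)


def select_mems(basis: DbMEMBasis, response_D: DistanceMatrix,
                alpha: float = 0.05, n_perm: int = 999,
                seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Retain eigenvectors with significant marginal effects on the response.

    A preliminary dbRDA on all positive eigenvectors is tested term-by-term.
    Because the eigenvector basis is orthonormal, each term's marginal sum
    of squares is its own projection norm, and all terms can be tested with
    one joint permutation stream: response rows are permuted and every
    per-eigenvector pseudo-F recomputed against the permuted full-model
    residual.  Eigenvectors with p <= alpha survive.  Returns (retained
    column indices, per-eigenvector test table).
    """
    V = basis.vectors
    n, m = V.shape
    res = pcoa(response_D)
    Y = res.coordinates - res.coordinates.mean(axis=0)
    df_res = n - 1 - m
    if df_res <= 0:
        raise MothscapeError("more eigenvectors than residual df")

    def all_f(Yk: np.ndarray) -> np.ndarray:
        proj = V.T @ Yk                       # m x k
        ss_j = (proj ** 2).sum(axis=1)
        ss_res = float(np.sum(Yk ** 2) - ss_j.sum())
        return ss_j / (ss_res / df_res)

    F_obs = all_f(Y)
    rng = np.random.default_rng(seed)
    hits = np.zeros(m, dtype=int)
    for _ in range(n_perm):
        hits += all_f(Y[rng.permutation(n)]) >= F_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    table = pd.DataFrame({"term": [f"MEM{k + 1}" for k in range(m)],
                          "df": 1, "F": F_obs, "p": p})
    retained = np.nonzero(p <= alpha)[0]
    return retained, table


# ---------------------------------------------------------------------------
# Raster and genotype PCA
# ---------------------------------------------------------------------------

@dataclass
class EnvPCARasters:
    """PCA of environmental rasters with PC score layers."""

    loadings: pd.DataFrame      # layers x PCs, orthonormal columns
    pc_rasters: RasterStack
    var_frac: np.ndarray
    retained: np.ndarray        # boolean, variance fraction > 1%

    def extract(self, samples: pd.DataFrame,
                retained_only: bool = True) -> pd.DataFrame:
        names = list(self.pc_rasters.names)
        keep = np.nonzero(self.retained)[0] if retained_only \
            else np.arange(len(names))
        r, c = self.pc_rasters.cell_of(samples["x_km"].to_numpy(float),
                                       samples["y_km"].to_numpy(float))
        out = {names[k]: self.pc_rasters.data[k][r, c] for k in keep}
        return pd.DataFrame(out, index=samples.index)


def env_raster_pca(rasters: RasterStack, retain_frac: float = 0.01,
                   ) -> EnvPCARasters:
    """Cell-wise standardized PCA of the environmental layers."""
    if len(rasters.names) < 2:
        raise MothscapeError("need at least 2 layers")
    valid = np.isfinite(rasters.data).all(axis=0)
    r, c = np.nonzero(valid)
    M = np.stack([rasters.data[k][r, c] for k in range(len(rasters.names))],
                 axis=1)
    sd = M.std(axis=0)
    keep_layers = sd > 0
    if not keep_layers.all():
        dropped = [n for n, k in zip(rasters.names, keep_layers) if not k]
        logger.warning("env_raster_pca: dropping constant layers %s", dropped)
    names = [n for n, k in zip(rasters.names, keep_layers) if k]
    M = (M[:, keep_layers] - M[:, keep_layers].mean(axis=0)) / sd[keep_layers]
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    var_frac = S ** 2 / np.sum(S ** 2)
    scores = U * S
    grids = np.full((S.size,) + rasters.shape, np.nan)
    for k in range(S.size):
        grids[k][r, c] = scores[:, k]
    pc_names = [f"envPC{k + 1}" for k in range(S.size)]
    return EnvPCARasters(
        loadings=pd.DataFrame(Vt.T, index=names, columns=pc_names),
        pc_rasters=rasters.with_layers(pc_names, grids),
        var_frac=var_frac, retained=var_frac > retain_frac)


def pca_genotypes(g: GenotypeMatrix, n_axes: int | None = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the locus-mean-imputed, centered dosage matrix.

    Returns (scores, explained-variance fractions); ``n_axes`` beyond the
    matrix rank is truncated with a warning.
    """
    X = g.imputed()
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > EIG_TOL * max(S[0], 1.0)))
    if n_axes is None:
        n_axes = rank
    elif n_axes > rank:
        logger.warning("pca_genotypes: n_axes=%d exceeds rank %d; truncated",
                       n_axes, rank)
        n_axes = rank
    frac = S ** 2 / np.sum(S ** 2)
    return (U * S)[:, :n_axes], frac[:n_axes]


# ---------------------------------------------------------------------------
# DAPC with stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass
class DAPCResult:
    """Cross-validated discriminant analysis of principal components."""

    candidates: list[int]
    success: dict               # candidate -> mean held-out assignment success
    chosen: int
    scores: np.ndarray          # discriminant scores on all data


def dapc_xval(g: GenotypeMatrix, groups: np.ndarray,
              candidates: list[int] | None = None, replicates: int = 100,
              holdout: float = 0.1, seed: int = 0) -> DAPCResult:
    """Choose the PC count for DAPC by stratified holdout cross-validation.

    For each candidate PC count, ``replicates`` stratified (1 - holdout) /
    holdout splits are scored: PCA on the training rows, linear discriminant
    on the group labels, assignment success on the held-out rows.  The PC
    count maximizing mean success wins; ties go to the smaller count.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.model_selection import StratifiedShuffleSplit

    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise MothscapeError("need >= 2 groups with >= 2 members each")
    n = g.n_samples
    n_test = max(1, int(round(holdout * n)))
    if counts.min() < 2 or n_test < len(labels):
        n_test = max(n_test, len(labels))
    X = g.imputed()
    X = X - X.mean(axis=0)
    max_pc = min(n - n_test - len(labels), g.n_loci) - 1
    if candidates is None:
        candidates = sorted({c for c in (2, 5, 10, 20, 40, 60) if c <= max_pc})
    if not candidates:
        raise MothscapeError("no feasible PC counts for this data size")

    splitter = StratifiedShuffleSplit(n_splits=replicates, test_size=n_test,
                                      random_state=seed)
    splits = list(splitter.split(X, groups))
    success = {}
    for n_pc in candidates:
        acc = []
        for train, test in splits:
            Xt = X[train] - X[train].mean(axis=0)
            U, S, Vt = np.linalg.svd(Xt, full_matrices=False)
            proj = Vt[:n_pc].T
            lda = LinearDiscriminantAnalysis()
            lda.fit(Xt @ proj, groups[train])
            Xh = (X[test] - X[train].mean(axis=0)) @ proj
            acc.append(float((lda.predict(Xh) == groups[test]).mean()))
        success[n_pc] = float(np.mean(acc))
    chosen = min(candidates, key=lambda c: (-success[c], c))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    lda = LinearDiscriminantAnalysis()
    pcs = X @ Vt[:chosen].T
    lda.fit(pcs, groups)
    scores = lda.transform(pcs)
    return DAPCResult(candidates=list(candidates), success=success,
                      chosen=chosen, scores=scores)


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

@dataclass
class DbRDAResult:
    """Fitted distance-based redundancy analysis."""

    Y: np.ndarray               # PCoA coordinates (positive axes)
    X: np.ndarray               # centered predictor block
    terms: list                 # (name, column indices) in X
    column_names: list
    r2: float
    ss_total: float
    ss_explained: float
    vif: pd.DataFrame
    standardized: bool
    anova: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def adj_r2(self) -> float:
        n, p = self.X.shape
        return _ezekiel(self.r2, n, p)


def _ezekiel(r2: float, n: int, p: int) -> float:
    if n - 1 - p <= 0:
        raise MothscapeError(
            f"too few samples (n={n}) for {p} predictors in adjusted R2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - p)


def _explained_ss(Y: np.ndarray, X: np.ndarray) -> float:
    """Explained sum of squares of multivariate least squares of Y on X."""
    if X.shape[1] == 0:
        return 0.0
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return float(np.sum((X @ coef) ** 2))


def _encode_host(host: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = sorted(pd.unique(host))
    cols = [(host == lev).astype(float) for lev in levels[1:]]  # drop first
    names = [f"host[{lev}]" for lev in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((host.size, 0)), names)


def dbrda_fit(response_D: DistanceMatrix | np.ndarray,
              geographic: pd.DataFrame | None = None,
              env: pd.DataFrame | None = None,
              host: np.ndarray | None = None,
              standardize: bool = True,
              group_terms: bool = False) -> DbRDAResult:
    """dbRDA of a distance matrix on geographic + environmental + host terms.

    The response is embedded by PCoA (positive axes, scaled by square-root
    eigenvalues); continuous predictors are standardized, the host factor is
    one-hot coded dropping the alphabetically first level.  By default each
    continuous variable and the host block form one ANOVA term;
    ``group_terms=True`` instead pools each predictor set (geographic /
    environmental / host) into a single multi-df term for block-level tests.
    """
    res = pcoa(response_D)
    Y = res.coordinates - res.coordinates.mean(axis=0)
    blocks, names, terms = [], [], []

    def add_block(frame: pd.DataFrame, kind: str) -> None:
        start = len(names)
        for col in frame.columns:
            v = frame[col].to_numpy(float)
            if standardize:
                sd = v.std()
                if sd == 0:
                    raise MothscapeError(f"constant predictor '{col}'")
                v = (v - v.mean()) / sd
            if not group_terms:
                terms.append((str(col), [len(names)]))
            names.append(str(col))
            blocks.append(v[:, None])
        if group_terms:
            terms.append((kind, list(range(start, len(names)))))

    if geographic is not None and len(geographic.columns):
        add_block(geographic, "geographic")
    if env is not None and len(env.columns):
        add_block(env, "environmental")
    if host is not None:
        H, hnames = _encode_host(np.asarray(host))
        if H.shape[1]:
            terms.append(("host", list(range(len(names), len(names) + H.shape[1]))))
            names.extend(hnames)
            blocks.append(H)
    if not blocks:
        raise MothscapeError("no predictors supplied")
    X = np.column_stack(blocks)
    X = X - X.mean(axis=0)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[k] for k in np.nonzero(diag < 1e-8 * diag.max())[0]]
        raise MothscapeError(f"rank-deficient predictors; collinear columns: {bad}")

    ss_total = float(np.sum(Y ** 2))
    ss_exp = _explained_ss(Y, X)
    r2 = ss_exp / ss_total if ss_total > 0 else 0.0

    corr = np.corrcoef(X, rowvar=False)
    vif_vals = np.diag(np.linalg.inv(corr)) if X.shape[1] > 1 else np.ones(1)
    vif = pd.DataFrame({"predictor": names, "vif": vif_vals})
    return DbRDAResult(Y=Y, X=X, terms=terms, column_names=names, r2=r2,
                       ss_total=ss_total, ss_explained=ss_exp, vif=vif,
                       standardized=standardize,
                       meta={"n_negative_eig": res.n_negative})


def permutation_anova(model: DbRDAResult, by: str = "margin",
                      n_perm: int = 999, seed: int = 0,
                      scheme: str = "direct") -> pd.DataFrame:
    """Marginal permutational ANOVA per dbRDA term.

    Each term's marginal sum of squares is the drop in explained SS when it
    leaves the full model; pseudo-F divides its mean square by the full
    model's residual mean square.  ``scheme='direct'`` (default) permutes
    the centered response rows jointly for all terms — the convention of
    marginal tests without a conditioning block in constrained-ordination
    practice; ``scheme='reduced'`` permutes the residuals of each term's
    reduced model (Freedman-Lane).  p-values use the add-one rule.
    """
    if by != "margin":
        raise MothscapeError("only marginal tests are implemented")
    if scheme not in ("direct", "reduced"):
        raise MothscapeError(f"unknown permutation scheme '{scheme}'")
    rng = np.random.default_rng(seed)
    Y, X = model.Y, model.X
    n, p = X.shape
    df_res = n - 1 - p
    if df_res <= 0:
        raise MothscapeError("no residual degrees of freedom")
    ss_res = model.ss_total - model.ss_explained

    reduced, obs = [], []
    for name, cols in model.terms:
        keep = [k for k in range(p) if k not in cols]
        Xr = X[:, keep]
        df_t = len(cols)
        ss_red = _explained_ss(Y, Xr) if Xr.shape[1] else 0.0
        ss_term = model.ss_explained - ss_red
        F_obs = (ss_term / df_t) / (ss_res / df_res)
        reduced.append((name, cols, Xr, df_t))
        obs.append((ss_term, F_obs))

    hits = np.zeros(len(model.terms), dtype=int)
    if scheme == "direct":
        for _ in range(n_perm):
            Yp = Y[rng.permutation(n)]
            exp_full = _explained_ss(Yp, X)
            denom = (model.ss_total - exp_full) / df_res
            for t, (name, cols, Xr, df_t) in enumerate(reduced):
                exp_red = _explained_ss(Yp, Xr) if Xr.shape[1] else 0.0
                if ((exp_full - exp_red) / df_t) / denom >= obs[t][1] - 1e-12:
                    hits[t] += 1
    else:
        for t, (name, cols, Xr, df_t) in enumerate(reduced):
            if Xr.shape[1]:
                coef_r, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
                fitted_r = Xr @ coef_r
            else:
                fitted_r = np.zeros_like(Y)
            resid_r = Y - fitted_r
            for _ in range(n_perm):
                Ystar = fitted_r + resid_r[rng.permutation(n)]
                Ystar = Ystar - Ystar.mean(axis=0)
                tot = float(np.sum(Ystar ** 2))
                exp_full = _explained_ss(Ystar, X)
                exp_red = _explained_ss(Ystar, Xr) if Xr.shape[1] else 0.0
                Fp = ((exp_full - exp_red) / df_t) / ((tot - exp_full) / df_res)
                if Fp >= obs[t][1] - 1e-12:
                    hits[t] += 1

    rows = [{"term": name, "df": df_t, "ss": ss_term, "F": F_obs,
             "p": (1 + h) / (1 + n_perm)}
            for (name, cols, Xr, df_t), (ss_term, F_obs), h
            in zip(reduced, obs, hits)]
    rows.append({"term": "Residual", "df": df_res, "ss": ss_res,
                 "F": np.nan, "p": np.nan})
    table = pd.DataFrame(rows)
    model.anova = table
    return table


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VarPartResult:
    """Adjusted-R2 fractions of three predictor sets."""

    fractions: dict             # a..g keyed as unique_G, unique_E, unique_H,
                                # shared_GE, shared_EH, shared_GH, shared_GEH
    adj_r2_full: float
    residual: float
    components: dict            # adjusted R2 of each of the 7 set unions

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fraction": k, "adj_r2": v} for k, v in self.fractions.items()]
        rows.append({"fraction": "residual", "adj_r2": self.residual})
        return pd.DataFrame(rows)


def varpart3(response_D: DistanceMatrix | np.ndarray, setG: pd.DataFrame,
             setE: pd.DataFrame, setH: pd.DataFrame,
             standardize: bool = True, adjusted: bool = True) -> VarPartResult:
    """Three-set variance partitioning by inclusion-exclusion of adjusted R2.

    Computes (adjusted) R2 for the seven non-empty unions of the predictor
    sets and solves for the three unique, three pairwise-shared, and one
    three-way-shared fraction; the fractions sum to the full model's
    adjusted R2 exactly and the residual is its complement.
    """
    sets = {"G": setG, "E": setE, "H": setH}
    for k, s in sets.items():
        if s is None or not len(s.columns):
            raise MothscapeError(f"predictor set {k} is empty")

    res = pcoa(response_D)
    Y = res.coordinates - res.coordinates.mean(axis=0)
    ss_total = float(np.sum(Y ** 2))
    n = Y.shape[0]

    def prep(frame: pd.DataFrame) -> np.ndarray:
        M = frame.to_numpy(float)
        if standardize:
            sd = M.std(axis=0)
            sd[sd == 0] = 1.0
            M = (M - M.mean(axis=0)) / sd
        return M - M.mean(axis=0)

    mats = {k: prep(s) for k, s in sets.items()}
    unions = ["G", "E", "H", "GE", "GH", "EH", "GEH"]
    aR = {}
    for u in unions:
        X = np.column_stack([mats[k] for k in u])
        r2 = _explained_ss(Y, X) / ss_total
        aR[u] = _ezekiel(r2, n, X.shape[1]) if adjusted else r2

    # solve  aR(union) = sum of its member fractions
    # order: a=unique_G, b=unique_E, c=unique_H, d=GE, e=EH, f=GH, g=GEH
    membership = {
        "G": [1, 0, 0, 1, 0, 1, 1],
        "E": [0, 1, 0, 1, 1, 0, 1],
        "H": [0, 0, 1, 0, 1, 1, 1],
        "GE": [1, 1, 0, 1, 1, 1, 1],
        "GH": [1, 0, 1, 1, 1, 1, 1],
        "EH": [0, 1, 1, 1, 1, 1, 1],
        "GEH": [1, 1, 1, 1, 1, 1, 1],
    }
    A = np.array([membership[u] for u in unions], float)
    b = np.array([aR[u] for u in unions])
    frac = np.linalg.solve(A, b)
    keys = ["unique_G", "unique_E", "unique_H", "shared_GE", "shared_EH",
            "shared_GH", "shared_GEH"]
    fractions = dict(zip(keys, frac))
    # enforce the exact-sum identity against rounding
    fractions["shared_GEH"] += aR["GEH"] - sum(fractions.values())
    return VarPartResult(fractions=fractions, adj_r2_full=aR["GEH"],
                         residual=1.0 - aR["GEH"], components=aR)


# ---------------------------------------------------------------------------
# Spatial autocorrelation helper
# ---------------------------------------------------------------------------

def morans_i(values: np.ndarray, W: np.ndarray) -> float:
    """Moran's I of a vector under a (symmetric, zero-diagonal) weight matrix."""
    z = np.asarray(values, float)
    z = z - z.mean()
    W = np.asarray(W, float)
    s0 = W.sum()
    return float(len(z) / s0 * (z @ W @ z) / (z @ z))
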