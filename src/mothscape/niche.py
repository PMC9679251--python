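"""Presence-background habitat-suitability modelling and resistance surfaces.

A penalized logistic regression of presence points against background points
sampled from the landscape, with linear + quadratic features on continuous
layers and one-hot features on categorical layers.  It fills the same role
as maximum-entropy niche models — presences + background in, a 0-1 logistic
suitability surface, holdout AUC and permutational variable importance out —
with a simpler, fully deterministic estimator.

The resistance surface for connectivity analyses is the reciprocal of the
(floored) suitability: conductance = suitability, resistance = 1/conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint
from shapely import contains_xy
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ._core import (
    MothscapeError,
    RasterStack,
    ResistanceSurface,
    SuitabilitySurface,
    logger,
)

__all__ = [
    "OccurrenceSet",
    "NicheModel",
    "ImportanceTable",
    "make_study_area",
    "fit_presence_background",
    "predict_surface",
    "cv_auc",
    "permutation_importance",
    "resistance_surface",
]


@dataclass
class OccurrenceSet:
    """Presence points in raster coordinates (km)."""

    x: np.ndarray
    y: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if not self.provenance:
            self.provenance = ["external-record"] * self.x.size

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class NicheModel:
    """Fitted presence-background model with its feature recipe."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    reg: float
    means: np.ndarray
    sds: np.ndarray
    continuous: list[str]
    categorical: list[str]
    meta: dict = field(default_factory=dict)

    def design(self, values: pd.DataFrame) -> np.ndarray:
        """Linear + quadratic (continuous) and one-hot (categorical) features."""
        cols = []
        for k, name in enumerate(self.continuous):
            z = (values[name].to_numpy(float) - self.means[k]) / self.sds[k]
            cols.append(z)
            cols.append(z ** 2)
        for name in self.categorical:
            levels = self.meta["levels"][name]
            v = values[name].to_numpy()
            for lev in levels:
                cols.append((v == lev).astype(float))
        return np.column_stack(cols)

    def predict(self, values: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        eta = self.design(values) @ self.coef + self.intercept
        return expit(eta)

    def save_coefficients(self, path) -> None:
        """Write coefficients as a key = value text file."""
        lines = [f"intercept = {self.intercept!r}",
                 f"reg = {self.reg!r}"]
        lines += [f"{name} = {c!r}"
                  for name, c in zip(self.feature_names, self.coef)]
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ImportanceTable:
    """Normalized permutational importance (mean and SE over model replicates)."""

    table: pd.DataFrame  # columns: variable, mean_importance, se

    def __post_init__(self) -> None:
        total = self.table["mean_importance"].sum()
        if abs(total - 100.0) > 0.01:
            raise MothscapeError("importances must be normalized to sum 100")


# ---------------------------------------------------------------------------
# Study area
# ---------------------------------------------------------------------------

def make_study_area(points_x: np.ndarray, points_y: np.ndarray,
                    rasters: RasterStack, occurrences: OccurrenceSet,
                    buffer_km: float = 50.0,
                    ) -> tuple[np.ndarray, RasterStack, OccurrenceSet]:
    """Buffered convex hull of collection points as the analysis mask.

    Returns the boolean cell mask, the masked raster stack (cells outside
    the polygon set to NaN), and the occurrences cropped to the polygon with
    duplicates removed at one-cell granularity.
    """
    hull = MultiPoint(list(zip(points_x, points_y))).convex_hull
    if hull.area == 0:
        raise MothscapeError("collection points are collinear; hull is degenerate")
    poly = hull.buffer(buffer_km)

    rows, cols = rasters.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    cx, cy = rasters.cell_center(rr.ravel(), cc.ravel())
    mask = contains_xy(poly, cx, cy).reshape(rows, cols)

    data = np.where(mask[None, :, :], rasters.data, np.nan)
    masked = rasters.with_layers(rasters.names, data)

    inside = contains_xy(poly, occurrences.x, occurrences.y)
    ox, oy = occurrences.x[inside], occurrences.y[inside]
    prov = [p for p, keep in zip(occurrences.provenance, inside) if keep]
    r, c = rasters.cell_of(ox, oy)
    cell_ok = mask[r, c]
    ox, oy = ox[cell_ok], oy[cell_ok]
    prov = [p for p, keep in zip(prov, cell_ok) if keep]
    r, c = r[cell_ok], c[cell_ok]
    _, first = np.unique(r * cols + c, return_index=True)
    first = np.sort(first)
    dropped = ox.size - first.size
    if dropped:
        logger.info("make_study_area: removed %d duplicate-cell occurrences",
                    dropped)
    return mask, masked, OccurrenceSet(ox[first], oy[first],
                                       [prov[i] for i in first])


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _raster_frame(rasters: RasterStack, cells: tuple[np.ndarray, np.ndarray],
                  categorical: list[str]) -> pd.DataFrame:
    r, c = cells
    out = {}
    for name in rasters.names:
        vals = rasters.layer(name)[r, c]
        out[name] = vals
    return pd.DataFrame(out)


def _sample_background(rasters: RasterStack, n_background: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    valid = np.isfinite(rasters.data).all(axis=0)
    flat = np.nonzero(valid.ravel())[0]
    if flat.size == 0:
        raise MothscapeError("no valid cells for background sampling")
    if n_background <= flat.size:
        chosen = rng.choice(flat, size=n_background, replace=False)
    else:
        logger.warning("background (%d) exceeds available cells (%d); "
                       "sampling with replacement", n_background, flat.size)
        chosen = rng.choice(flat, size=n_background, replace=True)
    return np.unravel_index(chosen, valid.shape)


def fit_presence_background(occ: OccurrenceSet, rasters: RasterStack,
                            n_background: int = 10_000, reg: float = 1.0,
                            seed: int = 0,
                            categorical: list[str] | None = None) -> NicheModel:
    """Fit the penalized presence-background logistic model.

    Background cells are sampled uniformly from valid cells (without
    replacement when possible); the L2 penalty weight is ``reg``.
    """
    if occ.n < 20:
        raise MothscapeError("need at least 20 presence points")
    categorical = categorical or []
    continuous = [n for n in rasters.names if n not in categorical]
    rng = np.random.default_rng(seed)

    br, bc = _sample_background(rasters, n_background, rng)
    pr, pc = rasters.cell_of(occ.x, occ.y)
    pres = _raster_frame(rasters, (pr, pc), categorical)
    back = _raster_frame(rasters, (br, bc), categorical)
    frame = pd.concat([pres, back], ignore_index=True)
    y = np.r_[np.ones(len(pres)), np.zeros(len(back))]

    means = frame[continuous].mean().to_numpy()
    sds = frame[continuous].std(ddof=0).replace(0, 1.0).to_numpy()
    levels = {name: sorted(pd.unique(frame[name])) for name in categorical}

    model = NicheModel(
        feature_names=[f"{n}{suf}" for n in continuous for suf in ("", "^2")]
        + [f"{n}={lev}" for n in categorical for lev in levels[n]],
        coef=np.zeros(1), intercept=0.0, reg=reg, means=means, sds=sds,
        continuous=continuous, categorical=categorical,
        meta={"levels": levels, "n_background": n_background, "seed": seed},
    )
    X = model.design(frame)
    clf = LogisticRegression(C=1.0 / max(reg, 1e-12), max_iter=2000)
    clf.fit(X, y)
    model.coef = clf.coef_.ravel()
    model.intercept = float(clf.intercept_[0])
    model.meta["train_frame"] = frame
    model.meta["train_y"] = y
    return model


def predict_surface(model: NicheModel, rasters: RasterStack) -> SuitabilitySurface:
    valid = np.isfinite(rasters.data).all(axis=0)
    r, c = np.nonzero(valid)
    frame = _raster_frame(rasters, (r, c), model.categorical)
    grid = np.full(rasters.shape, np.nan)
    grid[r, c] = model.predict(frame)
    return SuitabilitySurface(grid=grid, x0=rasters.x0, y0=rasters.y0,
                              cell_size=rasters.cell_size)


# ---------------------------------------------------------------------------
# Cross-validation and importance
# ---------------------------------------------------------------------------

def cv_auc(occ: OccurrenceSet, rasters: RasterStack, folds: int = 5,
           holdout: float = 0.2, n_background: int = 10_000, reg: float = 1.0,
           seed: int = 0, categorical: list[str] | None = None) -> dict:
    """K-fold presence holdout with rank-based AUC against fresh background.

    Each fold trains on (1 - holdout) of the presences and scores the
    held-out presences against a freshly drawn background sample.  Returns
    per-fold AUCs, summary statistics, the fitted fold models, and the
    fold-averaged suitability surface.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(occ.n)
    fold_ids = np.arange(occ.n) % folds
    fold_of = np.empty(occ.n, int)
    fold_of[order] = fold_ids

    aucs, models, surfaces = [], [], []
    for f in range(folds):
        test = fold_of == f
        if test.sum() < 2:
            logger.warning("cv_auc: fold %d has <2 test presences; skipped", f)
            continue
        train_occ = OccurrenceSet(occ.x[~test], occ.y[~test])
        model = fit_presence_background(train_occ, rasters,
                                        n_background=n_background, reg=reg,
                                        seed=int(rng.integers(2 ** 31)),
                                        categorical=categorical)
        br, bc = _sample_background(rasters, min(n_background, 2000), rng)
        test_frame = _raster_frame(
            rasters, rasters.cell_of(occ.x[test], occ.y[test]),
            model.categorical)
        back_frame = _raster_frame(rasters, (br, bc), model.categorical)
        scores = np.r_[model.predict(test_frame), model.predict(back_frame)]
        labels = np.r_[np.ones(test.sum()), np.zeros(len(back_frame))]
        aucs.append(roc_auc_score(labels, scores))
        models.append(model)
        surfaces.append(predict_surface(model, rasters).grid)

    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN masked cells
        mean_grid = np.nanmean(np.stack(surfaces), axis=0)
    mean_surface = SuitabilitySurface(
        grid=mean_grid, x0=rasters.x0, y0=rasters.y0,
        cell_size=rasters.cell_size)
    return {
        "fold_auc": aucs,
        "mean_auc": float(np.mean(aucs)),
        "min_auc": float(np.min(aucs)),
        "max_auc": float(np.max(aucs)),
        "models": models,
        "surface": mean_surface,
    }


def permutation_importance(models: list[NicheModel], seed: int = 0,
                           ) -> ImportanceTable:
    """AUC-drop permutational importance, normalized to sum 100.

    For each fitted model and variable, that variable's column in the
    training data is permuted, the training AUC recomputed, and the drop
    recorded; drops are normalized within each model and averaged.
    """
    rng = np.random.default_rng(seed)
    per_model = []
    variables = models[0].continuous + models[0].categorical
    for model in models:
        frame = model.meta["train_frame"]
        y = model.meta["train_y"]
        base = roc_auc_score(y, model.predict(frame))
        drops = []
        for name in variables:
            shuffled = frame.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            drops.append(max(base - roc_auc_score(y, model.predict(shuffled)), 0.0))
        drops = np.asarray(drops)
        total = drops.sum()
        per_model.append(drops / total * 100 if total > 0
                         else np.full(len(variables), 100.0 / len(variables)))
    arr = np.stack(per_model)
    mean = arr.mean(axis=0)
    mean = mean / mean.sum() * 100.0
    se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
        else np.zeros(arr.shape[1])
    return ImportanceTable(pd.DataFrame(
        {"variable": variables, "mean_importance": mean, "se": se}))


# ---------------------------------------------------------------------------
# Resistance
# ---------------------------------------------------------------------------

def resistance_surface(suitability: SuitabilitySurface, floor: float = 1e-3,
                       mode: str = "reciprocal") -> ResistanceSurface:
    """Resistance as the inverse of (floored) suitability.

    ``mode='reciprocal'`` (default): conductance = max(suitability, floor),
    resistance = 1/conductance, so perfectly suitable habitat has resistance
    1 and hostile cells are capped at 1/floor.  ``mode='complement'`` is the
    linear alternative resistance = max(1 - suitability, floor), with
    conductance its reciprocal.
    """
    s = suitability.grid
    if mode == "reciprocal":
        conductance = np.where(np.isfinite(s), np.maximum(s, floor), np.nan)
        resistance = 1.0 / conductance
    elif mode == "complement":
        resistance = np.where(np.isfinite(s), np.maximum(1.0 - s, floor), np.nan)
        conductance = 1.0 / resistance
    else:
        raise MothscapeError(f"unknown resistance mode '{mode}'")
    return ResistanceSurface(resistance=resistance, conductance=conductance,
                             x0=suitability.x0, y0=suitability.y0,
                             cell_size=suitability.cell_size, floor=floor,
                             meta={"mode": mode})
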