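"""Shared containers for the landscape-genomics pipeline.

Conventions used throughout the package:

* Coordinates are planar, in km, in a single projected system.  Rasters are
  row-major 2-D arrays; the cell centre of ``grid[r, c]`` sits at
  ``(x0 + (c + 0.5) * cell_size, y0 + (r + 0.5) * cell_size)``.  Missing
  cells (outside the study mask) are NaN.
* Pairwise matrices are dense, symmetric, zero-diagonal ``float64`` arrays
  labelled by an ordered list of sample ids.  Missing / unreachable pairs
  are NaN (infinite graph distances are converted to NaN with a warning at
  the point of use).
* Genotypes are dosage-coded (count of alternate alleles, 0/1/2) with NaN
  for missing calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mothscape")

# numerical guards used across modules
EPS = 1e-12
EIG_TOL = 1e-8  # relative tolerance for "positive" eigenvalues


class MothscapeError(Exception):
    """Base class for package errors."""


class ConfigurationError(MothscapeError):
    """Invalid configuration or parameter value."""


class DegenerateResultError(MothscapeError):
    """A statistic is undefined for the given input (e.g. constant matrix)."""


class PlacementError(MothscapeError):
    """Sampling sites could not be placed (e.g. all-zero suitability)."""


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Labelled symmetric pairwise distance matrix.

    Parameters
    ----------
    ids:
        Ordered sample identifiers; row/column order of ``values``.
    values:
        Square symmetric non-negative array with a zero diagonal.  NaN marks
        a missing pair (handled by pairwise deletion downstream).
    label:
        Variable name, e.g. ``"euclidean"`` or ``"env3"``.
    kind:
        One of ``geographic | environmental | host | genetic``.
    """

    ids: list[str]
    values: np.ndarray
    label: str = ""
    kind: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MothscapeError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} ids"
            )
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T), atol=1e-9):
            raise MothscapeError(f"distance matrix '{self.label}' not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries as a 1-D vector."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, label: str = "", kind: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(i) for i in df.index], values=df.to_numpy(float),
                   label=label or Path(path).stem, kind=kind)


def as_square(values: np.ndarray, ids: Sequence[str] | None = None,
              label: str = "", kind: str = "") -> DistanceMatrix:
    """Wrap a raw array (optionally generating ids) as a DistanceMatrix."""
    values = np.asarray(values, float)
    if ids is None:
        ids = [f"s{k}" for k in range(values.shape[0])]
    return DistanceMatrix(ids=list(map(str, ids)), values=values,
                          label=label, kind=kind)


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

@dataclass
class RasterStack:
    """Congruent named single-band grids on a common planar km grid."""

    names: list[str]
    data: np.ndarray            # (n_layers, rows, cols), NaN = missing
    x0: float = 0.0             # west edge, km
    y0: float = 0.0             # south edge, km
    cell_size: float = 1.0      # km
    crs_tag: str = "planar-km"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise MothscapeError("RasterStack data must be (layers, rows, cols)")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """(row, col) of the cell containing planar point(s)."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        rows, cols = self.shape
        return np.clip(row, 0, rows - 1), np.clip(col, 0, cols - 1)

    def cell_center(self, row, col):
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y0 + (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def with_layers(self, names: list[str], data: np.ndarray) -> "RasterStack":
        return RasterStack(names=names, data=data, x0=self.x0, y0=self.y0,
                           cell_size=self.cell_size, crs_tag=self.crs_tag)


@dataclass
class SuitabilitySurface:
    """Predicted habitat suitability in [0, 1] on a raster grid."""

    grid: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        finite = self.grid[np.isfinite(self.grid)]
        if finite.size and ((finite < -1e-9).any() or (finite > 1 + 1e-9).any()):
            raise MothscapeError("suitability values must lie in [0, 1]")

    def cell_of(self, x, y):
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        rows, cols = self.grid.shape
        return np.clip(row, 0, rows - 1), np.clip(col, 0, cols - 1)


@dataclass
class ResistanceSurface:
    """Per-cell resistance with implied conductance = 1 / resistance."""

    resistance: np.ndarray
    conductance: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell_size: float = 1.0
    floor: float = 1e-3
    meta: dict = field(default_factory=dict)

    def cell_of(self, x, y):
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        rows, cols = self.resistance.shape
        return np.clip(row, 0, rows - 1), np.clip(col, 0, cols - 1)


# --- plain-TIFF + world-file raster I/O ------------------------------------
#
# Single-band layers are written as 32-bit float TIFFs with an ESRI world
# file (.tfw) carrying the affine georeference, the lingua franca of simple
# GIS interchange.  World files use the top-left, north-up convention, so the
# row order is flipped on write and read.

def write_raster(path: str | Path, grid: np.ndarray, x0: float, y0: float,
                 cell_size: float) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.flipud(np.asarray(grid, np.float32)))
    rows = grid.shape[0]
    top_center_y = y0 + (rows - 0.5) * cell_size
    world = [cell_size, 0.0, 0.0, -cell_size, x0 + 0.5 * cell_size, top_center_y]
    path.with_suffix(".tfw").write_text("\n".join(f"{v:.10f}" for v in world) + "\n")


def read_raster(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    """Read a layer written by :func:`write_raster`; returns (grid, x0, y0, cell)."""
    import tifffile

    path = Path(path)
    img = np.asarray(tifffile.imread(path), dtype=float)
    vals = [float(v) for v in path.with_suffix(".tfw").read_text().split()]
    cell = vals[0]
    x0 = vals[4] - 0.5 * cell
    rows = img.shape[0]
    y0 = vals[5] - (rows - 0.5) * cell
    return np.flipud(img), x0, y0, cell


# ---------------------------------------------------------------------------
# Genotypes and samples
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele dosage matrix.

    ``dosage`` holds 0/1/2 with NaN for missing calls.  ``loci`` is a frame
    with columns ``scaffold`` and ``pos`` (1-based bp).  ``depth`` optionally
    carries per-genotype read depth aligned to ``dosage``.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, L = self.dosage.shape
        if len(self.sample_ids) != n:
            raise MothscapeError("sample_ids length does not match dosage rows")
        if len(self.loci) != L:
            raise MothscapeError("loci table length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise MothscapeError("sample ids must be unique")
        if (self.loci["pos"] <= 0).any():
            raise MothscapeError("locus positions must be positive")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-locus alternate-allele frequency, missing ignored."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_by_sample(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def missing_by_locus(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            loci=self.loci.copy(),
            dosage=self.dosage[idx],
            depth=None if self.depth is None else self.depth[idx],
            meta=dict(self.meta),
        )

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            meta=dict(self.meta),
        )

    def imputed(self) -> np.ndarray:
        """Dosage with missing calls replaced by the locus mean."""
        X = self.dosage.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean = np.nanmean(X, axis=0)
        mean = np.where(np.isfinite(mean), mean, 0.0)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = mean[nan_c]
        return X


SAMPLE_REQUIRED = ("id", "x_km", "y_km", "site", "host")


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check the per-individual table contract (id, coordinates, host, env*)."""
    for col in SAMPLE_REQUIRED:
        if col not in samples.columns:
            raise MothscapeError(f"sample table missing required column '{col}'")
    if samples["id"].duplicated().any():
        raise MothscapeError("sample ids must be unique")
    if samples[["x_km", "y_km"]].isna().any().any():
        bad = samples.loc[samples[["x_km", "y_km"]].isna().any(axis=1), "id"]
        raise MothscapeError(f"missing coordinates for samples: {list(bad)}")
    if samples["host"].isna().any():
        raise MothscapeError("missing host labels")
    return samples


def env_columns(samples: pd.DataFrame) -> list[str]:
    return [c for c in samples.columns if c.startswith("env")]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2**31."""
    import zlib

    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)
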