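"""Synthetic landscapes, samples, and SNP genotypes with known structure.

The generator emulates a site-based landscape-genomics sampling design for a
polyphagous forest insect: ~21 collection sites spread over a heterogeneous
landscape, ~104 individuals from 4 host tree species, and a few thousand
biallelic SNPs whose allele frequencies carry three controllable signal
components on the logit scale:

* **IBD** — a locus-specific spatially autocorrelated Gaussian field, so
  genetic distance grows with geographic separation;
* **IBE** — a slope on one environmental covariate for a fraction of loci;
* **HAD** — a shift for individuals collected on a focal host species, for a
  disjoint fraction of loci.

Full-sib families can be appended by Mendelian transmission from simulated
parents, giving the kinship filter something real to detect.

This is a statistical stand-in, not a coalescent simulation: it produces the
covariance structure the downstream distance-matrix statistics consume, with
per-locus truth labels for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist
from scipy.special import expit, logit

from ._core import (
    ConfigurationError,
    GenotypeMatrix,
    PlacementError,
    RasterStack,
    SuitabilitySurface,
    logger,
    validate_sample_table,
    write_raster,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "gen_landscape",
    "place_and_annotate",
    "simulate_genotypes",
    "simulate_families",
    "write_bundle",
    "read_bundle",
    "simulate_dataset",
    "morans_i_grid",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study design.

    Defaults mirror the emulated field study: a ~640 x 640 km landscape at
    10-km resolution, 8 environmental layers, 21 collection sites, 104
    individuals from 4 host species, and 3000 biallelic SNPs.  Effect sizes
    are logit-scale; ``frac_env_loci``/``frac_host_loci`` set the fractions
    of loci carrying environmental and host effects (the rest are neutral).
    """

    grid_rows: int = 64
    grid_cols: int = 64
    cell_size: float = 10.0          # km
    n_env_layers: int = 8
    spatial_range: float = 150.0     # autocorrelation length, km
    n_individuals: int = 104
    n_hosts: int = 4
    n_sites: int = 21
    n_loci: int = 3000
    ibd_sd: float = 0.5              # SD of the logit-scale spatial field
    env_effect: float = 1.0          # logit slope per SD of environment
    frac_env_loci: float = 0.05
    frac_host_loci: float = 0.05
    host_effect: float = 1.0         # logit shift on the focal host
    host_mixing: float = 1.0         # 1 = hosts uniform everywhere, 0 = one host/site
    maf_range: tuple[float, float] = (0.05, 0.5)
    suit_coefs: tuple[float, ...] | None = None  # logit weights per env layer
    depth_mean: float | None = None  # Poisson mean of simulated read depth
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 8 or self.grid_cols < 8:
            raise ConfigurationError("grid must be at least 8x8")
        if self.spatial_range <= 0:
            raise ConfigurationError("spatial_range must be positive")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.frac_env_loci + self.frac_host_loci > 1 + 1e-12:
            raise ConfigurationError("frac_env_loci + frac_host_loci must be <= 1")
        for name in ("ibd_sd", "env_effect", "host_effect"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must be a non-empty interval in (0, 0.5]")
        if not (0 <= self.host_mixing <= 1):
            raise ConfigurationError("host_mixing must be in [0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class TruthRecord:
    """Per-locus ground truth of the generative model."""

    loci: pd.DataFrame  # columns: locus, class, variable, effect
    host_focal: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.loci.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def _grf(shape: tuple[int, int], sigma_cells: float,
         rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field by smoothing white noise.

    A Gaussian smoothing kernel of width ``sigma_cells`` (wrap boundary, i.e.
    circulant) yields a stationary field with Gaussian autocovariance
    exp(-d^2 / (4 sigma^2)); the 1/e correlation length is 2*sigma cells.
    """
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=sigma_cells, mode="wrap")
    return (f - f.mean()) / f.std()


def gen_landscape(config: SimulationConfig) -> tuple[RasterStack, SuitabilitySurface]:
    """Generate environmental layers and a habitat-suitability surface.

    Suitability is the logistic transform of a linear combination of the
    standardized layers (``config.suit_coefs``; default weight 1 on layer 1
    and -0.5 on layer 2), so all cells fall in [0, 1].
    """
    shape = (config.grid_rows, config.grid_cols)
    sigma = config.spatial_range / (2.0 * config.cell_size)
    rng = config.rng(stage=1)
    layers = np.stack([_grf(shape, sigma, rng) for _ in range(config.n_env_layers)])
    names = [f"env{k + 1}" for k in range(config.n_env_layers)]
    stack = RasterStack(names=names, data=layers, x0=0.0, y0=0.0,
                        cell_size=config.cell_size)

    coefs = config.suit_coefs
    if coefs is None:
        coefs = tuple([1.0, -0.5][: config.n_env_layers]
                      + [0.0] * max(0, config.n_env_layers - 2))
    if len(coefs) != config.n_env_layers:
        raise ConfigurationError("suit_coefs length must equal n_env_layers")
    lin = np.tensordot(np.asarray(coefs), layers, axes=1)
    suit = SuitabilitySurface(grid=expit(lin), x0=0.0, y0=0.0,
                              cell_size=config.cell_size,
                              meta={"coefs": list(coefs)})
    return stack, suit


# ---------------------------------------------------------------------------
# Sampling design
# ---------------------------------------------------------------------------

def place_and_annotate(config: SimulationConfig, rasters: RasterStack,
                       suitability: SuitabilitySurface) -> pd.DataFrame:
    """Place sites and individuals on the landscape and annotate them.

    Site cells are drawn with probability proportional to suitability
    (without replacement); individuals are spread over sites as evenly as
    possible and jittered within their site's cell.  Host labels come from
    a site-level mixture: with probability ``host_mixing`` a uniform draw
    over hosts, otherwise the site's resident host.  Environmental values
    are the raster values at each individual's cell.
    """
    grid = suitability.grid
    flat = np.where(np.isfinite(grid.ravel()), grid.ravel(), 0.0)
    total = flat.sum()
    if total <= 0:
        raise PlacementError("suitability is zero everywhere; cannot place sites")
    if (flat > 0).sum() < config.n_sites:
        raise PlacementError("fewer positive-suitability cells than sites")

    rng = config.rng(stage=2)
    site_cells = rng.choice(flat.size, size=config.n_sites, replace=False,
                            p=flat / total)
    rows, cols = np.unravel_index(site_cells, grid.shape)

    # even allocation of individuals over sites
    site_of_ind = np.arange(config.n_individuals) % config.n_sites
    rng.shuffle(site_of_ind)

    r = rows[site_of_ind]
    c = cols[site_of_ind]
    cs = config.cell_size
    x = rasters.x0 + (c + rng.uniform(0.05, 0.95, size=r.size)) * cs
    y = rasters.y0 + (r + rng.uniform(0.05, 0.95, size=r.size)) * cs

    resident = np.arange(config.n_sites) % config.n_hosts
    uniform_draw = rng.integers(0, config.n_hosts, size=config.n_individuals)
    mixed = rng.random(config.n_individuals) < config.host_mixing
    host_idx = np.where(mixed, uniform_draw, resident[site_of_ind])

    table = pd.DataFrame({
        "id": [f"ind{k:04d}" for k in range(config.n_individuals)],
        "x_km": x,
        "y_km": y,
        "site": [f"site{s:02d}" for s in site_of_ind],
        "host": [f"host{h}" for h in host_idx],
    })
    for name in rasters.names:
        table[name] = rasters.layer(name)[r, c]
    return validate_sample_table(table)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _spatial_factor(coords: np.ndarray, spatial_range: float) -> np.ndarray:
    """Cholesky factor of an exponential spatial correlation among samples."""
    d = cdist(coords, coords)
    cov = np.exp(-d / spatial_range)
    cov[np.diag_indices_from(cov)] += 1e-9
    return np.linalg.cholesky(cov)


def simulate_genotypes(config: SimulationConfig, samples: pd.DataFrame,
                       rasters: RasterStack) -> tuple[GenotypeMatrix, TruthRecord]:
    """Draw genotypes from the logit-additive allele-frequency model.

    For locus *l* and individual *i*::

        logit p_il = logit(p0_l) + ibd_sd * G_l(x_i, y_i)
                     + env_effect * b_l * env_l(i)      (env-linked loci)
                     + host_effect * [host_i == focal_l] (host-linked loci)
        genotype_il ~ Binomial(2, clamp(p_il, 0.001, 0.999))

    where G_l is a locus-specific unit-variance spatial field with
    exponential correlation at the configured range, b_l is a random sign,
    and env_l is a standardized environmental covariate cycled over layers.
    """
    lo, hi = config.maf_range
    if not (hi > 0):
        raise ConfigurationError("empty maf_range")
    n, L = len(samples), config.n_loci
    rng = config.rng(stage=3)

    p0 = rng.uniform(lo, hi, size=L)

    n_env = int(round(config.frac_env_loci * L))
    n_host = int(round(config.frac_host_loci * L))
    classes = np.array(["neutral"] * L, dtype=object)
    perm = rng.permutation(L)
    env_loci = perm[:n_env]
    host_loci = perm[n_env:n_env + n_host]
    classes[env_loci] = "env"
    classes[host_loci] = "host"

    eta = np.tile(logit(p0), (n, 1))

    if config.ibd_sd > 0:
        coords = samples[["x_km", "y_km"]].to_numpy(float)
        chol = _spatial_factor(coords, config.spatial_range)
        eta += config.ibd_sd * (chol @ rng.standard_normal((n, L)))

    env_cols = [c for c in samples.columns if c.startswith("env")]
    var_of = np.full(L, "", dtype=object)
    eff = np.zeros(L)
    if n_env and config.env_effect > 0 and env_cols:
        signs = rng.choice([-1.0, 1.0], size=n_env)
        for k, (l, s) in enumerate(zip(env_loci, signs)):
            col = env_cols[k % len(env_cols)]
            v = samples[col].to_numpy(float)
            sd = v.std()
            z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
            eta[:, l] += config.env_effect * s * z
            var_of[l] = col
            eff[l] = config.env_effect * s
    host_focal: dict[int, str] = {}
    if n_host and config.host_effect > 0:
        hosts = sorted(samples["host"].unique())
        focal_idx = rng.integers(0, len(hosts), size=n_host)
        host_arr = samples["host"].to_numpy()
        for l, f in zip(host_loci, focal_idx):
            eta[:, l] += config.host_effect * (host_arr == hosts[f])
            var_of[l] = hosts[f]
            eff[l] = config.host_effect
            host_focal[int(l)] = hosts[f]

    p = np.clip(expit(eta), 1e-3, 1 - 1e-3)
    dosage = rng.binomial(2, p).astype(float)

    # spread loci over synthetic scaffolds with increasing positions
    n_scaffolds = max(1, L // 200)
    scaff = np.array([f"scaffold_{l % n_scaffolds + 1:04d}" for l in range(L)])
    pos = np.zeros(L, dtype=int)
    for s in np.unique(scaff):
        m = scaff == s
        pos[m] = 15000 * (np.arange(m.sum()) + 1)
    loci = pd.DataFrame({"scaffold": scaff, "pos": pos})
    order = np.lexsort((pos, scaff))
    loci = loci.iloc[order].reset_index(drop=True)

    depth = None
    if config.depth_mean is not None:
        depth = rng.poisson(config.depth_mean,
                            size=(n, L)).astype(float)[:, order]
    g = GenotypeMatrix(sample_ids=list(samples["id"]), loci=loci,
                       dosage=dosage[:, order], depth=depth,
                       meta={"generator": "logit-additive", "config": asdict(config)})
    truth = TruthRecord(loci=pd.DataFrame({
        "locus": np.arange(L),
        "class": classes[order],
        "variable": var_of[order],
        "effect": eff[order],
    }), host_focal=host_focal)
    return g, truth


def simulate_families(parent_genotypes: np.ndarray, n_offspring: int,
                      seed: int) -> np.ndarray:
    """Full-sib offspring by independent Mendelian transmission per locus.

    ``parent_genotypes`` is a (2, L) dosage array; each offspring receives
    one allele per parent, Bernoulli(dosage/2).  Returns (n_offspring, L).
    """
    parents = np.asarray(parent_genotypes, dtype=float)
    if parents.ndim != 2 or parents.shape[0] != 2:
        raise ConfigurationError("parent_genotypes must be a (2, L) array")
    if np.isnan(parents).any():
        raise ConfigurationError("parents must have no missing genotypes")
    rng = np.random.default_rng(seed)
    L = parents.shape[1]
    off = np.zeros((n_offspring, L))
    for parent in parents:
        off += rng.binomial(1, np.tile(parent / 2.0, (n_offspring, 1)))
    return off


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal VCF v4.2 with GT (and DP when present)."""
    path = Path(path)
    has_dp = g.depth is not None
    fmt = "GT:DP" if has_dp else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for s in sorted(g.loci["scaffold"].unique()):
            fh.write(f"##contig=<ID={s}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        order = np.lexsort((g.loci["pos"].to_numpy(), g.loci["scaffold"].to_numpy()))
        for l in order:
            rec = g.loci.iloc[l]
            cells = []
            for i in range(g.n_samples):
                d = g.dosage[i, l]
                gt = "./." if np.isnan(d) else _GT_CODE[float(d)]
                if has_dp:
                    dp = g.depth[i, l]
                    gt += ":" + (str(int(dp)) if np.isfinite(dp) else ".")
                cells.append(gt)
            fh.write(f"{rec['scaffold']}\t{int(rec['pos'])}\tL{l}\tA\tT\t.\tPASS\t.\t"
                     f"{fmt}\t" + "\t".join(cells) + "\n")


def write_bundle(genotypes: GenotypeMatrix, samples: pd.DataFrame,
                 rasters: RasterStack, outdir: str | Path,
                 suitability: SuitabilitySurface | None = None,
                 truth: TruthRecord | None = None) -> dict[str, Path]:
    """Serialize a simulated dataset (VCF, sample CSV, raster TIFFs, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if list(samples["id"]) != list(genotypes.sample_ids):
        raise ConfigurationError("sample table ids do not match genotype ids")
    files: dict[str, Path] = {}
    files["vcf"] = outdir / "genotypes.vcf"
    write_vcf(genotypes, files["vcf"])
    files["samples"] = outdir / "samples.csv"
    samples.to_csv(files["samples"], index=False)
    for k, name in enumerate(rasters.names):
        p = outdir / f"{name}.tif"
        write_raster(p, rasters.data[k], rasters.x0, rasters.y0, rasters.cell_size)
        files[name] = p
    if suitability is not None:
        files["suitability"] = outdir / "suitability.tif"
        write_raster(files["suitability"], suitability.grid, suitability.x0,
                     suitability.y0, suitability.cell_size)
    if truth is not None:
        files["truth"] = outdir / "truth.csv"
        truth.to_csv(files["truth"])
    logger.info("wrote synthetic bundle to %s (%d files)", outdir, len(files))
    return files


def read_bundle(outdir: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame, RasterStack]:
    """Read back a bundle written by :func:`write_bundle`."""
    from .geno_qc import read_vcf
    from ._core import read_raster

    outdir = Path(outdir)
    g = read_vcf(outdir / "genotypes.vcf")
    samples = pd.read_csv(outdir / "samples.csv")
    names = sorted([p.stem for p in outdir.glob("env*.tif")],
                   key=lambda s: int(s[3:]))
    grids, x0, y0, cell = [], 0.0, 0.0, 1.0
    for name in names:
        grid, x0, y0, cell = read_raster(outdir / f"{name}.tif")
        grids.append(grid)
    stack = RasterStack(names=names, data=np.stack(grids), x0=x0, y0=y0,
                        cell_size=cell)
    return g, samples, stack


def simulate_dataset(config: SimulationConfig):
    """Convenience: landscape -> samples -> genotypes in one call."""
    rasters, suit = gen_landscape(config)
    samples = place_and_annotate(config, rasters, suit)
    g, truth = simulate_genotypes(config, samples, rasters)
    return rasters, suit, samples, g, truth


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def morans_i_grid(field: np.ndarray) -> float:
    """Moran's I of a grid under rook (4-neighbour) contiguity weights."""
    z = field - field.mean()
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    w = z[:, :-1].size + z[:-1, :].size  # each unordered pair counted once
    return float((z.size / (2 * w)) * (2 * num) / (z ** 2).sum())
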