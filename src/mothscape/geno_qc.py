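"""VCF ingest, QC filter chain, kinship, sibling removal, genetic distance.

The filter chain mirrors a standard RAD-seq protocol: (1) drop individuals
with >25% missing calls, (2) mask genotypes below a read-depth floor and
drop low-mean-depth loci, (3) drop loci with minor-allele frequency <0.05,
(4) drop loci with >5% missing calls, and (5) thin loci so no pair within a
scaffold is closer than 10 kb (a linkage-disequilibrium decay bound for
Lepidoptera).  Full siblings are detected with a method-of-moments kinship
estimator whose expectation is 0.25 for full sibs and ~0 for unrelated
pairs, and removed above a 0.22 break point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._core import (
    DistanceMatrix,
    GenotypeMatrix,
    MothscapeError,
    logger,
)

__all__ = [
    "read_vcf",
    "FilterReport",
    "apply_filters",
    "thin_loci",
    "KinshipMatrix",
    "kinship_matrix",
    "drop_relatives",
    "genetic_distance",
]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Dosage counts alternate alleles; ``./.`` becomes NaN.  Multiallelic and
    non-SNP records are skipped and counted in ``meta['skipped_records']``.
    FORMAT/DP, when present, is carried along per genotype.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise MothscapeError(f"cannot parse VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    dosages: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    scaffolds: list[str] = []
    positions: list[int] = []
    skipped = 0
    any_dp = False
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            skipped += 1
            continue
        gt = variant.gt_types.astype(float)  # 0/1/2, 3 = unknown (gts012)
        gt[gt == 3] = np.nan
        dosages.append(gt)
        try:
            dp = variant.format("DP")
        except Exception:
            dp = None
        if dp is not None:
            dp = dp.astype(float).reshape(-1)
            dp[dp < 0] = np.nan
            depths.append(dp)
            any_dp = True
        else:
            depths.append(np.full(len(sample_ids), np.nan))
        scaffolds.append(variant.CHROM)
        positions.append(variant.POS)
    vcf.close()

    if not dosages:
        raise MothscapeError(f"no usable biallelic SNP records in {path}")
    dosage = np.stack(dosages, axis=1)
    depth = np.stack(depths, axis=1) if any_dp else None
    loci = pd.DataFrame({"scaffold": scaffolds, "pos": positions})
    if skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", skipped)
    return GenotypeMatrix(sample_ids=sample_ids, loci=loci, dosage=dosage,
                          depth=depth, meta={"skipped_records": skipped})


# ---------------------------------------------------------------------------
# Filter chain
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`apply_filters`."""

    individuals_missing: int = 0
    genotypes_depth_masked: int = 0
    loci_mean_depth: int = 0
    loci_maf: int = 0
    loci_missing: int = 0
    empty_result: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": ["individuals_missing", "genotypes_depth_masked",
                      "loci_mean_depth", "loci_maf", "loci_missing"],
             "removed": [self.individuals_missing, self.genotypes_depth_masked,
                         self.loci_mean_depth, self.loci_maf, self.loci_missing]}
        )


def apply_filters(g: GenotypeMatrix, max_ind_missing: float = 0.25,
                  min_depth: float = 5, min_maf: float = 0.05,
                  max_locus_missing: float = 0.05,
                  ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the QC chain in its fixed order; thresholds are strict where noted.

    Individuals are removed when missingness is strictly greater than
    ``max_ind_missing``; loci are removed when MAF is strictly below
    ``min_maf`` or missingness strictly above ``max_locus_missing``.  MAF is
    recomputed after depth masking.  Returns the surviving matrix and a
    per-rule report; an empty result is signalled, not raised.
    """
    report = FilterReport()

    # (1) individual missingness
    keep_ind = g.missing_by_sample() <= max_ind_missing
    report.individuals_missing = int((~keep_ind).sum())
    g = g.take_samples(np.nonzero(keep_ind)[0])

    # (2) depth: per-genotype masking, then per-locus mean depth
    if g.depth is not None and g.n_samples:
        low = (g.depth < min_depth) & ~np.isnan(g.dosage)
        report.genotypes_depth_masked = int(low.sum())
        dosage = g.dosage.copy()
        dosage[low] = np.nan
        g = GenotypeMatrix(g.sample_ids, g.loci, dosage, g.depth, dict(g.meta))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_depth = np.where(
                (~np.isnan(g.dosage)).any(axis=0),
                np.nanmean(np.where(np.isnan(g.dosage), np.nan, g.depth), axis=0),
                0.0,
            )
        keep = mean_depth >= min_depth
        report.loci_mean_depth = int((~keep).sum())
        g = g.take_loci(np.nonzero(keep)[0])

    if g.n_samples == 0 or g.n_loci == 0:
        report.empty_result = True
        return g, report

    # (3) minor allele frequency (recomputed post-masking)
    keep = g.maf() >= min_maf
    keep &= ~np.isnan(g.maf())
    report.loci_maf = int((~keep).sum())
    g = g.take_loci(np.nonzero(keep)[0])

    # (4) locus missingness
    if g.n_loci:
        keep = g.missing_by_locus() <= max_locus_missing
        report.loci_missing = int((~keep).sum())
        g = g.take_loci(np.nonzero(keep)[0])

    report.empty_result = g.n_samples == 0 or g.n_loci == 0
    return g, report


def thin_loci(g: GenotypeMatrix, min_gap_bp: int = 10_000) -> GenotypeMatrix:
    """Greedy physical thinning within scaffolds.

    Loci are scanned in (scaffold, position) order; the first locus on each
    scaffold is kept and thereafter any locus at least ``min_gap_bp`` from
    the last kept one ("within <10 kb" is strict, so an exact 10-kb gap
    survives).
    """
    scaff = g.loci["scaffold"].to_numpy()
    pos = g.loci["pos"].to_numpy()
    order = np.lexsort((pos, scaff))
    keep: list[int] = []
    last_scaffold = None
    last_pos = None
    for idx in order:
        if scaff[idx] != last_scaffold or pos[idx] - last_pos >= min_gap_bp:
            keep.append(idx)
            last_scaffold, last_pos = scaff[idx], pos[idx]
    keep_sorted = order[np.isin(order, keep)]
    return g.take_loci(keep_sorted)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Pairwise kinship coefficients with the estimator recorded."""

    ids: list[str]
    values: np.ndarray
    estimator: str = "grm-mom/2"

    def pairs_above(self, threshold: float) -> list[tuple[int, int]]:
        n = len(self.ids)
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                if self.values[i, j] > threshold:
                    out.append((i, j))
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


def kinship_matrix(g: GenotypeMatrix) -> KinshipMatrix:
    """Method-of-moments kinship: half the standardized genetic relationship.

    With sample allele frequency p_l, the per-locus contribution for pair
    (i, j) is (x_il - 2 p_l)(x_jl - 2 p_l) / (2 p_l (1 - p_l)); averaging
    over pairwise-complete polymorphic loci and halving gives an estimator
    whose expectation is 0.25 for full siblings, 0.5 for self, and 0 for
    unrelated individuals.
    """
    if g.n_samples < 2:
        raise MothscapeError("kinship needs at least two individuals")
    X = g.dosage
    p = g.allele_freq()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    X = X[:, poly]
    p = p[poly]
    denom = np.sqrt(2 * p * (1 - p))
    Z = (X - 2 * p) / denom
    obs = np.isfinite(Z)
    Z0 = np.where(obs, Z, 0.0)
    counts = obs.astype(float) @ obs.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = (Z0 @ Z0.T) / counts / 2.0
    K[counts == 0] = np.nan
    return KinshipMatrix(ids=list(g.sample_ids), values=K)


def drop_relatives(g: GenotypeMatrix, kin: KinshipMatrix,
                   threshold: float = 0.22,
                   ) -> tuple[GenotypeMatrix, list[str]]:
    """Iteratively remove one member of every pair above the kinship break.

    From each offending pair the individual with the larger missing-data
    fraction is removed (ties: larger kinship row-sum, then lexicographic
    id), generalizing the pairwise rule to sibling cliques.
    """
    if kin.ids != list(g.sample_ids):
        raise MothscapeError("kinship matrix not aligned to genotype matrix")
    K = kin.values.copy()
    np.fill_diagonal(K, -np.inf)
    miss = g.missing_by_sample()
    active = np.ones(g.n_samples, dtype=bool)
    removed: list[str] = []
    while True:
        sub = np.where(active[:, None] & active[None, :], K, -np.inf)
        i, j = np.unravel_index(np.nanargmax(sub), sub.shape)
        if not (sub[i, j] > threshold):
            break
        if miss[i] != miss[j]:
            drop = i if miss[i] > miss[j] else j
        else:
            rs_i = np.nansum(np.where(active, K[i], 0.0))
            rs_j = np.nansum(np.where(active, K[j], 0.0))
            if rs_i != rs_j:
                drop = i if rs_i > rs_j else j
            else:
                drop = max(i, j, key=lambda k: g.sample_ids[k])
        active[drop] = False
        removed.append(g.sample_ids[drop])
    logger.info("drop_relatives: removed %d individuals above %.2f",
                len(removed), threshold)
    return g.take_samples(np.nonzero(active)[0]), removed


def genetic_distance(g: GenotypeMatrix, impute: str = "locus_mean",
                     squared: bool = False) -> DistanceMatrix:
    """Pairwise Euclidean distance over locus-mean-imputed dosage vectors.

    ``squared=True`` returns squared Euclidean distances; the choice is
    recorded in the result metadata because both conventions appear in the
    literature under the same name.
    """
    if g.n_samples < 2:
        raise MothscapeError("need at least two individuals")
    if impute != "locus_mean":
        raise MothscapeError(f"unknown imputation '{impute}'")
    all_missing = np.isnan(g.dosage).all(axis=0)
    if all_missing.any():
        logger.warning("genetic_distance: dropping %d all-missing loci",
                       int(all_missing.sum()))
        g = g.take_loci(np.nonzero(~all_missing)[0])
    X = g.imputed()
    d = pdist(X, metric="sqeuclidean" if squared else "euclidean")
    return DistanceMatrix(ids=list(g.sample_ids), values=squareform(d),
                          label="genetic", kind="genetic",
                          meta={"metric": "squared_euclidean" if squared
                                else "euclidean", "impute": impute})
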