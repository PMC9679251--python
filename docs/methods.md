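# Methods

This note records the models, conventions, and numerical choices behind
`mothscape`, and what its synthetic-data tests do and do not demonstrate
about real data.

## The inference problem

Genomic differentiation within a species can arise from geographic
isolation (distance or landscape resistance limiting gene flow), from
divergent selection along environmental gradients, or — for phytophagous
insects — from host-plant association. These causes are confounded in
observational data: hosts and environments are themselves spatially
structured. The package therefore works throughout with *pairwise distance
matrices* (genetic, geographic, environmental, host) and uses two
complementary devices to separate the causes: reciprocal partial Mantel
tests (which condition one candidate on another) and constrained
ordination with variance partitioning (which attributes adjusted R² to
unique and shared combinations of predictor sets).

## Synthetic generative model

The generator is a *statistical* stand-in, not a population-genetic
simulator. Its purpose is to produce data whose covariance structure
matches what the downstream statistics assume, with known truth:

* **Landscape.** `n_env_layers` unit-variance Gaussian random fields on a
  `grid_rows x grid_cols` grid (default 64 x 64 cells of 10 km), built by
  Gaussian smoothing of white noise with wrap-around boundaries; the
  smoothing width is `spatial_range / (2 * cell_size)`, giving a Gaussian
  autocovariance with 1/e correlation length ≈ `spatial_range` (default
  150 km). Habitat suitability is the logistic transform of a linear
  combination of the layers (default weights 1 and −0.5 on the first two).
* **Sampling design.** `n_sites` (default 21) site cells drawn with
  probability proportional to suitability; `n_individuals` (default 104)
  spread evenly over sites; `n_hosts` (default 4) host labels drawn from a
  site-level mixture: with probability `host_mixing` a uniform draw,
  otherwise the site's resident host. `host_mixing = 1` makes host
  assignment independent of geography — something real data cannot offer —
  so HAD recovery can be tested unconfounded; `host_mixing = 0` maximally
  confounds them.
* **Genotypes.** For locus *l* with ancestral frequency
  `p0_l ~ Uniform(maf_range)` (default (0.05, 0.5)), the individual-level
  frequency on the logit scale is

      logit p_il = logit(p0_l) + ibd_sd * G_l(x_i)            [IBD]
                   + env_effect * b_l * env_std(x_i)          [IBE]
                   + host_effect * 1[host_i = focal_l]        [HAD]

  where `G_l` is a locus-specific spatial field with exponential
  correlation `exp(-d / spatial_range)` realized only at the sampled
  coordinates (Cholesky of the 104 x 104 correlation matrix), `b_l` a
  random sign on one environmental covariate (cycled over layers), and
  `focal_l` a random focal host. Env- and host-linked loci are disjoint
  fractions `frac_env_loci`, `frac_host_loci` (defaults 0.05 each);
  default effect sizes are `ibd_sd = 0.5`, `env_effect = 1.0`,
  `host_effect = 1.0` on the logit scale. Frequencies are clamped to
  [0.001, 0.999] before the Binomial(2, p) draw, so no locus is degenerate.
* **Families.** Full sibs by independent Mendelian transmission per locus
  from dosage-coded parents; this is exact, so the kinship estimator's
  0.25 expectation is a true calibration target.

What the generator does **not** emulate: linkage disequilibrium (loci are
independent), drift along a pedigree or coalescent history, sequencing
error, allele dropout, or realistic missingness patterns (missing data
enter only through the optional Poisson read-depth layer and the QC mask).
Passing tests therefore demonstrate that the *statistics* behave correctly
under their own assumptions, not that those assumptions hold for any
particular empirical dataset.

## QC conventions

* Thresholds follow the emulated protocol: individuals with missingness
  strictly above 0.25 are dropped; "read depth below five" is read as
  per-genotype masking at depth < 5 followed by dropping loci whose mean
  depth over retained calls is < 5 (the protocol sentence is ambiguous
  between genotype- and locus-level; both interpretations are applied and
  separately reported); MAF < 0.05 (recomputed after depth masking);
  locus missingness > 0.05; greedy 10-kb thinning per scaffold ("within
  <10 kb" is strict, so an exact 10-kb gap survives).
* **Kinship** is half the standardized genetic relationship computed over
  pairwise-complete polymorphic loci with *sample* allele frequencies.
  Expectation: 0.25 for full sibs, 0.5 for self, 0 for unrelated — minus a
  bias of order 1/n from estimating frequencies from the sample itself
  (measured ≈ −0.002 at n = 400, ≈ −0.017 at n = 60). The sib filter's
  0.22 threshold leaves ample margin at realistic sample sizes.
* **Relative removal** generalizes the pairwise rule to cliques:
  iteratively remove, from the currently worst pair, the individual with
  more missing data (ties: larger kinship row-sum, then lexicographic id),
  until no pair exceeds the threshold.
* **Genetic distance** is Euclidean over locus-mean-imputed dosage
  vectors. Because "Euclidean" and "squared Euclidean" both circulate
  under this name, the `squared` flag selects the convention and the
  choice is recorded in the matrix metadata; default is plain Euclidean
  (which is metric, so its PCoA has no negative eigenvalues).

## Niche model and resistance

The presence–background model is a penalized logistic regression — the
same inputs and outputs as maximum-entropy niche models (presences,
uniform background, logistic suitability in [0, 1], holdout AUC,
permutational importance) with a simpler, deterministic estimator.
Features are standardized linear + quadratic terms for continuous layers
and one-hot terms for categorical ones; hinge/product features are
deliberately omitted. The penalty weight `reg` (default 1.0) multiplies
the L2 term, so training log-likelihood is non-increasing in it.

The study area is the convex hull of the collection points buffered by 50
km; occurrences are deduplicated at one-cell granularity. Cross-validation
holds out 20% of presences per fold (5 folds) and scores rank-based AUC
against freshly drawn background. Permutational importance is the drop in
training AUC when one variable is shuffled, normalized to sum 100 within
each fold model and averaged.

Resistance: conductance = max(suitability, floor) with floor 0.001;
resistance its reciprocal (so perfect habitat has resistance 1, hostile
cells cap at 1000). A linear `1 − suitability` alternative is available by
flag.

## Graph distances

The raster becomes an undirected graph on non-missing cells with
8-neighbour connectivity (4-neighbour available); edge conductance is the
arithmetic mean of the two cells' conductances (harmonic available), edge
length `cell_size` (× √2 diagonally). Least-cost distance minimizes the
summed `length / conductance`. Effective resistance treats edge
conductances as circuit conductances and solves grounded-Laplacian systems
per connected component (dense solve below 1500 nodes, sparse LU above);
this matches a single edge of conductance c having resistance 1/c and is
verified against the Laplacian pseudo-inverse on random small graphs.
Edge length is deliberately *not* folded into the resistance weights: the
two geographic distances answer different questions (optimal-route cost
vs. all-routes connectivity) and keep their own conventions. Samples snap
to their containing cell; co-located samples get zero graph distance.
Disconnected pairs propagate as missing values with a logged warning and
are removed by pairwise deletion in the Mantel stage.

## Mantel tests and RCM

The Mantel statistic is the Pearson correlation of strictly-lower-triangle
entries; the partial statistic is the first-order partial correlation
(verified to 1e-12 against residual-on-residual regression). Nulls permute
the focal predictor matrix's rows and columns jointly and recompute the
full statistic; a residual-permutation scheme is available. Tests are
one-tailed (upper) by default, matching the directional isolation
hypotheses; p-values use the add-one rule and are never zero; an
exhaustive mode enumerates all n! relabelings for small n and reproduces
the enumeration p exactly.

RCM runs both orderings of every unordered predictor pair against the
response and reports the support index R_PM-A − R_PM-B in a matrix whose
rows are focal variables (antisymmetric by construction) plus a long-form
table of all coefficients and p-values.

## Ordination and variance partitioning

* **PCoA**: Gower double-centering of −D²/2, symmetric eigendecomposition,
  axes scaled by √eigenvalue. Negative eigenvalues (possible for
  non-metric inputs) are counted, logged, and excluded; no Lingoes/Cailliez
  correction is applied because the default genetic distance is metric.
* **dbMEM/PCNM**: minimum spanning distance = largest MST edge of the
  Euclidean matrix; truncation threshold = 4 × that distance (exact
  identity, tested); super-threshold entries are replaced by 4 × threshold
  (the PCNM convention). A "paper-literal" mode replaces them with the
  threshold itself, for comparability with descriptions that say distances
  were "truncated to" the threshold; the two conventions yield different
  eigenvectors, and the mode is recorded on the basis object.
* **MEM selection** exploits the basis orthonormality: each eigenvector's
  marginal SS is its own projection norm, so all per-eigenvector pseudo-F
  statistics are tested against one joint stream of response-row
  permutations. Retention at p ≤ 0.05; empty retention is legal and drops
  the geography block downstream.
* **dbRDA** regresses the PCoA coordinates on the standardized predictor
  block (host one-hot coded, alphabetically first level dropped, h−1 df).
  Collinearity is a hard error naming the offending columns; VIFs come
  from the inverse correlation matrix.
* **Permutational ANOVA** is marginal (each term's SS is its drop from the
  full model), matching a single p-value per multi-df host term. The null
  permutes the centered response rows jointly for all terms — the
  behaviour of the standard constrained-ordination implementation when no
  conditioning block is present. A per-term reduced-model-residual
  (Freedman–Lane) scheme is provided as an option; in the near-isotropic
  high-dimensional geometry of genetic-distance responses it proved
  conservative (rejection ≈ 0.015–0.02 at nominal 0.05 in 300 neutral
  replicates, vs. 0.03–0.04 for the direct scheme), which is why direct
  permutation is the default.
* **Variance partitioning** computes adjusted R² (Ezekiel:
  `1 − (1 − R²)(n−1)/(n−1−p)`) for all seven non-empty unions of the
  three predictor sets and solves the 7×7 membership system for the three
  unique, three pairwise-shared, and one three-way fraction; the fractions
  sum to the full model's adjusted R² exactly (enforced to the last bit)
  and shared fractions may legitimately be negative. Raw-R² mode exists
  for debugging.

## Selection scans

* **FST** follows Weir & Cockerham (1984): per-locus variance components
  a, b, c from group sizes, allele frequencies, and observed
  heterozygosities; per-locus θ = a/(a+b+c); the multilocus estimate is
  the ratio of sums, never the mean of ratios. Loci with fewer than two
  genotyped individuals in any group, or monomorphic across groups, are
  excluded. The implementation matches a scalar transcription of the
  published formulas to 1e-12 on exhaustive small configurations.
* **Outlier scan**: the Bayesian machinery of the original outlier method
  is deliberately not implemented; a permutation null takes its place and
  produces the same decision object (per-locus q-values at FDR 0.05).
  Labels are permuted once per replicate and all loci rescored; the pooled
  replicate × locus null gives add-one upper-tail p-values, then BH
  q-values. A per-locus null mode exists for heterogeneous-MAF settings.
* **GEA**: per locus, least squares of dosage on [intercept,
  standardized environmental variable, K latent factors], where the
  factors are the top-K left singular vectors of the centered imputed
  dosage matrix (K defaults to 2, user-set; no automatic selection). The
  per-locus t-statistic is mapped through its Student-t null CDF to a
  standard-normal z — at n ≈ 100 the raw t's heavier tails would inflate
  Bonferroni-level errors roughly 2.5-fold. λ = median(z²)/0.4549 rescales
  z² before the χ²₁ upper-tail p. The multi-run median-|z| bookkeeping is
  retained: runs differ only through re-drawn binomial imputation of
  missing genotypes (and re-estimated factors); with complete data the
  runs collapse to identical values and this is logged as degenerate.
  Loci significant for several collinear variables are assigned to the
  variable with the largest median |z| (ties report all).

## Orchestration

A single global seed expands to per-stage seeds by hashing the stage name
(CRC32 XOR seed, mod 2³¹), so toggling one stage never shifts another's
random stream; identical configs give byte-identical output tables. When
the pipeline simulates its own data, the niche stage supplements the
sequenced-sample occurrences with extra points drawn from the true
suitability surface, playing the role of external occurrence records.
Raster layers travel as single-band TIFFs with plain-text ESRI world
files for georeferencing.

## Test and calibration scales

The simulation studies in the test suite use reduced problem sizes chosen
to keep each study's Monte-Carlo error well inside its assertion band:
type-I calibration uses 500 neutral replicates at n = 60 individuals,
L = 500 loci, 12 sites with 99 permutations per test (p-value granularity
0.01, so the nominal 0.05 is attainable exactly); parameter recovery uses
50 replicates at n = 150, L = 2000, 21 sites with the default effect
sizes and 10% env-/host-linked loci; oracle equivalences run on ≤6-node
graphs and ≤(3,3) group configurations where brute force is exact. The
kinship calibration (200 sib pairs × 5000 loci) matches its target's
stated design exactly.

## Known limitations

* Partial Mantel tests are known to be anti-conservative under strong
  spatial autocorrelation of both matrices; no correction is applied (by
  design — the framework is reimplemented as used, with its warts).
* The niche model's feature space (linear + quadratic + one-hot) is a
  simplification; empirical AUCs and importance rankings from
  full-featured maximum-entropy models are not comparable targets.
* The generator's logit-additive model produces exchangeable individuals
  within a cell and no LD; statistics that exploit LD or pedigree depth
  have no power to demonstrate here.
* Effective-resistance distances grow without bound as the resistance
  floor shrinks on hostile landscapes; the floor (default 0.001) is the
  operative cap and should be reported with any result.
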