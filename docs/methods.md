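# Methods

This note documents the models and procedures implemented in `microgeo`,
their assumptions and tunable parameters, the design choices made where the
method was genuinely open, what the synthetic-data generator does and does
not emulate, and known limitations.

## Consensus calling and quality control

A sample's marker-gene pileup is reduced to per-position base counts. The
consensus base is the strict-majority base; a position becomes `N` when its
depth is below `min_depth` (default 5 reads) or the majority is tied.
Upstream consensus tools leave these per-position rules implicit, so the
package fixes them explicitly and exposes them as parameters. Indels are out
of model: observations are substitutions at fixed marker coordinates, which
matches a protein-coding marker analysed at SNP level.

Three inclusive (≥) sample gates follow: `min_reads` = 2000 marker-mapped
reads, `min_sccg_cov` = 5× mean single-copy core-gene coverage, and
`min_frac_hlii` = 0.90 of core-gene reads binned to the focal ecotype.
Failures are enumerated by gate name; only passing samples feed downstream
stages, and the pipeline manifest records sample counts so the monotone
shrinkage through QC is auditable.

In the binary SNP matrix, one column per (position, alternative base)
observed in at least one passing sample, an `N` is encoded as 0 (allele
absent) rather than as missing data: binary Jaccard has no missing-value
semantics, and dropping whole samples or columns for sparse ambiguity would
discard far more signal. The per-sample count of ambiguous positions is
logged for diagnostics.

## Haplotype clustering and stability

Pairwise sample dissimilarity is binary Jaccard, d = (b+c)/(a+b+c), with the
convention d = 0 (logged) for a pair of all-zero profiles. Trees are built
by WPGMA (McQuitty) agglomeration — the update d(k, i∪j) = (d(k,i)+d(k,j))/2
— implemented here rather than delegated so that tie-breaking is explicit
and platform-independent: the minimum-dissimilarity pair with the smallest
slot indices merges first, where a cluster occupies the slot of its earliest
member. WPGMA heights can invert; inversions are logged, not errors. The
test suite checks the implementation against scipy's independent linkage
code on random instances. A complete-linkage variant on Euclidean distances
serves genome presence/absence trees, serializable to Newick.

Within-cluster sum of squares of the binary rows is non-increasing in the
number of clusters k, so "minimize within-cluster sum of squares" is
operationalized as the elbow of the WSS curve: the k in 2..k_max maximizing
the second difference WSS(k−1) − 2·WSS(k) + WSS(k+1), with k = 1 returned
when no positive curvature exists (e.g. identical rows).

Cluster stability is scored by a character bootstrap, mirroring phylogenetic
practice for sequence-derived groupings: each of `n_boot` (default 1000)
replicates resamples SNP columns with replacement, re-clusters at the base
k, and a base cluster counts as recovered when some replicate cluster
matches its membership at Jaccard similarity ≥ `match_threshold` (default
0.9). Support is the fraction of recovering replicates; clusters with
support below `stability_threshold` (default 0.60, inclusive) are flagged
unstable and excluded from downstream comparisons. Bootstrapping samples
instead of characters would break the per-replicate membership comparison;
the column bootstrap is the documented choice, and both thresholds are
exposed.

## Ω nutrient-stress indicator

Raw coverage is divided by the sample's mean SCCG coverage, which roughly
estimates copies of a gene per genome and cancels sequencing depth exactly
(Ω is invariant to scaling any sample's whole coverage row). Each gene is
z-scored across the full sample set with the sample (n−1) standard
deviation; constant genes z-score to 0 with a warning. Ω for a nutrient type
is the mean z over that type's acquisition genes:

- P: phoA, phoX
- N: focA, moaA, moaB, moaC, moaD, moaE, moeA, napA, narB, nirA
- Fe: cirA, expD, febB, fepB, fepC, tolQ, tonB

(the shorthand "moaA-E" and "fepB/C" expand literally). Standardization is
global across samples by default — matching a pooled multi-cruise analysis —
with per-group gene lists overridable; genes absent from a table are skipped
with a log message, and a group resolving to zero genes is an error. Each Ω
column has zero mean over the standardization sample set by construction.

## Ordination

PCA operates on the z-scored (correlation-matrix) flexible-genome matrix via
SVD; SCCG columns are excluded by default since their normalized values
carry no copy-number signal. Loadings are orthonormal; for reproducibility
across SVD backends, each component is sign-fixed so its largest-magnitude
loading is positive. `top_loadings` ranks genes by |loading| (ties by gene
id) and tallies COG categories. `envfit` regresses an environmental variable
on two score columns: the arrow is the normalized coefficient vector, R² the
OLS coefficient of determination, and significance the permutation fraction
(1 + #{permuted R² ≥ observed}) / (n_perm + 1) with n_perm = 999 by default
(the convention of the reference implementation in vegan). Nutrient-gene
eigenvectors are averaged per nutrient type with the circular mean of
angles — an arithmetic mean of angles would wrap badly around ±π — and the
arithmetic mean of vector norms.

## Ocean distances and the one-dimensional geographic axis

The globe is a plate carrée raster, default 400 × 800 (~0.45°), row 0 at the
90°N edge, column 0 at 180°W; land cells are impassable. Ocean cells form a
graph whose edge weights are haversine distances between cell centers
(R = 6371 km), with longitude wrapping across the antimeridian so Pacific
paths do not detour the globe. Polar rows remain regular cells; the
haversine weights absorb meridian convergence.

Connectivity defaults to 16 neighbors: the 8 compass moves plus 8 knight
moves, the latter requiring their two intermediate cells to be ocean so no
edge cuts across land. The reason is quantitative: pure 8-neighbor (octile)
paths overestimate straight-line travel by up to 8.24% on a plane and by
more on a sphere at higher latitudes (we measured up to ~11% at 0.45°
resolution), whereas the knight-move set keeps the overestimate within a few
percent (measured ≤ 5.1% over random pairs at |lat| ≤ 60°). 4- and
8-neighbor connectivity remain available for comparison.

Samples whose coordinates rasterize onto land snap to the nearest ocean cell
by great-circle distance (ties to the smaller (row, col)); snap distances
are logged. Disconnected basins yield +inf distances, which downstream
statistics refuse.

The pairwise matrix is collapsed to one continuous axis by 1-D non-metric
MDS minimizing Kruskal stress-1: SMACOF majorization with isotonic
regression (scikit-learn's smacof provides the inner loop), initialized from
the classical-MDS first axis plus `n_restarts` random jitters, with the
best-stress configuration returned, centered at zero. Stress-1 of every
candidate (including the initializations themselves) is evaluated by this
package's own isotonic-regression scorer, so a perfect 1-D geometry reaches
stress < 1e-6 exactly when it should. One dimension cannot embed genuinely
2-D ocean geometry without distortion — typical stress on transect layouts
is 0.1–0.3 — but the axis is used only as a distance covariate in the
variance partition, not as an embedding claim.

## Variance partitioning and spatial statistics

PERMANOVA uses sequential (Type-I) sums of squares, the behaviour of adonis2
with terms in model order: with A = −d²/2 Gower-centered to G, each term's
SS is tr((H_t − H_{t−1}) G) for the nested design hat matrices, pseudo-F is
(SS_t/df_t)/(SS_res/df_res), and p-values come from free permutation of
sample labels with the entire sequential decomposition recomputed per
permutation (999 by default). Continuous covariates are single-df regression
terms; categorical covariates contribute (levels − 1) df as dummy blocks.
Rank-deficient additions raise an error naming the collinear pair. On
Euclidean distances of univariate data the decomposition reduces exactly to
classical ANOVA, which the tests exploit as an oracle. Term order follows
the survey's convention: geographic distance (the NMDS axis) always enters
first to absorb spatial autocorrelation, then remaining covariates ordered
by their marginal second-term R². The NMDS axis — rather than the raw
distance matrix — enters as the covariate because a PERMANOVA term must be a
per-sample variable; this reading is recorded as a design choice.

The Mantel statistic is the Pearson correlation of upper triangles, with a
two-sided permutation p from joint row/column permutation of the second
matrix. Distance decay is pair-level OLS of dissimilarity on geographic
distance — overall, within-transect, and between-transect strata — with
strata under 3 pairs reported as NaN. Pair-level OLS ignores the
pseudo-replication of pairs, exactly as an lm on pairs does; the Mantel test
is the companion significance tool. Two-group comparisons use the Welch
(unequal-variance) t-test — safer than the pooled test when cluster sizes
and variances differ, as they do here — and correlations are two-sided
Pearson or Spearman.

All permutation tests are deterministic given a seed, and the pipeline
derives per-stage seeds from one global seed and the stage name, so a full
rerun is byte-identical.

## The synthetic-community generator

`simulate_community` emulates the statistical structure of a global
surface-ocean transect survey of a warm-water picocyanobacterial ecotype.
Default study conditions: 120 samples on 4 predominantly meridional
transects (ocean sections run roughly north–south); SST = 29 − 0.28·|lat| °C
plus N(0, 0.5) noise; a basin-like phosphorus-limitation field — a zonal
Gaussian bump (35° e-folding width) residualized against SST so the two
planted drivers are orthogonal by construction and attribution is
identifiable — with the top 25% of samples labelled the low-P regime.

Marker model: a 600 bp reference; 14 diagnostic SNPs carried together by the
dominant haplotype of every low-P sample; 100 background SNPs assigned to
samples as label-independent Bernoulli draws whose prevalences follow a
U-shaped spectrum (70% rare at 0.02–0.05, 30% near-fixed at 0.85–0.98, as in
real site-frequency spectra — the near-fixed shared alleles keep binary
Jaccard well-conditioned where uniform mid-range prevalences would drown the
diagnostic signal). Reads: per-sample counts ~ negative binomial (mean 4000,
shape 20), read length 100, uniform placement, substitution errors at 0.005
per base; SNPs sit a read length away from marker edges, where coverage
ramps. An optional minority-haplotype admixture fraction (default 0) mixes
in the opposite haplotype for robustness experiments.

Coverage model: per-sample genome depth ~ Gamma(8, mean 20×); SCCG genes at
1 copy; Ω-list P genes (phoA, phoX) shifted by `p_gene_effect_size`
(default +1 copy) in low-P samples; a 10-gene P-stress cassette (pstA/B/C/S,
phoB/E/R, arsR, chrA, gap1 — the co-varying acquisition/regulatory genes a
low-P-adapted genome carries) tracking the continuous P-limitation field,
which is what gives the ordination a recoverable phosphorus axis; 40
flexible genes linearly coupled to SST (slope ±0.05 copies/°C); remaining
flexible genes constant-mean noise. All coverage is negative binomial
(shape 5) — overdispersed, as metagenome gene coverages are — never Poisson.
QC metrics are emitted per sample (read counts occasionally dip below the
2000-read gate, so QC attrition is exercised).

What the generator does **not** emulate: strain mixtures within a sample
beyond the optional two-haplotype admixture; linkage between background
SNPs; gene-length or GC coverage biases; compositionality of relative
abundances; recruitment/mapping artifacts; missing metadata. Passing tests
therefore demonstrate that the pipeline recovers structure *of the kind the
survey assumes* at realistic noise levels — not that real recruitment or
assembly artifacts are handled.

## Problem sizes in the test and acceptance runs

The package's own evaluation uses 120-sample communities, 200 bootstrap
replicates, 199 permutations, and a 120 × 240 (1.5°) ocean grid — sizes
chosen so the full planted-recovery, null-calibration and determinism
experiments complete in minutes while leaving every statistical conclusion
unchanged at the defaults (1000 bootstraps, 999 permutations, 400 × 800
grid).

## Known limitations

- The consensus model cannot represent within-sample haplotype diversity;
  a sample is summarized by its dominant sequence type.
- `N` → 0 encoding slightly deflates Jaccard distances for low-coverage
  samples; the ambiguous-position count is logged so such samples can be
  screened.
- The WSS elbow requires k_max ≥ 3 distinct curvatures; for k near n the
  curve is too flat to be informative.
- Pair-level distance-decay OLS understates uncertainty (pairs are not
  independent); use the Mantel test for significance.
- The 1-D NMDS axis is a covariate, not a faithful embedding; its stress is
  reported and should be inspected.
- Plate carrée cells are not equal-area; haversine edge weights correct
  path lengths but sample density per cell still varies with latitude.
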