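# microgeo

Within-ecotype phylogeography of marine picocyanobacteria from shotgun
metagenomes: from recruited-read pileups and gene-coverage tables to
consensus-SNP haplotype clusters with bootstrap support, genomic
nutrient-stress indicators (Ω), gene-content ordination, land-aware ocean
distances, and variance partitioning.

## Who this is for

Microbial ecologists working with ocean survey metagenomes (Bio-GO-SHIP /
GEOTRACES style transects) who want to ask whether fine-scale phylogenetic
variation *within* an ecotype — e.g. the warm-water, high-light
*Prochlorococcus* clade — is structured by nutrient limitation, temperature,
or dispersal. The package does not align or recruit reads; it starts from
per-sample read pileups over a marker gene (e.g. *rpoC1*) and a samples ×
genes coverage table, both plain TSV.

## The methods at the core

**Consensus haplotypes and QC.** Per sample, the consensus base at each
marker position is the strict-majority base among read observations;
positions with depth < 5 or tied majorities become `N`. Samples pass three
inclusive quality gates: ≥ 2000 marker-mapped reads, ≥ 5× mean single-copy
core-gene (SCCG) coverage, and ≥ 90% of SCCG reads binned to the focal
ecotype. Passing consensus sequences are binarized into a samples ×
(position, alternative allele) matrix against a reference.

**Haplotype clustering.** Binary Jaccard dissimilarity
d = (b + c) / (a + b + c) between SNP profiles, WPGMA (McQuitty)
agglomeration, cluster count at the elbow of the within-cluster
sum-of-squares curve, and per-cluster stability from 1000 column bootstraps
(re-cluster each resampled character matrix; a cluster is recovered when a
replicate cluster matches its membership at Jaccard ≥ 0.9). Clusters below
60% support are flagged unstable and excluded downstream.

**Ω nutrient-stress indicator.** Gene coverage is divided by the sample's
mean SCCG coverage (≈ copies per genome), z-scored per gene across samples,
and averaged over nutrient-acquisition gene sets:
Ω_P = mean z of {phoA, phoX}; Ω_N over {focA, moaA–E, moeA, napA, narB,
nirA}; Ω_Fe over {cirA, expD, febB, fepB, fepC, tolQ, tonB}.

**Ordination.** Correlation-matrix PCA (SVD of the z-scored flexible-genome
matrix) with deterministic loading signs; top-|loading| gene lists with COG
category counts; environmental vectors fitted post hoc by regressing the
variable on two score columns with permutation significance (envfit);
average nutrient-gene eigenvectors per nutrient type (circular-mean angle,
mean magnitude).

**Geography.** A plate carrée land-mask raster (default 400 × 800, ~0.45°)
becomes a graph over ocean cells (16-neighbor by default; haversine edge
weights, R = 6371 km; antimeridian wrap); pairwise sample distance is the
shortest over-ocean path, collapsed to one continuous axis by 1-D
non-metric MDS (Kruskal stress-1).

**Statistics.** Sequential (Type-I) PERMANOVA of a distance matrix on
ordered covariates via Gower-centered projections (distance first, remaining
terms ordered by marginal variance explained), Mantel tests, distance-decay
slopes (overall / within-transect / between-transect OLS on pairs), Welch
t-tests and Pearson/Spearman correlations.

A synthetic-community generator (`microgeo.synthdata`) emulates the survey
structure — transect geometry, a planted low-phosphorus haplotype carrying
14 diagnostic marker SNPs among 100 background SNPs, P-gene enrichment,
temperature-coupled flexible genes, negative-binomial coverage noise — and
emits ground-truth labels, so the entire pipeline is testable end to end
without any downloads.

## Worked example

```python
from microgeo import (SimConfig, simulate_community, call_consensus, qc_filter,
                      binarize_snps, cluster_snps, bootstrap_support,
                      stable_clusters, omega_from_coverage, group_compare)
from microgeo.consensus import set_qc_metrics

cfg = SimConfig(seed=42)                       # 120 samples, 4 transects
coverage, pileup, meta, truth = simulate_community(cfg)

cons = call_consensus(pileup, min_depth=5)
set_qc_metrics(cons, meta)
qc_filter(cons)                                # 2000 reads / 5x SCCG / 90%
snps = binarize_snps(cons, truth.reference_seq)
print(f"{snps.n_samples} samples passed QC; {snps.n_columns} SNP columns")

clusters = cluster_snps(snps)                  # Jaccard -> WPGMA -> elbow k
clusters.support = bootstrap_support(snps, clusters, n_boot=200, seed=1)
clusters = stable_clusters(clusters, threshold=0.60)
print(clusters.summary_frame().to_string(index=False))

om = omega_from_coverage(coverage)             # SCCG-normalize -> z -> means
t, df, p = group_compare(om.omega["P"], clusters.labels)
for lab in sorted(clusters.labels.unique()):
    mean_p = om.omega.loc[clusters.labels.index[clusters.labels == lab], "P"].mean()
    print(f"cluster {lab}: mean omega_P = {mean_p:+.2f}")
print(f"Welch t = {t:.1f}, p = {p:.2e}")
```

prints

```
120 samples passed QC; 114 SNP columns
 cluster  n_samples  support  stable
       1         30    0.985    True
       2         90    0.985    True
cluster 1: mean omega_P = +1.14
cluster 2: mean omega_P = -0.38
Welch t = 9.1, p = 2.70e-10
```

Cluster 1 is the planted low-phosphorus haplotype: 30 samples, stable in
98.5% of character bootstraps, and carrying a significantly higher
phosphorus-acquisition gene load (Ω_P +1.14 vs −0.38) than the background
population — the signature the pipeline is designed to detect.

The same workflow runs from the shell:

```sh
microgeo run --simulate --seed 42 --out-dir runs/demo
```

which writes every stage's outputs (consensus FASTA, SNP matrix, cluster
support table, Ω table, PCA scores/loadings, ocean distances, PERMANOVA
tables, decay slopes) plus a `manifest.json` recording parameters, derived
seeds and per-stage record counts. Reruns with the same seed are
byte-identical. Individual stages are available as subcommands
(`simulate`, `consensus`, `cluster`, `omega`, `pca`, `geodist`, `nmds1d`,
`permanova`, `mantel`, `decay`).

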