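"""End-to-end workflow: simulate/load -> consensus -> clustering -> stats.

Each stage writes plain files into the output directory so any stage can be
re-run independently; a manifest records inputs, parameters, per-stage seeds
and record counts. Stage seeds are derived deterministically from the global
seed and the stage name, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import consensus as cns
from . import formats, geodist, haploclust, omega, ordination, stats, synthdata

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    out_dir: str = "microgeo_run"
    seed: int = 0
    simulate: bool = True
    sim: synthdata.SimConfig | None = None
    # file inputs used when simulate=False
    coverage_path: str | None = None
    gene_meta_path: str | None = None
    sample_meta_path: str | None = None
    pileup_path: str | None = None
    reference_fasta: str | None = None
    landmask_path: str | None = None
    # stage parameters
    min_depth: int = 5
    min_reads: int = 2000
    min_sccg_cov: float = 5.0
    min_frac_hlii: float = 0.90
    n_boot: int = 1000
    stability_threshold: float = 0.60
    k_max: int = 10
    grid_rows: int = 400
    grid_cols: int = 800
    n_perm: int = 999
    nmds_restarts: int = 10

    def __post_init__(self):
        if self.sim is None:
            self.sim = synthdata.SimConfig(seed=stage_seed(self.seed, "simulate"))


def _float_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("sim", "out_dir")
        },
    }

    # ----- inputs ---------------------------------------------------------
    if config.simulate:
        manifest["parameters"]["sim"] = asdict(config.sim)
        coverage, pileup, meta, truth = synthdata.simulate_community(config.sim)
        mask = synthdata.synthetic_landmask(config.grid_rows, config.grid_cols)
        formats.write_coverage_table(coverage, out / "coverage.tsv",
                                     out / "gene_meta.tsv")
        formats.write_sample_meta(meta, out / "sample_meta.tsv")
        pileup.to_tsv(out / "pileup.tsv")
        truth.to_json(out / "truth.json")
        formats.write_landmask(mask, out / "landmask.tsv")
        reference_seq = truth.reference_seq
    else:
        for name in ("coverage_path", "gene_meta_path", "sample_meta_path",
                     "pileup_path", "reference_fasta", "landmask_path"):
            if getattr(config, name) is None:
                raise formats.ValidationError(f"missing required input {name!r}")
        coverage = formats.read_coverage_table(config.coverage_path,
                                               config.gene_meta_path)
        meta = formats.read_sample_meta(config.sample_meta_path)
        ref = formats.read_consensus_fasta(config.reference_fasta)
        reference_seq = next(iter(ref.values()))
        pileup = cns.PileupSet.from_tsv(config.pileup_path,
                                        marker_length=len(reference_seq),
                                        reference_seq=reference_seq)
        mask = formats.read_landmask(config.landmask_path)
    manifest["stages"]["input"] = {"n_samples": len(meta)}

    # ----- consensus + QC -------------------------------------------------
    consensus_set = cns.call_consensus(pileup, min_depth=config.min_depth)
    cns.set_qc_metrics(consensus_set, meta)
    cns.qc_filter(consensus_set, min_reads=config.min_reads,
                  min_sccg_cov=config.min_sccg_cov,
                  min_frac_hlii=config.min_frac_hlii)
    cons_meta = cns.consensus_metadata_frame(consensus_set)
    _float_csv(cons_meta, out / "consensus_meta.tsv", index=True)
    formats.write_consensus_fasta(
        {sid: c.sequence for sid, c in consensus_set.items()},
        out / "consensus.fasta")
    passing = [sid for sid, c in consensus_set.items() if c.qc_pass]
    manifest["stages"]["consensus"] = {
        "n_samples": len(consensus_set), "n_qc_pass": len(passing)}
    if len(passing) < 3:
        raise formats.ValidationError("fewer than 3 samples passed QC")
    meta_pass = meta.loc[passing]

    # ----- SNPs + clustering ---------------------------------------------
    snps = cns.binarize_snps(consensus_set, reference_seq)
    snps.to_tsv(out / "snps.tsv")
    base = haploclust.cluster_snps(snps, k_max=config.k_max)
    support = haploclust.bootstrap_support(
        snps, base, n_boot=config.n_boot,
        seed=stage_seed(config.seed, "bootstrap"))
    base.support = support
    base.n_boot = config.n_boot
    result = haploclust.stable_clusters(base, config.stability_threshold)
    _float_csv(result.labels.to_frame(), out / "clusters.tsv", index=True,
               index_label="sample_id")
    _float_csv(result.summary_frame(), out / "cluster_support.tsv", index=False)
    (out / "dendrogram.nwk").write_text(result.dendrogram.to_newick() + "\n")
    stable_ids = result.stable_sample_ids()
    manifest["stages"]["cluster"] = {
        "n_samples": snps.n_samples, "n_snp_columns": snps.n_columns,
        "k": result.k,
        "n_stable_clusters": int(sum(result.stable.values())),
        "support": {str(k): v for k, v in result.support.items()},
        "n_samples_in_stable": len(stable_ids),
    }

    # ----- omega + ordination --------------------------------------------
    norm = omega.normalize_by_sccg(coverage)
    norm_pass = formats.CoverageTable(values=norm.values.loc[passing],
                                      gene_meta=norm.gene_meta,
                                      normalized=True)
    om = omega.omega_from_coverage(norm_pass)
    _float_csv(om.omega, out / "omega.tsv", index=True, index_label="sample_id")
    ord_res = ordination.genomic_pca(norm_pass)
    _float_csv(ord_res.scores, out / "pca_scores.tsv", index=True,
               index_label="sample_id")
    _float_csv(ord_res.loadings, out / "pca_loadings.tsv", index=True,
               index_label="gene_id")
    _float_csv(pd.DataFrame({"var_explained": ord_res.var_explained}),
               out / "pca_var_explained.tsv", index=False)
    arrow = ordination.envfit(ord_res, meta_pass["sst"].to_numpy(),
                              plane=(1, 2), n_perm=config.n_perm,
                              seed=stage_seed(config.seed, "envfit"),
                              variable_name="sst")
    nvecs = ordination.nutrient_vectors(ord_res, norm_pass.gene_meta, plane=(1, 2))
    arrows = pd.DataFrame(
        [{"variable": arrow.variable_name, "dx": arrow.direction[0],
          "dy": arrow.direction[1], "r_squared": arrow.r_squared,
          "p_value": arrow.p_value}]
        + [{"variable": f"omega_{g}", "dx": np.cos(v.mean_angle),
            "dy": np.sin(v.mean_angle), "r_squared": v.mean_magnitude ** 2,
            "p_value": np.nan} for g, v in nvecs.items()])
    _float_csv(arrows, out / "arrows.tsv", index=False)
    manifest["stages"]["ordination"] = {
        "n_samples": len(ord_res.scores),
        "n_components": ord_res.component_count,
        "sst_envfit_r2": arrow.r_squared,
    }

    # ----- geography ------------------------------------------------------
    grid = geodist.OceanGrid(land=mask)
    geo_dm = geodist.pairwise_ocean_distance(meta_pass, grid)
    formats.write_distance_matrix(geo_dm, out / "geo_dist.tsv")
    axis, stress = geodist.nmds_1d(geo_dm, n_restarts=config.nmds_restarts,
                                   seed=stage_seed(config.seed, "nmds"))
    _float_csv(axis.to_frame(), out / "geo_axis.tsv", index=True,
               index_label="sample_id")
    manifest["stages"]["geodist"] = {
        "n_samples": len(geo_dm), "nmds_stress": stress}

    # ----- distance matrices for statistics -------------------------------
    z = omega.zscore_genes(norm_pass)
    gx = z[[g for g in z.columns if not norm_pass.gene_meta.loc[g, "is_sccg"]]]
    gm = gx.to_numpy()
    diff = gm[:, None, :] - gm[None, :, :]
    genomic_dm = formats.DistanceMatrix(
        passing, np.sqrt((diff ** 2).sum(axis=2)), "euclidean_zscore")
    phylo_dm = haploclust.jaccard_binary(snps)
    formats.write_distance_matrix(genomic_dm, out / "genomic_dist.tsv")
    formats.write_distance_matrix(phylo_dm, out / "phylo_dist.tsv")

    # ----- PERMANOVA / Mantel / decay --------------------------------------
    covariates = pd.DataFrame({
        "distance": axis,
        "sst": meta_pass["sst"],
        "omega_P": om.omega["P"],
        "omega_N": om.omega["N"],
        "omega_Fe": om.omega["Fe"],
    })
    results = {}
    for name, dm in (("genomic", genomic_dm), ("phylogenetic", phylo_dm)):
        order = stats.order_terms_by_marginal_r2(
            dm, "distance", ["sst", "omega_P", "omega_N", "omega_Fe"],
            covariates, n_perm=1, seed=stage_seed(config.seed, f"order-{name}"))
        tab = stats.permanova_sequential(
            dm, covariates[order], n_perm=config.n_perm,
            seed=stage_seed(config.seed, f"permanova-{name}"))
        _float_csv(tab.summary(), out / f"permanova_{name}.tsv", index=True)
        results[name] = tab
    mres = stats.mantel(genomic_dm, phylo_dm, n_perm=config.n_perm,
                        seed=stage_seed(config.seed, "mantel"))
    decay = {
        name: stats.distance_decay(dm, geo_dm, meta_pass["transect_id"])
        for name, dm in (("genomic", genomic_dm), ("phylogenetic", phylo_dm))
    }
    decay_df = pd.DataFrame({name: asdict(d) for name, d in decay.items()})
    _float_csv(decay_df, out / "distance_decay.tsv", index=True)
    manifest["stages"]["stats"] = {
        "n_samples": len(passing),
        "mantel_r2": mres.r_squared,
        "mantel_p": mres.p_value,
        "permanova": {
            name: {t: tab.r_squared[t] for t in tab.terms}
            for name, tab in results.items()
        },
        "decay_slope": {name: d.slope_overall for name, d in decay.items()},
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
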