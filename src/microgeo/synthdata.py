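"""Synthetic ocean-transect communities with planted phylogeographic structure.

The generator emulates the statistical structure of a global surface-ocean
metagenome survey of a warm-water picocyanobacterial ecotype:

* samples placed along cruise-like transects with a sea-surface-temperature
  field monotone in |latitude|;
* a dominant background marker-gene haplotype plus a planted low-phosphorus
  haplotype distinguished by a fixed set of diagnostic SNPs, against
  label-independent background SNPs;
* per-sample read pileups over the marker with negative-binomial read counts
  and uniform per-base sequencing error;
* a gene coverage table in which single-copy core genes track a per-sample
  genome depth, phosphorus-acquisition genes are enriched in low-P samples,
  a designated block of flexible genes is linearly coupled to temperature,
  and everything carries overdispersed (negative binomial) noise.

Every draw flows from one seed; identical configs give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .consensus import BASES, PileupSet
from .formats import CoverageTable, ValidationError

# Nutrient-acquisition marker genes grouped by stress type. "moaA-E" expands
# to moaA..moaE and "fepB/C" to fepB, fepC.
DEFAULT_GENE_GROUPS: dict[str, list[str]] = {
    "P": ["phoA", "phoX"],
    "N": ["focA", "moaA", "moaB", "moaC", "moaD", "moaE", "moeA",
          "napA", "narB", "nirA"],
    "Fe": ["cirA", "expD", "febB", "fepB", "fepC", "tolQ", "tonB"],
}

# P-stress response cassette: co-varying acquisition/regulatory genes carried
# by low-P-adapted genomes. They respond to the continuous P-limitation field
# (and are therefore enriched in low-P samples) but are not part of the
# canonical Omega-P indicator list above.
P_CASSETTE_GENES = ["pstA", "pstB", "pstC", "pstS", "phoB", "phoE", "phoR",
                    "arsR", "chrA", "gap1"]

COG_LETTERS = list("CDEFGHIJKLMNOPQRSTUV")


@dataclass
class SimConfig:
    """Study conditions for one synthetic community.

    Defaults mirror the survey being emulated: 120 samples on 4 transects,
    a 600 bp marker with 14 diagnostic and 100 background SNPs, ~25% of
    samples in the low-P regime, read counts overdispersed around 4000
    recruited reads, and gene coverage overdispersed around a per-sample
    genome depth of 20x.
    """

    n_samples: int = 120
    n_transects: int = 4
    marker_length: int = 600
    n_diagnostic_snps: int = 14
    n_background_snps: int = 100
    n_genes_flexible: int = 150
    n_temp_coupled: int = 40
    n_sccg: int = 50
    frac_lowP_samples: float = 0.25
    read_depth_mean: float = 4000.0
    read_length: int = 100
    read_count_dispersion: float = 20.0
    seq_error_rate: float = 0.005
    coverage_depth_mean: float = 20.0
    coverage_dispersion: float = 5.0
    temp_effect_size: float = 0.05
    p_gene_effect_size: float = 1.0
    minority_haplotype_fraction: float = 0.0
    sst_noise_sd: float = 0.5
    plim_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_transects < 1:
            raise ValidationError("n_samples and n_transects must be positive")
        if self.n_diagnostic_snps + self.n_background_snps > self.marker_length:
            raise ValidationError(
                f"{self.n_diagnostic_snps} diagnostic + {self.n_background_snps} "
                f"background SNPs exceed marker length {self.marker_length}"
            )
        if self.marker_length <= 2 * self.read_length:
            raise ValidationError("marker_length must exceed twice read_length")
        for name in ("frac_lowP_samples", "seq_error_rate",
                     "minority_haplotype_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in ("read_depth_mean", "coverage_depth_mean",
                     "coverage_dispersion", "read_count_dispersion"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        n_named = (sum(len(v) for v in DEFAULT_GENE_GROUPS.values())
                   + len(P_CASSETTE_GENES))
        if self.n_genes_flexible < n_named + self.n_temp_coupled:
            raise ValidationError(
                f"n_genes_flexible must cover {n_named} nutrient/cassette genes "
                f"plus {self.n_temp_coupled} temperature-coupled genes"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimTruth:
    """Ground truth emitted with each simulated community."""

    haplotype_label: pd.Series            # sample -> {background, lowP}
    env_p_limitation: pd.Series           # sample -> real
    planted_snp_columns: list[tuple[int, str]]
    background_snp_columns: list[tuple[int, str]]
    effect_table: pd.DataFrame            # gene -> (effect, value)
    reference_seq: str

    def to_json(self, path) -> None:
        payload = {
            "haplotype_label": self.haplotype_label.to_dict(),
            "env_p_limitation": {k: float(v) for k, v
                                 in self.env_p_limitation.items()},
            "planted_snp_columns": [[int(p), b] for p, b
                                    in self.planted_snp_columns],
            "background_snp_columns": [[int(p), b] for p, b
                                       in self.background_snp_columns],
            "effect_table": {g: {"effect": r["effect"], "value": float(r["value"])}
                             for g, r in self.effect_table.iterrows()},
            "reference_seq": self.reference_seq,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# sample placement and environment
# ---------------------------------------------------------------------------

def _place_transects(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Samples along cruise-like tracks; lat clamped to [-65, 65]."""
    sids, lats, lons, tids = [], [], [], []
    per = np.full(cfg.n_transects, cfg.n_samples // cfg.n_transects)
    per[: cfg.n_samples % cfg.n_transects] += 1
    k = 0
    for t in range(cfg.n_transects):
        lat0 = rng.uniform(-50, 50)
        lon0 = rng.uniform(-180, 180)
        # predominantly meridional tracks, as ocean survey sections are
        dlat = 2.5 * float(rng.choice((-1.0, 1.0)))
        dlon = float(rng.uniform(-0.5, 0.5))
        for i in range(per[t]):
            lat = float(np.clip(lat0 + i * dlat + rng.normal(0, 0.3), -65, 65))
            lon = float((lon0 + i * dlon + rng.normal(0, 0.3) + 180) % 360 - 180)
            sids.append(f"s{k:04d}")
            lats.append(lat)
            lons.append(lon)
            tids.append(f"T{t}")
            k += 1
    df = pd.DataFrame({"latitude": lats, "longitude": lons, "transect_id": tids},
                      index=pd.Index(sids, name="sample_id"))
    return df


def simulate_env_field(sample_meta: pd.DataFrame, seed: int,
                       sst_noise_sd: float = 0.5,
                       plim_noise_sd: float = 0.05) -> pd.DataFrame:
    """Per-sample SST and P-limitation covariates for given sample positions.

    SST is strictly decreasing in |latitude| before noise. P limitation is a
    smooth spatial bump (basin-like) centred on the first sample's position,
    so low-P pressure is regionally coherent rather than tied to latitude.
    """
    rng = np.random.default_rng(seed)
    lat = sample_meta["latitude"].to_numpy(dtype=float)
    lon = sample_meta["longitude"].to_numpy(dtype=float)
    sst = 29.0 - 0.28 * np.abs(lat) + rng.normal(0, sst_noise_sd, len(lat))
    # basin-like P limitation: a zonal (longitude-only) bump centred on the
    # first sample's basin, residualized against SST so the two planted
    # drivers are orthogonal by construction and separable downstream
    dlon = (lon - lon[0] + 180) % 360 - 180
    bump = np.exp(-((dlon / 35.0) ** 2))
    X = np.column_stack([np.ones_like(sst), sst])
    coef, *_ = np.linalg.lstsq(X, bump, rcond=None)
    plim = bump - X @ coef + rng.normal(0, plim_noise_sd, len(lat))
    return pd.DataFrame({"sst": sst, "p_limitation": plim},
                        index=sample_meta.index)


# ---------------------------------------------------------------------------
# marker haplotypes and pileups
# ---------------------------------------------------------------------------

def _random_reference(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _alt_base(ref_idx: int, rng: np.random.Generator) -> int:
    return int((ref_idx + rng.integers(1, 4)) % 4)


def _simulate_pileup(cfg: SimConfig, rng: np.random.Generator,
                     hap_idx: dict[str, np.ndarray],
                     minor_idx: dict[str, np.ndarray],
                     ref_seq: str) -> PileupSet:
    L, ell = cfg.marker_length, cfg.read_length
    k = cfg.read_count_dispersion
    p_nb = k / (k + cfg.read_depth_mean)
    pileup = PileupSet(marker_length=L, reference_seq=ref_seq)
    for sid, hap in hap_idx.items():
        n_reads = int(rng.negative_binomial(k, p_nb))
        pileup.n_reads[sid] = n_reads
        counts = np.zeros((L, 4), dtype=np.int64)
        mfrac = cfg.minority_haplotype_fraction
        n_minor = rng.binomial(n_reads, mfrac) if mfrac > 0 else 0
        for hap_i, n_r in ((hap, n_reads - n_minor), (minor_idx[sid], n_minor)):
            if n_r == 0:
                continue
            starts = rng.integers(0, L - ell + 1, size=n_r)
            diff = np.zeros(L + 1, dtype=np.int64)
            np.add.at(diff, starts, 1)
            np.add.at(diff, starts + ell, -1)
            depth = np.cumsum(diff[:-1])
            _accumulate_base_counts(counts, depth, hap_i, cfg.seq_error_rate, rng)
        pileup.counts[sid] = counts
    return pileup


def _accumulate_base_counts(counts: np.ndarray, depth: np.ndarray,
                            hap_idx: np.ndarray, err: float,
                            rng: np.random.Generator) -> None:
    """Add depth observations of hap_idx with uniform substitution errors."""
    n_err = rng.binomial(depth, err) if err > 0 else np.zeros_like(depth)
    # split errors uniformly over the three non-true bases
    e1 = rng.binomial(n_err, 1.0 / 3.0)
    e2 = rng.binomial(n_err - e1, 0.5)
    e3 = n_err - e1 - e2
    L = len(depth)
    rows = np.arange(L)
    counts[rows, hap_idx] += depth - n_err
    for j, e in enumerate((e1, e2, e3)):
        alt = (hap_idx + 1 + j) % 4
        counts[rows, alt] += e


# ---------------------------------------------------------------------------
# gene coverage
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative binomial with mean `mean` and shape k (var = m + m^2/k)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    lam = rng.gamma(shape=k, scale=mean / k)
    return rng.poisson(lam).astype(float)


def _simulate_coverage(cfg: SimConfig, rng: np.random.Generator,
                       meta: pd.DataFrame, lowp: np.ndarray,
                       plim: np.ndarray
                       ) -> tuple[CoverageTable, pd.DataFrame, pd.Series]:
    n = len(meta)
    sccg_ids = [f"sccg_{i:04d}" for i in range(cfg.n_sccg)]
    nutrient_ids = [g for genes in DEFAULT_GENE_GROUPS.values() for g in genes]
    temp_ids = [f"flex_t{i:04d}" for i in range(cfg.n_temp_coupled)]
    n_noise = (cfg.n_genes_flexible - len(nutrient_ids)
               - len(P_CASSETTE_GENES) - cfg.n_temp_coupled)
    noise_ids = [f"flex_n{i:04d}" for i in range(n_noise)]
    gene_ids = sccg_ids + nutrient_ids + P_CASSETTE_GENES + temp_ids + noise_ids

    depth = rng.gamma(shape=8.0, scale=cfg.coverage_depth_mean / 8.0, size=n)
    sst = meta["sst"].to_numpy(dtype=float)
    sst_c = sst - sst.mean()

    mu = np.empty((n, len(gene_ids)))
    effects = []
    col = 0
    for _ in sccg_ids:
        mu[:, col] = 1.0
        effects.append(("none", 0.0))
        col += 1
    for group, genes in DEFAULT_GENE_GROUPS.items():
        for _ in genes:
            base = rng.uniform(0.3, 0.8)
            shift = cfg.p_gene_effect_size * lowp if group == "P" else 0.0
            mu[:, col] = base + shift
            effects.append(("p_shift" if group == "P" else "none",
                            cfg.p_gene_effect_size if group == "P" else 0.0))
            col += 1
    for _ in P_CASSETTE_GENES:
        base = rng.uniform(0.2, 0.5)
        mu[:, col] = base + cfg.p_gene_effect_size * np.clip(plim, 0.0, None)
        effects.append(("p_cassette", cfg.p_gene_effect_size))
        col += 1
    for _ in temp_ids:
        sign = rng.choice((-1.0, 1.0))
        slope = sign * cfg.temp_effect_size
        mu[:, col] = np.clip(0.6 + slope * sst_c, 0.02, None)
        effects.append(("sst_slope", slope))
        col += 1
    for _ in noise_ids:
        mu[:, col] = rng.uniform(0.2, 1.5)
        effects.append(("none", 0.0))
        col += 1

    cov = _nb_draw(rng, mu * depth[:, None], cfg.coverage_dispersion)
    # SCCGs must stay strictly positive so normalization is defined
    sccg_block = cov[:, : cfg.n_sccg]
    sccg_block[sccg_block == 0] = 1.0

    values = pd.DataFrame(cov, index=meta.index, columns=gene_ids)
    group_of = {g: grp for grp, genes in DEFAULT_GENE_GROUPS.items() for g in genes}
    gene_meta = pd.DataFrame({
        "is_sccg": [g in set(sccg_ids) for g in gene_ids],
        "nutrient_group": [group_of.get(g, "none") for g in gene_ids],
        "cog_category": rng.choice(COG_LETTERS, size=len(gene_ids)),
    }, index=pd.Index(gene_ids, name="gene_id"))
    table = CoverageTable(values=values, gene_meta=gene_meta, normalized=False)
    effect_table = pd.DataFrame(effects, columns=["effect", "value"],
                                index=pd.Index(gene_ids, name="gene_id"))
    return table, effect_table, pd.Series(depth, index=meta.index, name="depth")


# ---------------------------------------------------------------------------
# top-level generator
# ---------------------------------------------------------------------------

def simulate_community(cfg: SimConfig
                       ) -> tuple[CoverageTable, PileupSet, pd.DataFrame, SimTruth]:
    """Generate one synthetic community: coverage, pileups, metadata, truth."""
    rng = np.random.default_rng(cfg.seed)

    meta = _place_transects(cfg, rng)
    env = simulate_env_field(meta, seed=int(rng.integers(2**31)),
                             sst_noise_sd=cfg.sst_noise_sd,
                             plim_noise_sd=cfg.plim_noise_sd)
    meta["sst"] = env["sst"]

    n = cfg.n_samples
    n_lowp = int(round(cfg.frac_lowP_samples * n))
    order = np.argsort(-env["p_limitation"].to_numpy(), kind="stable")
    lowp = np.zeros(n, dtype=bool)
    lowp[order[:n_lowp]] = True
    labels = pd.Series(np.where(lowp, "lowP", "background"), index=meta.index,
                       name="haplotype_label")

    # marker sequences: reference, diagnostic alleles, background alleles
    ref_idx = _random_reference(cfg.marker_length, rng)
    margin = cfg.read_length
    positions = rng.choice(
        np.arange(margin, cfg.marker_length - margin),
        size=cfg.n_diagnostic_snps + cfg.n_background_snps, replace=False)
    diag_pos = np.sort(positions[: cfg.n_diagnostic_snps])
    bg_pos = np.sort(positions[cfg.n_diagnostic_snps:])
    diag_alt = np.array([_alt_base(ref_idx[p], rng) for p in diag_pos])
    bg_alt = np.array([_alt_base(ref_idx[p], rng) for p in bg_pos])
    # U-shaped allele-frequency spectrum: mostly rare variants plus a block
    # of near-fixed derived alleles shared across the ecotype relative to
    # the reference (keeps binary Jaccard well-conditioned, as in real data)
    n_bg = len(bg_pos)
    n_common = int(round(0.3 * n_bg))
    bg_prev = np.concatenate([
        rng.uniform(0.02, 0.05, size=n_bg - n_common),
        rng.uniform(0.85, 0.98, size=n_common),
    ])
    bg_carrier = rng.random((n, n_bg)) < bg_prev  # label-independent

    hap_idx: dict[str, np.ndarray] = {}
    minor_idx: dict[str, np.ndarray] = {}
    for i, sid in enumerate(meta.index):
        hap = ref_idx.copy()
        hap[bg_pos[bg_carrier[i]]] = bg_alt[bg_carrier[i]]
        minor = hap.copy()
        if lowp[i]:
            hap[diag_pos] = diag_alt  # dominant low-P haplotype
        else:
            minor[diag_pos] = diag_alt
        hap_idx[sid] = hap
        minor_idx[sid] = minor

    ref_seq = "".join(BASES[i] for i in ref_idx)
    pileup = _simulate_pileup(cfg, rng, hap_idx, minor_idx, ref_seq)

    coverage, effect_table, depth = _simulate_coverage(
        cfg, rng, meta, lowp, env["p_limitation"].to_numpy())
    meta["n_rpoc1_reads"] = [pileup.n_reads[s] for s in meta.index]
    meta["mean_sccg_coverage"] = coverage.values[
        [g for g in coverage.genes if coverage.gene_meta.loc[g, "is_sccg"]]
    ].mean(axis=1)
    meta["frac_sccg_hlii"] = rng.uniform(0.92, 1.0, size=n)

    truth = SimTruth(
        haplotype_label=labels,
        env_p_limitation=env["p_limitation"],
        planted_snp_columns=[(int(p), BASES[a]) for p, a in zip(diag_pos, diag_alt)],
        background_snp_columns=[(int(p), BASES[a]) for p, a in zip(bg_pos, bg_alt)],
        effect_table=effect_table,
        reference_seq=ref_seq,
    )
    return coverage, pileup, meta, truth


def synthetic_landmask(rows: int, cols: int) -> np.ndarray:
    """A simple deterministic mask: one meridional continent with a gap.

    The continent spans a band of columns near one third of the grid width,
    from 60°N down to 30°S, leaving the southern ocean open so the grid stays
    connected while blocking direct zonal paths at mid latitudes.
    """
    mask = np.zeros((rows, cols), dtype=bool)
    c0, c1 = int(cols * 0.30), int(cols * 0.34) + 1
    r0 = int(rows * (90 - 60) / 180)   # 60 N
    r1 = int(rows * (90 + 30) / 180)   # 30 S
    mask[r0:r1, c0:c1] = True
    return mask
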